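"""Community flux fitting: recovery, conservation, scenario contrast."""

import numpy as np
import pytest

from tidemet.community import (
    CommunityModel,
    FitError,
    fit_rates,
    population_abundances,
    scenario_compare,
)
from tidemet.network import Network
from tidemet.stoichiometry import ConversionVector
from tidemet.synth import generate_observations


def _single_reaction_network(network):
    rxn = network.get("e")  # aerobic acetate respiration
    return Network(registry=network.registry, reactions=[rxn])


class TestFitBasics:
    def test_single_reaction_rate_recovered_exactly(self, network):
        small = _single_reaction_network(network)
        obs = generate_observations(small, {"e": 2.0})
        res = fit_rates(small, obs, scenario="both")
        assert res.rates["e"] == pytest.approx(2.0, abs=1e-6)
        assert res.residual_norm < 1e-6

    def test_modeled_equals_s_times_v(self, network, observed):
        res = fit_rates(network, observed, include_growth=False)
        compounds = network.compound_ids(res.model.reactions)
        S = network.stoich_matrix(compounds, res.model.reactions)
        v = np.array([res.rates[r.id] for r in res.model.reactions])
        flux = S @ v
        for cid, f in zip(compounds, flux):
            if cid == "biomass":
                assert res.modeled.biomass_rate == pytest.approx(f)
            else:
                assert res.modeled.rates[cid] == pytest.approx(f)

    def test_all_zero_observations_warn_and_return_zero(self, network):
        obs = ConversionVector({"acetate": 0.0, "O2": 0.0})
        with pytest.warns(UserWarning, match="zero"):
            res = fit_rates(network, obs, include_growth=False)
        assert all(v == 0 for v in res.rates.values())

    def test_empty_scenario_rejected(self, network):
        obs = ConversionVector({"acetate": -1.0})
        with pytest.raises(FitError):
            CommunityModel(network, obs, scenario="nonexistent")


class TestRecovery:
    def test_noise_free_roundtrip_recovers_rates(self, network):
        """Forward-simulate a sparse identifiable rate vector, refit, and
        recover it to 1e-5."""
        truth = {"d": 1.2, "e": 0.8, "h": 0.5, "r": 1.5, "q": 0.3, "v": 0.4}
        obs = generate_observations(network, truth)
        res = fit_rates(network, obs, scenario="unsorted", include_growth=True)
        for rid, v in truth.items():
            assert res.rates[rid] == pytest.approx(v, abs=1e-5), rid
        # modeled conversions match the construction everywhere
        for cid, rate in obs.rates.items():
            assert res.modeled.rates[cid] == pytest.approx(rate, abs=1e-6)

    def test_random_sparse_recovery(self, network):
        rng = np.random.default_rng(42)
        identifiable = ["d", "e", "f", "g", "h", "i", "k", "o", "p", "q", "r", "s", "v"]
        for _ in range(5):
            support = rng.choice(identifiable, size=4, replace=False)
            truth = {rid: float(rng.uniform(0.1, 3.0)) for rid in support}
            obs = generate_observations(network, truth)
            # no ridge: the tie-break is unnecessary for identifiable
            # supports and would bias ill-conditioned pairs slightly
            res = fit_rates(network, obs, scenario="unsorted", regularization=0.0)
            for rid, v in truth.items():
                assert res.rates[rid] == pytest.approx(v, abs=1e-5)

    def test_yield_stable_under_observation_noise(self, network, observed):
        """5% relative noise on the observations shifts the community yield
        by less than 0.05."""
        base = fit_rates(network, observed, include_growth=False).community_yield
        rng = np.random.default_rng(7)
        for seed in range(3):
            noisy_rates = {
                cid: rate * (1 + 0.05 * rng.standard_normal())
                for cid, rate in observed.rates.items()
            }
            noisy = ConversionVector(noisy_rates)
            y = fit_rates(network, noisy, include_growth=False).community_yield
            assert abs(y - base) < 0.05


class TestConservation:
    def test_fitted_conversions_conserve_elements(self, network, observed):
        """C, N and electron totals of the modeled conversion vector vanish
        (biomass and all free outputs included)."""
        res = fit_rates(network, observed, include_growth=False)
        reg = network.registry
        totals = {"C": 0.0, "N": 0.0, "e": 0.0}
        items = dict(res.modeled.rates)
        items["biomass"] = res.modeled.biomass_rate
        for cid, rate in items.items():
            comp = reg[cid]
            totals["C"] += rate * comp.formula.get("C", 0.0)
            totals["N"] += rate * comp.formula.get("N", 0.0)
            totals["e"] += rate * comp.electron_content()
        for key, val in totals.items():
            assert abs(val) < 1e-6, key


class TestCommunityQuantities:
    def test_paper_conditions_yield(self, network, observed):
        res = fit_rates(network, observed, scenario="unsorted", include_growth=False)
        assert res.community_yield == pytest.approx(0.32, abs=0.05)

    def test_single_population_abundance_is_one(self, network):
        small = _single_reaction_network(network)
        obs = generate_observations(small, {"e": 1.0})
        res = fit_rates(small, obs, scenario="both")
        assert res.abundances == {"A": pytest.approx(1.0)}

    def test_two_bins_growing_one_to_three(self, network):
        sub = Network(
            registry=network.registry,
            reactions=[network.get("e"), network.get("f")],
        )
        ye = network.get("e").net_stoich["biomass"]
        yf = network.get("f").net_stoich["biomass"]
        obs = generate_observations(sub, {"e": 1.0 / ye, "f": 3.0 / yf})
        res = fit_rates(sub, obs, scenario="both")
        assert res.abundances["A"] == pytest.approx(0.25, abs=1e-6)
        assert res.abundances["B"] == pytest.approx(0.75, abs=1e-6)

    def test_zero_growth_abundances_rejected(self, network):
        obs = ConversionVector({"glucose": 0.0})
        with pytest.warns(UserWarning):
            res = fit_rates(network, obs, include_growth=False)
        with pytest.raises(FitError):
            population_abundances(res)

    def test_yield_undefined_without_carbon_consumption(self, network):
        obs = ConversionVector({"glucose": 0.0})
        with pytest.warns(UserWarning):
            res = fit_rates(network, obs, include_growth=False)
        with pytest.raises(FitError):
            res.community_yield


class TestScenarios:
    def test_sorted_yield_exceeds_unsorted(self, network, observed):
        cmp = scenario_compare(network, observed, include_growth=False)
        assert cmp.sorted_fit.community_yield > cmp.unsorted_fit.community_yield

    def test_unsorted_matches_observations_better(self, network, observed):
        cmp = scenario_compare(network, observed, include_growth=False)
        assert cmp.unsorted_fit.residual_norm < cmp.sorted_fit.residual_norm
        assert cmp.better == "unsorted"

    def test_fermenters_grow_only_in_unsorted_scenario(self, network, observed):
        cmp = scenario_compare(network, observed, include_growth=False)
        unsorted_ab = cmp.unsorted_fit.abundances
        sorted_ab = cmp.sorted_fit.abundances
        assert unsorted_ab.get("D", 0) > 0
        assert unsorted_ab.get("F", 0) > 0
        assert sorted_ab.get("D", 0) == 0
        assert sorted_ab.get("F", 0) == 0

    def test_identical_allowed_sets_identical_results(self, network, observed):
        a = fit_rates(network, observed, scenario="unsorted", include_growth=False)
        b = fit_rates(network, observed, scenario="unsorted", include_growth=False)
        assert a.rates == b.rates
        assert a.residual_norm == b.residual_norm

    def test_pure_canonical_respiration_fits_sorted_exactly(self, network):
        truth = {"a": 1.0, "b": 0.6, "c": 0.1}
        obs = generate_observations(network, truth)
        res = fit_rates(network, obs, scenario="sorted")
        assert res.residual_norm < 1e-6
        for rid, v in truth.items():
            assert res.rates[rid] == pytest.approx(v, abs=1e-5)

    def test_summary_mentions_both_scenarios(self, network, observed):
        cmp = scenario_compare(network, observed, include_growth=False)
        text = cmp.summary()
        assert "sorted" in text and "unsorted" in text
        assert "better match" in text
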