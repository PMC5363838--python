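"""Synthetic-data generators: chemostat dynamics, observation vectors,
count tables."""

import math

import numpy as np
import pytest

from tidemet.omics import transcriptional_activity
from tidemet.synth import (
    ChemostatParams,
    SimulationError,
    generate_counts,
    generate_observations,
    simulate_cycle,
)


@pytest.fixture(scope="module")
def default_run():
    return simulate_cycle()


class TestSimulateCycle:
    def test_oxygen_window_about_two_hours(self, default_run):
        """Oxygen remains available for ~2 h after the pulse ends."""
        assert default_run.o2_window() == pytest.approx(2.0, abs=0.5)

    def test_concentrations_stay_nonnegative(self, default_run):
        for name, traj in default_run.states.items():
            assert traj.min() > -1e-8, name

    def test_same_seed_identical_trajectories(self):
        a = simulate_cycle(ChemostatParams(seed=5), noise_sd=0.05)
        b = simulate_cycle(ChemostatParams(seed=5), noise_sd=0.05)
        for name in a.states:
            assert np.array_equal(a.states[name], b.states[name]), name

    def test_different_seed_different_noise(self):
        a = simulate_cycle(ChemostatParams(seed=1), noise_sd=0.05)
        b = simulate_cycle(ChemostatParams(seed=2), noise_sd=0.05)
        assert not np.array_equal(a.states["O2"], b.states["O2"])

    def test_zero_biomass_oxygen_decay_matches_closed_form(self):
        """Without cells (and without headspace exchange) dissolved O2
        decays as a pure exponential through stripping + dilution."""
        p = ChemostatParams(biomass0=0.0, headspace=False, pulse_mmol=0.0)
        out = simulate_cycle(p, n_cycles=1, initial={"O2": 0.1})
        k = p.strip_rate + p.dilution_rate
        expected = 0.1 * np.exp(-k * out.time)
        assert np.allclose(out.states["O2"], expected, atol=1e-6)

    def test_electron_balance_consistent_with_trajectories(self, default_run):
        """Delta-e equals donors-supplied minus acceptors-consumed,
        recomputed independently from the concentration trajectories."""
        from scipy.integrate import cumulative_trapezoid

        out = default_run
        p = out.params
        t = out.time

        def cumtrapz(rate):
            return cumulative_trapezoid(rate, t, initial=0.0)

        supplied = cumtrapz(
            p.dilution_rate
            * (24.0 * p.feed_glucose + 8.0 * p.feed_acetate + 14.0 * p.feed_aa)
            * np.ones_like(t)
        )
        # acceptors: O2 consumed = inputs - outputs - inventory change.
        # The pulse is piecewise constant (grid points sit on the breaks),
        # so a left-endpoint sum integrates it exactly.
        o2 = out.states["O2"]
        gas = out.states["O2_gas"]
        pulses = np.where(
            (t % p.period) < p.pulse_duration, p.pulse_mmol / p.pulse_duration, 0.0
        )
        inflow = np.concatenate([[0.0], np.cumsum(np.diff(t) * pulses[:-1])])
        outflow = cumtrapz(p.vent_rate * gas + p.dilution_rate * o2)
        o2_consumed = inflow - outflow - (o2 + gas - o2[0] - gas[0])
        # NOx reduced: feed - washout - inventory change, per pathway step
        no3, no2, n2o = out.states["NO3"], out.states["NO2"], out.states["N2O"]
        no3_red = cumtrapz(p.dilution_rate * (p.feed_no3 - no3)) - (no3 - no3[0])
        no2_red = (
            cumtrapz(p.dilution_rate * (p.feed_no2 - no2))
            + no3_red
            - (no2 - no2[0])
        )
        n2o_red = (
            no2_red / 2.0 - (n2o - n2o[0]) - cumtrapz(p.dilution_rate * n2o)
        )
        accepted = 4.0 * o2_consumed + 2.0 * (no3_red + no2_red + n2o_red)
        delta_e = supplied - accepted
        # reconstruction vs integrator, absolute tolerance on a signal of
        # magnitude ~40 mmol-e/l
        assert np.allclose(delta_e, out.delta_e, atol=0.2)
        assert out.delta_e[-1] > 0  # donors outpace acceptors over a cycle

    def test_integrator_parameters_validated(self):
        with pytest.raises(SimulationError):
            ChemostatParams(period=10.0)
        with pytest.raises(SimulationError):
            ChemostatParams(kla=-1.0)


class TestGenerateObservations:
    def test_noise_free_is_exact_stoichiometry(self, network):
        truth = {"e": 1.5}
        obs = generate_observations(network, truth)
        rxn = network.get("e")
        for cid, coef in rxn.net_stoich.items():
            if cid == "biomass":
                assert obs.biomass_rate == pytest.approx(1.5 * coef)
            else:
                assert obs.rates[cid] == pytest.approx(1.5 * coef)

    def test_seeded_noise_reproducible(self, network):
        truth = {"e": 1.0, "r": 2.0}
        a = generate_observations(network, truth, noise_sd=0.05, seed=11)
        b = generate_observations(network, truth, noise_sd=0.05, seed=11)
        c = generate_observations(network, truth, noise_sd=0.05, seed=12)
        assert a.rates == b.rates
        assert a.rates != c.rates

    def test_negative_rates_rejected(self, network):
        with pytest.raises(SimulationError):
            generate_observations(network, {"e": -1.0})

    def test_unknown_reaction_rejected(self, network):
        with pytest.raises(SimulationError, match="zz"):
            generate_observations(network, {"zz": 1.0})


class TestGenerateCounts:
    def _setup(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        orfs = [f"orf{i}" for i in range(n)]
        activities = {o: float(rng.lognormal(0.0, 0.8)) for o in orfs}
        lengths = {o: float(rng.integers(300, 3000)) for o in orfs}
        bins = {o: ("A" if i < n // 2 else "B") for i, o in enumerate(orfs)}
        return activities, lengths, bins

    def test_uniform_activities_counts_proportional_to_length(self):
        acts = {f"o{i}": 1.0 for i in range(20)}
        lens = {f"o{i}": 500.0 * (1 + i % 4) for i in range(20)}
        bins = {f"o{i}": "A" for i in range(20)}
        depth = 1_000_000
        counts = generate_counts(acts, lens, bins, depth, seed=3)
        total_len = sum(lens.values())
        for _, row in counts.iterrows():
            expected = depth * row["length"] / total_len
            # ~6 sigma multinomial slack
            assert abs(row["count"] - expected) < 6 * math.sqrt(expected)

    def test_activity_recovery_at_high_depth(self):
        """Activities recovered by the normalization converge to the truth:
        RMSE < 0.05 at depth 1e6."""
        activities, lengths, bins = self._setup()
        counts = generate_counts(activities, lengths, bins, 1_000_000, seed=21)
        recovered = transcriptional_activity(counts).set_index("orf_id")["activity"]
        # the generator's activities are arbitrary-scale; normalize per bin
        errs = []
        for bin_id in set(bins.values()):
            orfs = [o for o in activities if bins[o] == bin_id]
            w = np.array([lengths[o] for o in orfs])
            a = np.array([activities[o] for o in orfs])
            truth = a / (np.sum(w * a) / np.sum(w))
            errs.extend(recovered[orfs].to_numpy() - truth)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.05

    def test_depth_zero_rejected(self):
        activities, lengths, bins = self._setup(n=4)
        with pytest.raises(SimulationError, match="depth"):
            generate_counts(activities, lengths, bins, 0)

    def test_seeded_reproducibility(self):
        activities, lengths, bins = self._setup(n=10)
        a = generate_counts(activities, lengths, bins, 1000, seed=5)
        b = generate_counts(activities, lengths, bins, 1000, seed=5)
        assert a.equals(b)

    def test_mismatched_keys_rejected(self):
        with pytest.raises(SimulationError):
            generate_counts({"a": 1.0}, {"b": 100.0}, {"a": "A"}, 10)
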