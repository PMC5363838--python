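"""Communal-metabolism flux fitting.

The model: the community's net conversions are a non-negative combination
of the balanced metabolic reactions of a scenario,

    observed ~ S v,   v >= 0,

with S the net stoichiometric matrix restricted to the measured
compounds.  The fit solves

    min || W (S v - observed) ||_2^2  +  eps ||v||_2^2,   v >= 0,

by non-negative least squares; W holds relative weights (1/|observed|,
with a floor for compounds observed at zero net conversion, i.e. the
cross-fed intermediates) and the small ridge term eps breaks ties in
underdetermined networks so the reported solution is the minimal-norm
member of the optimal family.

Usage follows the Model/Results pattern::

    model = CommunityModel(network, observed, scenario="unsorted")
    res = model.fit()
    print(res.summary())
    res.community_yield, res.abundances

``scenario_compare`` fits the thermodynamically sorted (reactions a-c)
and unsorted/braided (d-v) scenarios side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .network import Network
from .stoichiometry import ConversionVector, MetabolicReaction, StoichiometryError


class FitError(ValueError):
    pass


class CommunityModel:
    """Non-negative flux model of communal metabolism.

    Parameters
    ----------
    network : Network
        Balanced reaction network (provides net stoichiometries, population
        bins and per-reaction yields).
    observed : ConversionVector
        Measured net conversion rates (mmol l-1 day-1).  Compounds absent
        from ``observed.rates`` are treated as free (unmeasured) outputs.
    scenario : str
        "sorted", "unsorted" or "both"; selects the allowed reactions.
    include_growth : bool
        If True, the observed biomass production rate is fitted as a
        target; if False growth is a free output and the community yield
        is purely a model prediction.
    weights : mapping, optional
        Compound -> weight; defaults to relative weighting 1/|observed|
        with a floor of 1% of the largest observed magnitude.
    regularization : float
        Ridge penalty eps (default 1e-8).
    """

    def __init__(
        self,
        network: Network,
        observed: ConversionVector,
        scenario: str = "unsorted",
        include_growth: bool = True,
        weights: Optional[Mapping[str, float]] = None,
        regularization: float = 1e-8,
    ):
        self.network = network
        self.observed = observed
        self.scenario = scenario
        self.include_growth = include_growth
        self.regularization = regularization
        self.reactions: List[MetabolicReaction] = network.subset(scenario)
        if not self.reactions:
            raise FitError(f"scenario {scenario!r} allows no reactions")

        self.constrained = list(observed.rates)
        if include_growth:
            if "biomass" not in self.constrained:
                self.constrained.append("biomass")
        elif "biomass" in self.constrained:
            self.constrained.remove("biomass")
        self._target = np.array(
            [
                observed.biomass_rate if cid == "biomass" else observed.rates.get(cid, 0.0)
                for cid in self.constrained
            ]
        )
        self._S = network.stoich_matrix(self.constrained, self.reactions)
        if weights is not None:
            self._w = np.array([weights.get(cid, 1.0) for cid in self.constrained])
        else:
            scale = np.max(np.abs(self._target)) if len(self._target) else 0.0
            if scale == 0.0:
                self._w = np.ones_like(self._target)
            else:
                self._w = 1.0 / np.maximum(np.abs(self._target), 0.01 * scale)

    def fit(self) -> "CommunityFitResults":
        """Solve the weighted, ridge-regularized NNLS problem."""
        if np.all(self._target == 0.0):
            warnings.warn("all observed conversions are zero; returning zero rates")
            rates = np.zeros(len(self.reactions))
            return CommunityFitResults(self, rates)
        A = self._w[:, None] * self._S
        b = self._w * self._target
        if self.regularization > 0:
            ridge = np.sqrt(self.regularization) * np.eye(len(self.reactions))
            A = np.vstack([A, ridge])
            b = np.concatenate([b, np.zeros(len(self.reactions))])
        rates, _ = optimize.nnls(A, b, maxiter=10 * max(A.shape))
        return CommunityFitResults(self, rates)


@dataclass
class CommunityFitResults:
    """Fitted reaction rates and derived community quantities.

    Attributes
    ----------
    rates : dict
        Reaction id -> fitted rate (mmol l-1 day-1, >= 0).
    modeled : ConversionVector
        S v over *all* network compounds, including the free outputs.
    residual_norm : float
        Weighted L2 norm of the misfit on the constrained compounds.
    population_growth : dict
        Bin -> biomass production (C-mmol l-1 day-1); storage excluded.
    abundances : dict
        Bin -> fraction of total growth.
    community_yield : float
        C-mol biomass produced per C-mol organic substrate consumed.
    """

    model: CommunityModel
    _x: np.ndarray

    def __post_init__(self) -> None:
        self.rates: Dict[str, float] = {
            r.id: float(v) for r, v in zip(self.model.reactions, self._x)
        }
        all_compounds = self.model.network.compound_ids(self.model.reactions)
        S_full = self.model.network.stoich_matrix(all_compounds, self.model.reactions)
        flux = S_full @ self._x
        biomass = 0.0
        modeled_rates: Dict[str, float] = {}
        for cid, f in zip(all_compounds, flux):
            if cid == "biomass":
                biomass = float(f)
            else:
                modeled_rates[cid] = float(f)
        self.modeled = ConversionVector(modeled_rates, biomass_rate=biomass)
        misfit = self.model._w * (self.model._S @ self._x - self.model._target)
        self.residual_norm = float(np.linalg.norm(misfit))

    # -- derived quantities -------------------------------------------------

    @property
    def population_growth(self) -> Dict[str, float]:
        growth: Dict[str, float] = {}
        for rxn, v in zip(self.model.reactions, self._x):
            if rxn.population == "storage":
                continue
            coef = rxn.net_stoich.get("biomass", 0.0)
            if coef:
                growth[rxn.population] = growth.get(rxn.population, 0.0) + v * coef
        return growth

    @property
    def abundances(self) -> Dict[str, float]:
        return population_abundances(self)

    @property
    def community_yield(self) -> float:
        return community_yield(self)

    @property
    def storage_rate(self) -> float:
        """Net carbon stored as glucan (C-mmol l-1 day-1)."""
        reg = self.model.network.registry
        rate = self.modeled.rates.get("storage", 0.0)
        return rate * reg["storage"].carbon_count

    def carbon_consumed(self) -> float:
        """Net organic carbon consumption (C-mmol l-1 day-1); storage and
        CO2 are not organic substrates."""
        reg = self.model.network.registry
        total = 0.0
        for cid, rate in self.modeled.rates.items():
            if cid in ("CO2", "storage"):
                continue
            c = reg[cid].carbon_count
            if c > 0 and rate < -1e-12:
                total += -rate * c
        return total

    def summary(self) -> str:
        lines = [
            "Communal metabolism fit",
            "=" * 55,
            f"scenario:        {self.model.scenario}",
            f"reactions:       {len(self.model.reactions)}",
            f"residual norm:   {self.residual_norm:.4g} (weighted)",
            f"biomass growth:  {self.modeled.biomass_rate:.3f} C-mmol/l/day",
            f"carbon consumed: {self.carbon_consumed():.3f} C-mmol/l/day",
            f"community yield: {self.community_yield:.3f} C-mol/C-mol",
            f"storage flux:    {self.storage_rate:.3f} C-mmol/l/day",
            "",
            "population abundances (fraction of growth):",
        ]
        for pop, frac in sorted(self.abundances.items()):
            lines.append(f"  {pop:8s} {frac:6.3f}")
        lines.append("")
        lines.append("reaction rates (mmol/l/day):")
        for rxn in self.model.reactions:
            v = self.rates[rxn.id]
            if v > 1e-9:
                lines.append(
                    f"  {rxn.id:3s} {rxn.population:8s} {v:10.4f}  Y={rxn.yield_Y:.3f}"
                )
        return "\n".join(lines)


def community_yield(fit: CommunityFitResults) -> float:
    """C-mol biomass produced per C-mol organic substrate consumed."""
    consumed = fit.carbon_consumed()
    if consumed <= 0:
        raise FitError("no net carbon consumption; yield undefined")
    return fit.modeled.biomass_rate / consumed


def population_abundances(fit: CommunityFitResults) -> Dict[str, float]:
    """Relative abundance of each population bin, proportional to its
    biomass production rate (storage flux excluded)."""
    growth = fit.population_growth
    total = sum(growth.values())
    if total <= 0:
        raise FitError("all population growth is zero; abundances undefined")
    return {pop: g / total for pop, g in growth.items()}


def fit_rates(
    network: Network,
    observed: ConversionVector,
    scenario: str = "unsorted",
    weights: Optional[Mapping[str, float]] = None,
    regularization: float = 1e-8,
    include_growth: bool = True,
) -> CommunityFitResults:
    """Functional wrapper around CommunityModel(...).fit()."""
    return CommunityModel(
        network, observed, scenario=scenario, include_growth=include_growth,
        weights=weights, regularization=regularization,
    ).fit()


@dataclass
class ScenarioComparison:
    sorted_fit: CommunityFitResults
    unsorted_fit: CommunityFitResults

    @property
    def better(self) -> str:
        """Scenario with the lower weighted residual."""
        return (
            "sorted"
            if self.sorted_fit.residual_norm < self.unsorted_fit.residual_norm
            else "unsorted"
        )

    def summary(self) -> str:
        rows = [
            ("residual norm", "residual_norm", "{:.4g}"),
            ("community yield", "community_yield", "{:.3f}"),
            ("biomass growth", None, "{:.3f}"),
        ]
        lines = [
            "Scenario comparison (sorted = redox tower, unsorted = braided)",
            "=" * 62,
            f"{'':22s}{'sorted':>12s}{'unsorted':>12s}",
        ]
        for label, attr, fmt in rows:
            if attr is None:
                sv = self.sorted_fit.modeled.biomass_rate
                uv = self.unsorted_fit.modeled.biomass_rate
            else:
                sv = getattr(self.sorted_fit, attr)
                uv = getattr(self.unsorted_fit, attr)
            lines.append(f"{label:22s}{fmt.format(sv):>12s}{fmt.format(uv):>12s}")
        pops = sorted(
            set(self.sorted_fit.abundances) | set(self.unsorted_fit.abundances)
        )
        lines.append("abundances:")
        for pop in pops:
            sv = self.sorted_fit.abundances.get(pop, 0.0)
            uv = self.unsorted_fit.abundances.get(pop, 0.0)
            lines.append(f"  {pop:20s}{sv:12.3f}{uv:12.3f}")
        lines.append(f"better match (lower residual): {self.better}")
        return "\n".join(lines)


def scenario_compare(
    network: Network,
    observed: ConversionVector,
    include_growth: bool = True,
    **kwargs,
) -> ScenarioComparison:
    """Fit the sorted and unsorted scenarios to the same observations."""
    return ScenarioComparison(
        sorted_fit=fit_rates(
            network, observed, "sorted", include_growth=include_growth, **kwargs
        ),
        unsorted_fit=fit_rates(
            network, observed, "unsorted", include_growth=include_growth, **kwargs
        ),
    )
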