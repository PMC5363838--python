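"""Compounds, half-reactions and conservation-law bookkeeping.

Everything downstream (yield prediction, community flux fitting, the
chemostat simulator) is built on the types defined here.  Conventions:

* Stoichiometric coefficients are negative for consumption, positive for
  production.
* Elemental composition covers C, H, O, N, S plus net charge; balance is
  enforced to an absolute tolerance of 1e-9 per element.
* Degree of reduction uses the conventional heterotrophic valences
  (C=+4, H=+1, O=-2, N=-3 i.e. ammonium reference, S=+6 i.e. sulfate
  reference) with a charge correction.
* Flux units are mmol l-1 day-1 throughout; biomass flux is C-mmol l-1 day-1.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

ELEMENTS = ("C", "H", "O", "N", "S")

#: Electron bookkeeping valences (degree-of-reduction convention,
#: N referenced to ammonium, S to sulfate).
VALENCE = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "S": 6.0}

BALANCE_TOL = 1e-9

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)([0-9]*\.?[0-9]*)")


class StoichiometryError(ValueError):
    """Raised for malformed compounds or unbalanced reactions."""


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse an empirical formula string like ``"C6H12O6"`` or ``"CH1.8O0.5N0.2"``.

    Fractional subscripts are allowed (C-mol formulas for biomass, storage
    polymer and substrate mixtures).
    """
    if not formula:
        return {}
    out: Dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise StoichiometryError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(1):
            continue
        elem, num = m.group(1), m.group(2)
        if elem not in ELEMENTS:
            raise StoichiometryError(f"unsupported element {elem!r} in {formula!r}")
        out[elem] = out.get(elem, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise StoichiometryError(f"cannot parse formula {formula!r}")
    return out


def format_formula(comp: Mapping[str, float]) -> str:
    parts = []
    for elem in ELEMENTS:
        n = comp.get(elem, 0.0)
        if n == 0:
            continue
        if abs(n - round(n)) < 1e-12:
            ns = "" if round(n) == 1 else str(int(round(n)))
        else:
            ns = repr(n)  # full precision, so formulas round-trip
        parts.append(f"{elem}{ns}")
    return "".join(parts)


@dataclass(frozen=True)
class Compound:
    """A chemical species with elemental composition and pH-7 formation energy.

    Parameters
    ----------
    id : str
        Short name used in reaction maps ("glucose", "NO2-", ...).
    formula : mapping
        Element -> atom count (possibly fractional for C-mol formulas).
    charge : float
        Net charge of the dominant species at pH 7.
    dGf0_prime : float or None
        Standard Gibbs energy of formation at 25 degC, pH 7, kJ/mol.
        ``None`` marks compounds excluded from energy calculations.
    roles : tuple of str
        Free-form tags: substrate / product / electron-acceptor / biomass /
        storage.
    mean_chain_length : float or None
        For mixture pseudo-compounds expressed per C-mol: the mole-weighted
        mean carbon number of the underlying molecules (used by the
        dissipation correlation, which needs the chain length of the actual
        substrate, not of the 1-carbon pseudo-formula).
    """

    id: str
    formula: Mapping[str, float]
    charge: float = 0.0
    dGf0_prime: Optional[float] = None
    roles: Tuple[str, ...] = ()
    mean_chain_length: Optional[float] = None
    note: str = ""

    @property
    def carbon_count(self) -> float:
        return self.formula.get("C", 0.0)

    @property
    def chain_length(self) -> float:
        """Carbon chain length used by the yield correlation."""
        if self.mean_chain_length is not None:
            return self.mean_chain_length
        return self.carbon_count

    def electron_content(self) -> float:
        """Available electrons per formula unit (valence bookkeeping).

        Negative values mean the compound is an electron acceptor relative
        to the reference set (CO2, H2O, NH4+, SO4 2-).
        """
        e = -self.charge
        for elem, n in self.formula.items():
            e += VALENCE[elem] * n
        return e

    def __post_init__(self) -> None:
        for elem in self.formula:
            if elem not in ELEMENTS:
                raise StoichiometryError(f"{self.id}: unsupported element {elem}")
        if self.dGf0_prime is not None and not math.isfinite(self.dGf0_prime):
            raise StoichiometryError(f"{self.id}: dGf0' must be finite")


def degree_of_reduction(compound: Compound) -> float:
    """Degree of reduction (gamma): available electrons per C-mol.

    gamma = (4 C + H - 2 O - 3 N + 6 S - charge) / C with N referenced to
    ammonium and S to sulfate.  Undefined for carbon-free compounds.

    >>> degree_of_reduction(Compound("glucose", parse_formula("C6H12O6")))
    4.0
    """
    c = compound.carbon_count
    if c < 1e-12:
        raise StoichiometryError(
            f"gamma undefined for C0 compounds (got {compound.id})"
        )
    return compound.electron_content() / c


class Registry(dict):
    """Compound registry: id -> Compound, with a helpful KeyError."""

    def __missing__(self, key):
        raise StoichiometryError(f"unknown compound id {key!r}")

    def add(self, compound: Compound) -> Compound:
        self[compound.id] = compound
        return compound


@dataclass
class HalfReaction:
    """One half of a metabolic reaction.

    ``stoich`` maps compound id -> coefficient (negative = consumed).
    ``kind`` is "catabolic" or "anabolic".
    """

    stoich: Dict[str, float]
    kind: str = "catabolic"

    def scaled(self, factor: float) -> "HalfReaction":
        return HalfReaction(
            {c: k * factor for c, k in self.stoich.items()}, kind=self.kind
        )

    def __add__(self, other: "HalfReaction") -> "HalfReaction":
        out = dict(self.stoich)
        for c, k in other.stoich.items():
            out[c] = out.get(c, 0.0) + k
        return HalfReaction(
            {c: k for c, k in out.items() if abs(k) > 1e-15}, kind="net"
        )


@dataclass
class MetabolicReaction:
    """Catabolic + anabolic halves coupled into one balanced net reaction.

    ``lambda_cat`` is the number of catabolic formula units coupled to the
    anabolic half (which is normalized to produce 1 C-mol biomass);
    ``net_stoich = anabolic + lambda_cat * catabolic``.  ``yield_Y`` is
    C-mol biomass formed per C-mol organic substrate consumed by the net
    reaction.  Reactions with no anabolic half (e.g. storage polymer
    formation) carry ``lambda_cat = 1`` and ``yield_Y = 0``.
    """

    id: str
    catabolic: HalfReaction
    anabolic: Optional[HalfReaction]
    lambda_cat: float
    population: str = ""
    scenario: str = "both"
    yield_Y: float = 0.0
    chain: Optional[str] = None
    note: str = ""
    net_stoich: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.net_stoich:
            net = self.catabolic.scaled(self.lambda_cat)
            if self.anabolic is not None:
                net = HalfReaction(self.anabolic.stoich, "anabolic") + net
            self.net_stoich = net.stoich


def _totals(
    stoich: Mapping[str, float], registry: Mapping[str, Compound]
) -> Dict[str, float]:
    tot = {elem: 0.0 for elem in ELEMENTS}
    tot["charge"] = 0.0
    for cid, coef in stoich.items():
        comp = registry[cid]
        for elem, n in comp.formula.items():
            tot[elem] += coef * n
        tot["charge"] += coef * comp.charge
    return tot


def check_balance(
    reaction, registry: Mapping[str, Compound], tol: float = BALANCE_TOL
) -> List[Tuple[str, float]]:
    """Element and charge balance violations of a reaction.

    Accepts a HalfReaction, a MetabolicReaction (its net stoichiometry is
    checked) or a bare stoichiometry mapping.  Returns a list of
    (element, imbalance) pairs; an empty list means balanced within ``tol``.
    """
    if isinstance(reaction, MetabolicReaction):
        stoich = reaction.net_stoich
    elif isinstance(reaction, HalfReaction):
        stoich = reaction.stoich
    else:
        stoich = reaction
    tot = _totals(stoich, registry)
    return [(k, v) for k, v in tot.items() if abs(v) > tol]


@dataclass
class Medium:
    """Feed composition (mM) and dilution rate (per day) of the chemostat."""

    concentrations: Dict[str, float]
    dilution_rate: float

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise StoichiometryError("dilution_rate must be positive")
        for cid, conc in self.concentrations.items():
            if conc < 0:
                raise StoichiometryError(f"negative concentration for {cid}")


@dataclass
class ConversionVector:
    """Net conversion rates per compound (mmol l-1 day-1, negative = consumed)
    plus a biomass production rate (C-mmol l-1 day-1)."""

    rates: Dict[str, float]
    biomass_rate: float = 0.0

    def __post_init__(self) -> None:
        for cid, r in self.rates.items():
            if not math.isfinite(r):
                raise StoichiometryError(f"non-finite rate for {cid}")
        if not math.isfinite(self.biomass_rate):
            raise StoichiometryError("non-finite biomass rate")


def carbon_fractions(
    medium: Medium,
    registry: Mapping[str, Compound],
    grouping: Optional[Mapping[str, str]] = None,
) -> Dict[str, float]:
    """Fraction of supplied carbon (C-mol basis) per compound group.

    ``grouping`` maps compound id -> group label; compounds not listed form
    their own group.  Fractions sum to 1.
    """
    totals: Dict[str, float] = {}
    for cid, conc in medium.concentrations.items():
        c = registry[cid].carbon_count
        if c <= 0 or conc <= 0:
            continue
        group = grouping.get(cid, cid) if grouping else cid
        totals[group] = totals.get(group, 0.0) + conc * c
    grand = sum(totals.values())
    if grand <= 0:
        raise StoichiometryError("medium contains no carbon")
    return {g: v / grand for g, v in totals.items()}


def supply_rates(medium: Medium) -> ConversionVector:
    """Medium supply fluxes: concentration x dilution rate, mmol l-1 day-1."""
    return ConversionVector(
        {cid: conc * medium.dilution_rate for cid, conc in medium.concentrations.items()}
    )


def generations(duration_days: float, dilution_rate: float) -> float:
    """Number of microbial generations over a chemostat run.

    At steady state the specific growth rate equals the dilution rate, so
    generations = duration x D / ln 2.
    """
    if duration_days <= 0 or dilution_rate <= 0:
        raise StoichiometryError("duration and dilution rate must be positive")
    return duration_days * dilution_rate / math.log(2)


def mixture_compound(
    cid: str,
    components: Mapping[str, float],
    registry: Mapping[str, Compound],
    roles: Tuple[str, ...] = ("substrate",),
) -> Compound:
    """Build a per-C-mol pseudo-compound from a mixture of carbon compounds.

    ``components`` maps compound id -> relative molar amount (e.g. medium
    concentrations).  The result carries the C-mol-weighted elemental
    composition per carbon, the amount-weighted formation energy per C-mol,
    and the mole-weighted mean chain length for the yield correlation.
    """
    total_c = 0.0
    total_mol = 0.0
    elems = {e: 0.0 for e in ELEMENTS}
    charge = 0.0
    dg = 0.0
    for comp_id, amount in components.items():
        comp = registry[comp_id]
        if comp.carbon_count <= 0:
            raise StoichiometryError(f"mixture component {comp_id} has no carbon")
        if comp.dGf0_prime is None:
            raise StoichiometryError(f"mixture component {comp_id} lacks dGf0'")
        total_c += amount * comp.carbon_count
        total_mol += amount
        for e in ELEMENTS:
            elems[e] += amount * comp.formula.get(e, 0.0)
        charge += amount * comp.charge
        dg += amount * comp.dGf0_prime
    if total_c <= 0:
        raise StoichiometryError("mixture contains no carbon")
    formula = {e: n / total_c for e, n in elems.items() if abs(n) > 1e-15}
    return Compound(
        id=cid,
        formula=formula,
        charge=charge / total_c,
        dGf0_prime=dg / total_c,
        roles=roles,
        mean_chain_length=total_c / total_mol,
        note="per-C-mol mixture pseudo-compound",
    )
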