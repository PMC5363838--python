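"""Thermodynamic biomass-yield prediction.

Each metabolic reaction is the sum of a catabolic half (energy generation)
and an anabolic half (assimilation of a carbon substrate into biomass,
normalized to 1 C-mol).  The two are coupled by requiring that the energy
delivered by catabolism covers the Gibbs energy dissipated during
biosynthesis:

    lambda = (D_diss + dG_an) / (eta * (-dG_cat))

where D_diss is the empirical Gibbs-energy dissipation per C-mol biomass
(a correlation in the carbon chain length C and degree of reduction gamma
of the substrate), dG_an the Gibbs energy of the anabolic half per C-mol
biomass, dG_cat the Gibbs energy of the catabolic half per formula unit,
and eta the fraction of the catabolic energy the cell actually conserves.

For fermentative (substrate-level) catabolism eta = 1.  For respiratory
catabolism the package takes eta from the respiratory-chain efficiency
(charges x PMF over the redox span, see :mod:`tidemet.bioenergetics`):
a canonical proton-pumping chain conserves ~79% of the NADH -> O2 span,
a bd-oxidase-terminated chain ~32%, and a denitrification chain ~42% of
the NADH -> NO2-/N2 span.  This treatment makes denitrifying and
bd-terminated growth markedly less efficient than canonical aerobic
growth, as required by the observed community energetics.

The biomass yield is Y = C-mol biomass / C-mol organic substrate consumed
by the balanced net reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .bioenergetics import RespiratoryChain, chain_efficiency
from .stoichiometry import (
    BALANCE_TOL,
    ELEMENTS,
    Compound,
    HalfReaction,
    MetabolicReaction,
    StoichiometryError,
    check_balance,
    degree_of_reduction,
    mixture_compound,
)


class YieldError(ValueError):
    pass


@dataclass
class EnergyContext:
    """Thermodynamic context for yield calculations.

    ``dGf0_table`` maps compound id -> Compound (with dGf0' filled in);
    ``dissipation_override`` replaces the dissipation correlation with a
    fixed value (kJ per C-mol biomass) when set.
    """

    dGf0_table: Mapping[str, Compound]
    temperature: float = 298.15
    dissipation_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise YieldError("temperature must be positive")


@dataclass
class YieldEstimate:
    """Outcome of coupling a catabolic and an anabolic half."""

    dissipation: float  # kJ per C-mol biomass
    dG_cat: float  # kJ per catabolic formula unit
    dG_an: float  # kJ per C-mol biomass
    lambda_cat: float
    Y: float
    efficiency: float = 1.0


def dissipation_correlation(carbon_count: float, gamma: float) -> float:
    """Gibbs-energy dissipation per C-mol biomass for heterotrophic growth.

    D = 200 + 18 (6 - C)^1.8 + exp[((3.8 - gamma)^2)^0.16 (3.6 + 0.4 C)]
    in kJ per C-mol biomass.  Dissipation grows steeply for short-chain
    (C1, C2) and unusually oxidized or reduced substrates, reflecting the
    extra biosynthetic work they impose.
    """
    if carbon_count < 1:
        raise YieldError("dissipation correlation requires C >= 1")
    if gamma <= 0:
        raise YieldError("dissipation correlation requires gamma > 0")
    return (
        200.0
        + 18.0 * abs(6.0 - carbon_count) ** 1.8
        + math.exp(((3.8 - gamma) ** 2) ** 0.16 * (3.6 + 0.4 * carbon_count))
    )


def reaction_gibbs(half: Union[HalfReaction, Mapping[str, float]], ctx: EnergyContext) -> float:
    """Gibbs energy of a (half-)reaction: sum of coefficient x dGf0'."""
    stoich = half.stoich if isinstance(half, HalfReaction) else half
    dg = 0.0
    for cid, coef in stoich.items():
        try:
            comp = ctx.dGf0_table[cid]
        except (KeyError, StoichiometryError):
            raise YieldError(f"no dGf0' entry for compound {cid!r}") from None
        if comp.dGf0_prime is None:
            raise YieldError(f"compound {cid!r} has no dGf0' value")
        dg += coef * comp.dGf0_prime
    return dg


# ---------------------------------------------------------------------------
# Half-reaction construction
#
# Free coefficients are solved from element/charge conservation.  A "column"
# is either a compound id or a tuple of (id, weight) pairs that move together
# (used for fixed product ratios and for substrate mixtures).

Column = Union[str, Sequence[Tuple[str, float]]]


def _column_vector(col: Column, registry: Mapping[str, Compound]) -> np.ndarray:
    rows = list(ELEMENTS) + ["charge"]
    vec = np.zeros(len(rows))
    items = [(col, 1.0)] if isinstance(col, str) else list(col)
    for cid, w in items:
        comp = registry[cid]
        for i, elem in enumerate(ELEMENTS):
            vec[i] += w * comp.formula.get(elem, 0.0)
        vec[-1] += w * comp.charge
    return vec


def balance_half(
    fixed: Mapping[str, float],
    free: Sequence[Column],
    registry: Mapping[str, Compound],
    kind: str = "catabolic",
) -> HalfReaction:
    """Complete a half-reaction by solving for the free coefficients.

    ``fixed`` holds the imposed part of the stoichiometry; each entry of
    ``free`` contributes one unknown coefficient.  Raises if conservation
    cannot be satisfied to 1e-9.
    """
    b = np.zeros(len(ELEMENTS) + 1)
    for cid, coef in fixed.items():
        b += coef * _column_vector(cid, registry)
    A = np.column_stack([_column_vector(col, registry) for col in free])
    x, *_ = np.linalg.lstsq(A, -b, rcond=None)
    stoich: Dict[str, float] = dict(fixed)
    for col, coef in zip(free, x):
        items = [(col, 1.0)] if isinstance(col, str) else list(col)
        for cid, w in items:
            stoich[cid] = stoich.get(cid, 0.0) + coef * w
    stoich = {c: k for c, k in stoich.items() if abs(k) > 1e-12}
    half = HalfReaction(stoich, kind=kind)
    violations = check_balance(half, registry)
    if violations:
        raise StoichiometryError(
            f"could not balance half-reaction (fixed={fixed}): {violations}"
        )
    return half


def assimilation_half(
    c_source: Column,
    registry: Mapping[str, Compound],
    n_source: str = "NH4+",
) -> HalfReaction:
    """Anabolic half: assimilate a carbon source into 1 C-mol biomass.

    The substrate coefficient, CO2/H2O/H+ release and the nitrogen-source
    uptake follow from element and charge conservation.  ``c_source`` may
    be a compound id or a weighted mixture.
    """
    free: List[Column] = [c_source, "CO2", "H2O", "H+", n_source]
    src_ids = [c_source] if isinstance(c_source, str) else [c for c, _ in c_source]
    if any(registry[c].formula.get("S", 0) for c in src_ids):
        free.append("HS-")
    return balance_half({"biomass": 1.0}, free, registry, kind="anabolic")


#: Electron-acceptor couples: acceptor -> reduced product (H2O is implicit
#: for O2 and solved by the balancer).
ACCEPTOR_COUPLES = {
    ("O2", None),
    ("NO2-", "N2O"),
    ("NO2-", "N2"),
    ("NO3-", "NO2-"),
    ("NO3-", "N2"),
    ("N2O", "N2"),
    ("SO4--", "HS-"),
}


def respiration_half(
    donor: Column,
    acceptor: str,
    product: Optional[str] = None,
    registry: Mapping[str, Compound] = None,
    oxidized_product: Optional[str] = None,
) -> HalfReaction:
    """Catabolic half: full oxidation of one formula unit of ``donor``
    (organic carbon to CO2, or H2/HS- to their oxidized forms) with the
    given electron acceptor.

    ``product`` is the reduced acceptor species (None for O2 -> H2O);
    ``oxidized_product`` overrides the donor's oxidation product (e.g.
    S0 for incomplete sulfide oxidation).
    """
    if (acceptor, product) not in ACCEPTOR_COUPLES:
        raise YieldError(f"unsupported acceptor couple {acceptor!r} -> {product!r}")
    fixed: Dict[str, float] = {}
    items = [(donor, 1.0)] if isinstance(donor, str) else list(donor)
    donor_n = donor_s = 0.0
    for cid, w in items:
        fixed[cid] = fixed.get(cid, 0.0) - w
        donor_n += w * registry[cid].formula.get("N", 0.0)
        donor_s += w * registry[cid].formula.get("S", 0.0)
    free: List[Column] = [acceptor, "H2O", "H+"]
    if product is not None:
        free.append(product)
    if any(registry[c].formula.get("C", 0) for c, _ in items):
        free.append("CO2")
    n_acceptor = registry[acceptor].formula.get("N", 0) > 0
    if donor_n > 0:
        if n_acceptor:
            # donor nitrogen is released as ammonium; only acceptor N may
            # reach the gaseous products (keeps the balance determined)
            fixed["NH4+"] = fixed.get("NH4+", 0.0) + donor_n
        else:
            free.append("NH4+")
    if donor_s > 0:
        free.append(oxidized_product or "HS-")
    elif oxidized_product:
        fixed[oxidized_product] = fixed.get(oxidized_product, 0.0) + 1.0
    return balance_half(fixed, free, registry, kind="catabolic")


def couple_halves(
    catabolic: HalfReaction,
    anabolic: HalfReaction,
    ctx: EnergyContext,
    substrate: Compound,
    chain: Optional[RespiratoryChain] = None,
    rxn_id: str = "",
    population: str = "",
    scenario: str = "both",
    note: str = "",
) -> Tuple[MetabolicReaction, YieldEstimate]:
    """Couple a catabolic and an anabolic half into a balanced net reaction.

    ``substrate`` is the carbon source of the anabolic half (its chain
    length and degree of reduction set the dissipation); ``chain`` is the
    respiratory chain carrying the catabolic electrons (None for
    substrate-level / fermentative energy conservation).

    Returns the net MetabolicReaction plus the YieldEstimate holding the
    intermediate energies, lambda and Y.
    """
    dG_cat = reaction_gibbs(catabolic, ctx)
    if dG_cat >= 0:
        raise YieldError(f"not a catabolism: dG_cat = {dG_cat:+.1f} kJ >= 0")
    dG_an = reaction_gibbs(anabolic, ctx)
    if ctx.dissipation_override is not None:
        diss = ctx.dissipation_override
    else:
        diss = dissipation_correlation(
            substrate.chain_length, degree_of_reduction(substrate)
        )
    eta = chain_efficiency(chain) if chain is not None else 1.0
    lam = (diss + dG_an) / (eta * -dG_cat)
    if lam < 0:
        raise YieldError(
            "anabolic half releases more energy than is dissipated; "
            "lambda would be negative"
        )
    rxn = MetabolicReaction(
        id=rxn_id,
        catabolic=catabolic,
        anabolic=anabolic,
        lambda_cat=lam,
        population=population,
        scenario=scenario,
        chain=chain.name if chain is not None else None,
        note=note,
    )
    y = yield_from_net(rxn.net_stoich, ctx.dGf0_table)
    rxn.yield_Y = y
    est = YieldEstimate(
        dissipation=diss, dG_cat=dG_cat, dG_an=dG_an, lambda_cat=lam, Y=y,
        efficiency=eta,
    )
    return rxn, est


def yield_from_net(
    net: Mapping[str, float], registry: Mapping[str, Compound]
) -> float:
    """C-mol biomass formed per C-mol organic substrate consumed."""
    biomass_c = 0.0
    consumed_c = 0.0
    for cid, coef in net.items():
        comp = registry[cid]
        if cid == "biomass":
            biomass_c += coef * comp.carbon_count
        elif cid != "CO2" and coef < 0:
            consumed_c += -coef * comp.carbon_count
    if consumed_c <= 0:
        return 0.0
    return biomass_c / consumed_c


def yield_report_rows(
    reactions: Iterable[MetabolicReaction],
    estimates: Mapping[str, YieldEstimate],
) -> List[Dict[str, float]]:
    """Rows for the TSV yield report (id, dG_cat, dG_an, dissipation,
    efficiency, lambda, Y)."""
    rows = []
    for rxn in reactions:
        est = estimates.get(rxn.id)
        if est is None:
            continue
        rows.append(
            {
                "reaction": rxn.id,
                "population": rxn.population,
                "chain": rxn.chain or "-",
                "dG_cat_kJ": round(est.dG_cat, 2),
                "dG_an_kJ": round(est.dG_an, 2),
                "dissipation_kJ_per_CmolX": round(est.dissipation, 2),
                "efficiency": round(est.efficiency, 4),
                "lambda": round(est.lambda_cat, 4),
                "Y_Cmol_per_Cmol": round(est.Y, 4),
            }
        )
    return rows
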