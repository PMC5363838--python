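"""The default communal-metabolism reaction network.

The network is a reconstruction of the chemostat community's metabolism,
constrained by the observed conversions and per-population gene
activities:

* Bins D (*Vibrio*) and F (Firmicutes) ferment the high-quality carbon
  substrates: glucose (and, for F, alanine plus serine) to formate,
  acetate and hydrogen, and the remaining amino acids to succinate.
* Bin A (Rhodobacterales) respires fermentation products aerobically with
  a cbb3-type (canonical) chain and reduces nitrite to nitrous oxide.
* Bins B/C (*Arcobacter*) respire formate and hydrogen aerobically,
  reduce nitrate to nitrite and nitrous oxide to N2, and oxidize sulfide
  incompletely to elemental sulfur.
* Bin E (*Desulfovibrio*) reduces sulfate with hydrogen.
* *Vibrio* additionally eliminates oxygen with a non-proton-pumping
  cytochrome bd oxidase (reaction q), and part of the glucose is stored
  as a glucan without being assigned to any population (reaction v).
* Reactions a-c describe the "thermodynamically sorted" alternative:
  canonical respiration of the complete substrate mixture with oxygen,
  nitrite and nitrate, assigned to bin A.

Reaction letters a-v follow this scheme; the sorted scenario uses a-c,
the unsorted (braided) scenario uses d-v.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .bioenergetics import PRESETS, RespiratoryChain
from .library import AMINO_ACIDS, PAPER_MEDIUM_MM, default_registry, paper_medium
from .stoichiometry import (
    Compound,
    ConversionVector,
    HalfReaction,
    Medium,
    MetabolicReaction,
    Registry,
    StoichiometryError,
    check_balance,
    mixture_compound,
)
from .yields import (
    EnergyContext,
    YieldEstimate,
    assimilation_half,
    balance_half,
    couple_halves,
    respiration_half,
)

#: Average O2 made available to the culture by the pulse regimen
#: (20 ml/min pure O2 for 5 min, twice daily, 25 degC, 1 atm, 2.8 l working
#: volume), mmol l-1 day-1.
O2_SUPPLY_RATE = (
    101325.0 * (20e-3 * 5 * 2 * 1e-3) / (8.314 * 298.15) * 1000.0 / 2.8
)

#: Fermentation-product split of mixed-acid fermentation: equal moles of
#: acetate and formate per fermented substrate.
_AC_FORM = (("acetate", 1.0), ("formate", 1.0))


@dataclass
class Network:
    """A set of balanced metabolic reactions over a compound registry."""

    registry: Registry
    reactions: List[MetabolicReaction]
    estimates: Dict[str, YieldEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise StoichiometryError("duplicate reaction ids in network")

    def get(self, rxn_id: str) -> MetabolicReaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def subset(self, scenario: str) -> List[MetabolicReaction]:
        """Reactions allowed in a scenario ("sorted", "unsorted" or "both")."""
        if scenario == "both":
            return list(self.reactions)
        return [r for r in self.reactions if r.scenario in (scenario, "both")]

    def compound_ids(self, reactions: Optional[Sequence[MetabolicReaction]] = None) -> List[str]:
        seen: Dict[str, None] = {}
        for r in reactions if reactions is not None else self.reactions:
            for cid in r.net_stoich:
                seen.setdefault(cid)
        return list(seen)

    def stoich_matrix(
        self,
        compounds: Sequence[str],
        reactions: Sequence[MetabolicReaction],
    ) -> np.ndarray:
        """Net stoichiometric matrix S (compounds x reactions)."""
        S = np.zeros((len(compounds), len(reactions)))
        idx = {cid: i for i, cid in enumerate(compounds)}
        for j, r in enumerate(reactions):
            for cid, coef in r.net_stoich.items():
                i = idx.get(cid)
                if i is not None:
                    S[i, j] = coef
        return S

    def validate(self) -> Dict[str, List[Tuple[str, float]]]:
        """Balance report: reaction id -> violations (empty if clean)."""
        report = {}
        for r in self.reactions:
            v = check_balance(r, self.registry)
            if v:
                report[r.id] = v
        return report


def medium_mixture(registry: Mapping[str, Compound]) -> Tuple[Compound, List[Tuple[str, float]]]:
    """The complete carbon-substrate mixture of the feed as a per-C-mol
    pseudo-compound plus the matching weighted column (mol per C-mol)."""
    comps = {
        cid: mM
        for cid, mM in PAPER_MEDIUM_MM.items()
        if registry[cid].carbon_count > 0
    }
    mix = mixture_compound("medium-mix", comps, registry)
    total_c = sum(mM * registry[cid].carbon_count for cid, mM in comps.items())
    column = [(cid, mM / total_c) for cid, mM in comps.items()]
    return mix, column


def other_aa_mixture(registry: Mapping[str, Compound]) -> Tuple[Compound, List[Tuple[str, float]]]:
    """Glutamate/aspartate/tyrosine/histidine/methionine (the amino acids not
    fermented to formate+acetate) in feed proportions, per C-mol."""
    comps = {
        aa: PAPER_MEDIUM_MM[aa]
        for aa in ("glutamate", "aspartate", "tyrosine", "histidine", "methionine")
    }
    mix = mixture_compound("otherAA-mix", comps, registry)
    total_c = sum(mM * registry[cid].carbon_count for cid, mM in comps.items())
    column = [(cid, mM / total_c) for cid, mM in comps.items()]
    return mix, column


def ala_ser_mixture(registry: Mapping[str, Compound]) -> Tuple[Compound, List[Tuple[str, float]]]:
    """Alanine + serine in feed proportions (1 : 0.8/1.5), per mol alanine."""
    comps = {"alanine": 1.0, "serine": PAPER_MEDIUM_MM["serine"] / PAPER_MEDIUM_MM["alanine"]}
    mix = mixture_compound("alaSer-mix", comps, registry)
    column = [(cid, amount) for cid, amount in comps.items()]
    return mix, column


def glucose_fermentation_half(registry: Mapping[str, Compound]) -> HalfReaction:
    """Mixed-acid fermentation of glucose to acetate + formate + H2."""
    return balance_half(
        {"glucose": -1.0},
        [_AC_FORM, "H2", "H2O", "H+"],
        registry,
    )


def ala_ser_fermentation_half(registry: Mapping[str, Compound]) -> HalfReaction:
    """Co-fermentation of alanine and serine to acetate + formate + H2.

    Alanine fermentation alone is endergonic at standard conditions; pairing
    it with serine (in feed proportions) keeps the lumped catabolism
    exergonic, mimicking the Stickland-style coupling the fermenters used.
    """
    _, column = ala_ser_mixture(registry)
    fixed = {cid: -w for cid, w in column}
    return balance_half(fixed, [_AC_FORM, "H2", "NH4+", "H2O", "H+"], registry)


def other_aa_fermentation_half(registry: Mapping[str, Compound]) -> HalfReaction:
    """Fermentation of the remaining amino acids to succinate (per C-mol of
    the amino-acid mixture), releasing ammonium, sulfide and a little H2."""
    _, column = other_aa_mixture(registry)
    fixed = {cid: -w for cid, w in column}
    return balance_half(
        fixed, ["succinate", "H2", "NH4+", "HS-", "H2O", "H+"], registry
    )


def storage_half(registry: Mapping[str, Compound]) -> HalfReaction:
    """Polymerization of glucose into a glucan storage polymer."""
    return balance_half({"glucose": -1.0, "storage": 6.0}, ["H2O"], registry)


def default_network(
    pmf: float = 0.18,
    dissipation_override: Optional[float] = None,
) -> Network:
    """Build the default a-v reaction network with thermodynamic yields.

    Every reaction is constructed from balanced catabolic and anabolic
    halves; the coupling factor lambda and the yield Y follow from the
    Gibbs-dissipation correlation and the respiratory-chain efficiencies
    at the given proton motive force.
    """
    reg = default_registry()
    ctx = EnergyContext(dGf0_table=reg, dissipation_override=dissipation_override)
    canonical = PRESETS["canonical"] if pmf == 0.18 else RespiratoryChain(
        "canonical", 10.0, pmf, 1.14
    )
    bd = PRESETS["bd"] if pmf == 0.18 else RespiratoryChain("bd", 4.0, pmf, 1.14)
    denit = PRESETS["denitrification"] if pmf == 0.18 else RespiratoryChain(
        "denitrification", 6.0, pmf, 1.30
    )

    mix, mix_col = medium_mixture(reg)
    aa_mix, aa_col = other_aa_mixture(reg)
    alaser_mix, _ = ala_ser_mixture(reg)
    glucose = reg["glucose"]
    acetate = reg["acetate"]
    formate = reg["formate"]
    succinate = reg["succinate"]

    an_mix = assimilation_half(mix_col, reg)
    an_aa = assimilation_half(aa_col, reg)
    an_glc = assimilation_half("glucose", reg)
    an_ac = assimilation_half("acetate", reg)
    an_form = assimilation_half("formate", reg)
    an_succ = assimilation_half("succinate", reg)
    an_alaser = assimilation_half(
        [(cid, w) for cid, w in ala_ser_mixture(reg)[1]], reg
    )

    # (id, population, scenario, catabolic half, anabolic half, substrate, chain)
    spec_rows = [
        # sorted scenario: canonical respiration of the complete mixture
        ("a", "A", "sorted", respiration_half(mix_col, "O2", None, reg), an_mix, mix, canonical),
        ("b", "A", "sorted", respiration_half(mix_col, "NO2-", "N2", reg), an_mix, mix, denit),
        ("c", "A", "sorted", respiration_half(mix_col, "NO3-", "N2", reg), an_mix, mix, denit),
        # aerobic respiration of fermentation products
        ("d", "A", "unsorted", respiration_half("succinate", "O2", None, reg), an_succ, succinate, canonical),
        ("e", "A", "unsorted", respiration_half("acetate", "O2", None, reg), an_ac, acetate, canonical),
        ("f", "B", "unsorted", respiration_half("formate", "O2", None, reg), an_form, formate, canonical),
        ("g", "B", "unsorted", respiration_half("H2", "O2", None, reg), an_ac, acetate, canonical),
        # denitrification: nitrite -> N2O by Rhodobacterales
        ("h", "A", "unsorted", respiration_half("succinate", "NO2-", "N2O", reg), an_succ, succinate, denit),
        ("i", "A", "unsorted", respiration_half("acetate", "NO2-", "N2O", reg), an_ac, acetate, denit),
        ("j", "A", "unsorted", respiration_half("formate", "NO2-", "N2O", reg), an_form, formate, denit),
        # nitrate -> nitrite and N2O -> N2 by Arcobacter / Vibrio
        ("k", "B", "unsorted", respiration_half("formate", "NO3-", "NO2-", reg), an_form, formate, denit),
        ("l", "D", "unsorted", respiration_half("H2", "NO3-", "NO2-", reg), an_ac, acetate, denit),
        ("m", "B", "unsorted", respiration_half("formate", "N2O", "N2", reg), an_form, formate, denit),
        ("n", "C", "unsorted", respiration_half("H2", "N2O", "N2", reg), an_ac, acetate, denit),
        # sulfur loop: incomplete sulfide oxidation, sulfate reduction
        ("o", "C", "unsorted", respiration_half("HS-", "O2", None, reg, oxidized_product="S0"), an_ac, acetate, canonical),
        ("p", "E", "unsorted", respiration_half("H2", "SO4--", "HS-", reg), an_ac, acetate, None),
        # oxygen elimination via the non-pumping bd oxidase (Vibrio)
        ("q", "D", "unsorted", respiration_half("formate", "O2", None, reg), an_form, formate, bd),
        # fermentations
        ("r", "D", "unsorted", glucose_fermentation_half(reg), an_glc, glucose, None),
        ("s", "F", "unsorted", ala_ser_fermentation_half(reg), an_alaser, alaser_mix, None),
        ("t", "F", "unsorted", other_aa_fermentation_half(reg), an_aa, aa_mix, None),
        ("u", "D", "unsorted", other_aa_fermentation_half(reg), an_aa, aa_mix, None),
    ]

    reactions: List[MetabolicReaction] = []
    estimates: Dict[str, YieldEstimate] = {}
    for rid, pop, scen, cat, an, substrate, chain in spec_rows:
        rxn, est = couple_halves(
            cat, an, ctx, substrate, chain=chain,
            rxn_id=rid, population=pop, scenario=scen,
        )
        reactions.append(rxn)
        estimates[rid] = est

    # v: storage of glucose as glucan, no biomass, no population bin
    storage = MetabolicReaction(
        id="v",
        catabolic=storage_half(reg),
        anabolic=None,
        lambda_cat=1.0,
        population="storage",
        scenario="unsorted",
        yield_Y=0.0,
        note="glucan storage, not assigned to a population",
    )
    reactions.append(storage)

    net = Network(registry=reg, reactions=reactions, estimates=estimates)
    bad = net.validate()
    if bad:
        raise StoichiometryError(f"default network unbalanced: {bad}")
    return net


def paper_conversions(
    medium: Optional[Medium] = None,
    o2_rate: float = O2_SUPPLY_RATE,
    registry: Optional[Mapping[str, Compound]] = None,
) -> ConversionVector:
    """Observed net conversion vector for the steady-state chemostat.

    Built from the feed composition assuming the experimentally reported
    behaviour: complete consumption of all carbon substrates, nitrite and
    nitrate (denitrified to N2), complete consumption of the oxygen made
    available by the pulse regimen, and no net accumulation of the
    cross-fed intermediates (formate, succinate, H2, N2O) over a cycle.
    Sulfate is reduced and re-oxidized to elemental sulfur.  CO2, water,
    protons, ammonium, biomass and storage are left unconstrained.
    """
    medium = medium or paper_medium()
    reg = registry or default_registry()
    supply = {cid: conc * medium.dilution_rate for cid, conc in medium.concentrations.items()}
    rates: Dict[str, float] = {}
    n_to_n2 = 0.0
    s_to_s0 = 0.0
    for cid, rate in supply.items():
        comp = reg[cid]
        if cid in ("NO2-", "NO3-"):
            rates[cid] = -rate
            n_to_n2 += rate * comp.formula.get("N", 0.0)
        elif cid == "SO4--":
            rates[cid] = -rate
            s_to_s0 += rate
        elif comp.carbon_count > 0:
            rates[cid] = -rate
            # methionine sulfur leaves as elemental sulfur via the
            # sulfide -> S0 loop
            s_to_s0 += rate * comp.formula.get("S", 0.0)
    rates["N2"] = n_to_n2 / 2.0
    rates["S0"] = s_to_s0
    rates["O2"] = -o2_rate
    for intermediate in ("formate", "succinate", "H2", "N2O", "HS-"):
        rates.setdefault(intermediate, 0.0)
    return ConversionVector(rates)
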