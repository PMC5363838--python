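"""Default compound library and the chemostat feed medium.

Formation energies are standard transformed Gibbs energies of formation at
25 degC, pH 7 (kJ/mol), taken from the classical biochemical compilations
(Thauer/Jungermann/Decker-style tables).  Values for the aromatic and
sulfur amino acids are approximate (marked in the note field); they carry
a small share of the medium carbon.

Biomass is the standard C-mol formula CH1.8O0.5N0.2 with dGf0' = -67
kJ/C-mol.  The storage polymer is a glycogen-like glucan expressed per
C-mol (CH1.667O0.833).
"""

from __future__ import annotations

from .stoichiometry import Compound, Medium, Registry, parse_formula

#: id -> (formula, charge, dGf0' kJ/mol, roles, note)
_TABLE = [
    ("glucose", "C6H12O6", 0, -917.22, ("substrate",), ""),
    ("acetate", "C2H3O2", -1, -369.41, ("substrate", "product"), ""),
    ("formate", "CHO2", -1, -351.04, ("product",), ""),
    ("succinate", "C4H4O4", -2, -690.23, ("product",), ""),
    ("glutamate", "C5H8NO4", -1, -699.60, ("substrate",), ""),
    ("aspartate", "C4H6NO4", -1, -700.40, ("substrate",), ""),
    ("alanine", "C3H7NO2", 0, -371.54, ("substrate",), ""),
    ("serine", "C3H7NO3", 0, -510.87, ("substrate",), ""),
    ("tyrosine", "C9H11NO3", 0, -370.90, ("substrate",), "approximate"),
    ("histidine", "C6H9N3O2", 0, -226.80, ("substrate",), "approximate"),
    ("methionine", "C5H11NO2S", 0, -502.90, ("substrate",), "approximate"),
    ("CO2", "CO2", 0, -394.36, ("product",), "gaseous"),
    ("H2O", "H2O", 0, -237.18, (), ""),
    ("H+", "H", 1, -39.87, (), "pH 7 convention"),
    ("O2", "O2", 0, 0.0, ("electron-acceptor",), ""),
    ("H2", "H2", 0, 0.0, ("product",), "gaseous"),
    ("N2", "N2", 0, 0.0, ("product",), "gaseous"),
    ("N2O", "N2O", 0, 104.18, ("product",), "gaseous"),
    ("NO3-", "NO3", -1, -111.34, ("electron-acceptor",), ""),
    ("NO2-", "NO2", -1, -32.22, ("electron-acceptor",), ""),
    ("NH4+", "NH4", 1, -79.37, (), ""),
    ("SO4--", "SO4", -2, -744.63, ("electron-acceptor",), ""),
    ("HS-", "HS", -1, 12.05, ("product",), ""),
    ("S0", "S", 0, 0.0, ("product",), "elemental sulfur"),
    ("biomass", {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}, 0, -67.0,
     ("biomass",), "per C-mol"),
    ("storage", {"C": 1.0, "H": 5.0 / 3.0, "O": 5.0 / 6.0}, 0, -110.8,
     ("storage",), "glucosyl unit in a glucan, per C-mol"),
]


def default_registry() -> Registry:
    """Registry with every compound the shipped reaction network uses."""
    reg = Registry()
    for cid, formula, charge, dg, roles, note in _TABLE:
        reg.add(
            Compound(
                id=cid,
                formula=parse_formula(formula) if isinstance(formula, str) else formula,
                charge=float(charge),
                dGf0_prime=dg,
                roles=roles,
                note=note,
            )
        )
    return reg


#: Carbon and nitrogen substrates of the feed medium, mM.
PAPER_MEDIUM_MM = {
    "NO2-": 20.0,
    "NO3-": 1.0,
    "glucose": 6.0,
    "acetate": 3.1,
    "glutamate": 1.1,
    "aspartate": 1.5,
    "alanine": 1.5,
    "serine": 0.80,
    "tyrosine": 0.51,
    "histidine": 0.12,
    "methionine": 0.25,
    "SO4--": 0.01,
}

PAPER_DILUTION_RATE = 0.26  # per day

AMINO_ACIDS = (
    "glutamate",
    "aspartate",
    "alanine",
    "serine",
    "tyrosine",
    "histidine",
    "methionine",
)


def paper_medium() -> Medium:
    """The chemostat feed: 20 mM nitrite, 1 mM nitrate, 6 mM glucose,
    3.1 mM acetate, seven amino acids and 0.01 mM sulfate at D = 0.26/day."""
    return Medium(dict(PAPER_MEDIUM_MM), PAPER_DILUTION_RATE)


def medium_grouping() -> dict:
    """Compound -> group map for carbon-fraction reporting
    (glucose / acetate / amino acids)."""
    grouping = {"glucose": "glucose", "acetate": "acetate"}
    for aa in AMINO_ACIDS:
        grouping[aa] = "amino acids"
    return grouping
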