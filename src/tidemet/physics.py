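"""Diffusion-limited oxygen supply to cells and microaggregates.

A suspended cell (or aggregate, treated as a point sink) of radius r sits
inside a static boundary layer of radius R; outside the layer turbulence
keeps the concentration at the bulk value.  The quasi-steady spherical
diffusion flux toward the object is

    J = 4 pi D (r R / (R - r)) (C_bulk - C_surf)      [mol/s]

with D the diffusion coefficient.  For R -> infinity this reduces to the
classical 4 pi D r dC.  When the object consumes oxygen faster than
diffusion can deliver it, the surface concentration falls to zero and the
bulk concentration at which supply exactly meets demand is

    C_bulk* = uptake / (4 pi D r R / (R - r)).

For a single 1-um cell respiring at the community's maximal specific rate
this threshold lies in the tens of nanomolar; for a microaggregate of N
cells it is roughly N/r times higher, which is why aggregates can be
anoxic inside an oxic bulk liquid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

#: Default diffusion coefficient of O2 in water, m^2/s.
DEFAULT_D = 1e-9
#: Default static boundary-layer radius (Kolmogorov scale), m.
DEFAULT_R_BL = 1e-5
#: 1 uM in mol/m^3.
UM = 1e-3
#: Oxygen concentration at ~10% air saturation (mol/m^3), i.e. ~20 uM.
TEN_PERCENT_AIR_SAT = 20 * UM
#: Default protein content of a 1-um spherical cell (g), back-calculated so
#: that 20 mmol O2/g protein/h corresponds to 25 fmol/cell/day.
DEFAULT_PROTEIN_PER_CELL = 25e-15 / (20e-3 * 24)

SECONDS_PER_DAY = 86400.0


class PhysicsError(ValueError):
    pass


@dataclass(frozen=True)
class DiffusionSetting:
    """Geometry and concentrations for the spherical-diffusion flux.

    All SI: radii in m, concentrations in mol/m^3, D in m^2/s.
    """

    r_obj: float
    C_bulk: float = 0.0
    C_surf: float = 0.0
    D_diff: float = DEFAULT_D
    R_bl: float = DEFAULT_R_BL

    def __post_init__(self) -> None:
        if self.r_obj <= 0:
            raise PhysicsError("object radius must be positive")
        if math.isfinite(self.R_bl) and self.r_obj >= self.R_bl:
            raise PhysicsError(
                f"object radius {self.r_obj} must be smaller than the "
                f"boundary layer radius {self.R_bl}"
            )
        if self.C_bulk < 0 or self.C_surf < 0:
            raise PhysicsError("concentrations must be >= 0")
        if self.D_diff <= 0:
            raise PhysicsError("diffusion coefficient must be positive")


def _geometry_factor(setting: DiffusionSetting) -> float:
    """4 pi D r R/(R-r); with R = inf this is 4 pi D r."""
    if math.isinf(setting.R_bl):
        eff = setting.r_obj
    else:
        eff = setting.r_obj * setting.R_bl / (setting.R_bl - setting.r_obj)
    return 4.0 * math.pi * setting.D_diff * eff


def diffusive_flux(setting: DiffusionSetting) -> float:
    """Oxygen flux toward the object, mol/s (positive toward the object)."""
    return _geometry_factor(setting) * (setting.C_bulk - setting.C_surf)


def depletion_threshold(
    uptake: float,
    r_obj: float,
    D_diff: float = DEFAULT_D,
    R_bl: float = DEFAULT_R_BL,
) -> float:
    """Bulk concentration (mol/m^3) at which diffusion just sustains
    ``uptake`` (mol/s) with a fully depleted surface (C_surf = 0)."""
    if uptake <= 0:
        raise PhysicsError("uptake must be positive")
    setting = DiffusionSetting(r_obj=r_obj, D_diff=D_diff, R_bl=R_bl)
    return uptake / _geometry_factor(setting)


@dataclass(frozen=True)
class UptakeSpec:
    """Conversion between specific and per-cell oxygen uptake.

    specific_rate in mmol O2 per g protein per hour; protein_per_cell in g.
    """

    specific_rate: float
    protein_per_cell: float = DEFAULT_PROTEIN_PER_CELL
    cells: int = 1

    def __post_init__(self) -> None:
        if self.specific_rate < 0 or self.protein_per_cell <= 0 or self.cells < 1:
            raise PhysicsError("uptake spec fields must be positive")


def uptake_per_cell(spec: UptakeSpec) -> float:
    """Per-cell oxygen uptake in fmol/cell/day.

    >>> round(uptake_per_cell(UptakeSpec(20.0)), 6)
    25.0
    """
    mmol_per_day = spec.specific_rate * spec.protein_per_cell * 24.0
    return mmol_per_day * 1e12  # mmol -> fmol


def uptake_mol_per_s(spec: UptakeSpec) -> float:
    """Total uptake of ``cells`` cells, mol/s (for the flux comparison)."""
    fmol_day = uptake_per_cell(spec) * spec.cells
    return fmol_day * 1e-15 / SECONDS_PER_DAY


def aggregate_threshold(
    n_cells: int,
    cell_uptake: float,
    r_aggregate: float,
    D_diff: float = DEFAULT_D,
    R_bl: float = DEFAULT_R_BL,
) -> float:
    """Depletion threshold of an N-cell aggregate treated as a point sink
    with N times the single-cell uptake (mol/s)."""
    return depletion_threshold(n_cells * cell_uptake, r_aggregate, D_diff, R_bl)
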