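"""Synthetic data generation: tidal-cycle chemostat dynamics, observed
conversion vectors with known ground truth, and read-count tables with
known per-gene activities.

The chemostat simulator integrates mass-balance ODEs for the dissolved
species over repeated 12-h "tidal" cycles.  Oxygen is injected as a short
pulse into a recirculated headspace reservoir that exchanges with the
liquid; the community's electron-donor-limited uptake then drains the
reservoir over roughly two hours, reproducing the transient oxygen window
of the experiment.  Fermentation, aerobic respiration, stepwise
denitrification (nitrate -> nitrite -> N2O -> N2) and a small transient
elemental-sulfur loop run in parallel by default ("braided" mode); in
``redox_tower`` mode the anaerobic processes are switched off whenever
oxygen is above a threshold, giving the in-silico contrast between the
two community-assembly hypotheses.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import Network
from .stoichiometry import ConversionVector


class SimulationError(RuntimeError):
    pass


#: O2 injected per pulse, mmol per liquid litre: 20 ml/min x 5 min of pure
#: O2 at 25 degC, 1 atm, for 2.8 l of culture.
PULSE_MMOL_PER_L = 101325.0 * (20e-3 * 5 * 1e-3) / (8.314 * 298.15) * 1000.0 / 2.8


@dataclass(frozen=True)
class ChemostatParams:
    """Parameters of the tidal-cycle chemostat simulation.

    Concentrations in mM, times in hours, first-order rates in 1/h.
    ``vmax_*`` are specific rates per C-mM biomass per hour.
    """

    dilution_rate: float = 0.26 / 24.0  # per hour
    period: float = 12.0  # tidal cycle, h
    pulse_duration: float = 5.0 / 60.0  # h
    pulse_mmol: float = PULSE_MMOL_PER_L  # mmol O2 per liquid litre per pulse

    # feed (mM): glucose, acetate, nitrite, nitrate, amino-acid pool
    feed_glucose: float = 6.0
    feed_acetate: float = 3.1
    feed_no2: float = 20.0
    feed_no3: float = 1.0
    feed_aa: float = 3.48  # other amino acids, mol basis

    # headspace gas exchange
    kla: float = 15.0
    vent_rate: float = 0.15
    headspace: bool = True
    #: equilibrium dissolved O2 per mmol of headspace O2 (mM per mmol/l):
    #: 1.26 mM saturation under pure O2, 0.36 l headspace per liquid litre.
    c_eq_per_gas: float = 1.26 / (0.36 * 40.9)
    strip_rate: float = 0.5  # direct stripping when headspace disabled

    # guild kinetics (per C-mM biomass per hour) and half-saturations (mM)
    vmax_ferm: float = 0.010
    vmax_aa: float = 0.004
    vmax_ac_o2: float = 0.012
    vmax_form_o2: float = 0.020
    vmax_succ_o2: float = 0.003
    vmax_no3: float = 0.002
    vmax_no2: float = 0.012
    vmax_n2o: float = 0.020
    vmax_s0: float = 0.0002
    k_glc: float = 0.05
    k_aa: float = 0.05
    k_ac: float = 0.05
    k_form: float = 0.05
    k_succ: float = 0.02
    k_o2: float = 0.002
    k_no: float = 0.005
    k_don: float = 0.02
    k_s0_decay: float = 0.3

    # growth bookkeeping
    y_resp: float = 0.45  # C-mol biomass per C-mol respired
    y_ferm: float = 0.12  # per C-mol fermented
    biomass0: float = 20.0  # initial biomass, C-mM

    redox_tower: bool = False
    o2_inhibition: float = 0.001  # mM; tower mode switch
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period != 12.0:
            raise SimulationError("tidal period is fixed at 12 h")
        for name in (
            "dilution_rate", "pulse_duration", "pulse_mmol", "kla", "vent_rate",
            "vmax_ferm", "vmax_ac_o2", "vmax_form_o2", "vmax_no2", "vmax_n2o",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


STATE_NAMES = (
    "O2", "O2_gas", "NO3", "NO2", "N2", "N2O",
    "glucose", "acetate", "formate", "succinate", "aa", "S0",
    "biomass", "e_donated", "e_accepted",
)


@dataclass
class SimulationOutput:
    """Trajectories of a tidal-cycle simulation.

    ``frame`` is a tidy DataFrame (time_h + one column per state);
    ``delta_e`` is the cumulative electron balance (electrons supplied by
    the feed donors minus electrons accepted by O2/NOx), mmol-e per litre.
    """

    params: ChemostatParams
    time: np.ndarray
    states: Dict[str, np.ndarray]

    @property
    def frame(self) -> pd.DataFrame:
        data = {"time_h": self.time}
        data.update(self.states)
        return pd.DataFrame(data)

    @property
    def delta_e(self) -> np.ndarray:
        return self.states["e_donated"] - self.states["e_accepted"]

    def o2_window(self, threshold_mM: float = 0.001) -> float:
        """Hours after the end of the last pulse until dissolved O2 first
        falls below ``threshold_mM`` (default 1 uM)."""
        p = self.params
        n_cycles = int(round(self.time[-1] / p.period))
        pulse_end = (n_cycles - 1) * p.period + p.pulse_duration
        mask = self.time >= pulse_end
        t, o2 = self.time[mask], self.states["O2"][mask]
        below = np.nonzero(o2 < threshold_mM)[0]
        if len(below) == 0:
            return float("inf")
        return float(t[below[0]] - pulse_end)


def _monod(c: float, k: float) -> float:
    return max(c, 0.0) / (max(c, 0.0) + k)


def _rhs(t: float, y: np.ndarray, p: ChemostatParams) -> np.ndarray:
    (o2, gas, no3, no2, n2, n2o, glc, ac, form, succ, aa, s0,
     x, _ed, _ea) = y
    D = p.dilution_rate
    in_pulse = (t % p.period) < p.pulse_duration
    pulse = p.pulse_mmol / p.pulse_duration if in_pulse else 0.0

    # in redox-tower mode the anaerobic processes stop above the O2 switch
    tower = 1.0 if (not p.redox_tower or o2 < p.o2_inhibition) else 0.0
    fdon = _monod(form, p.k_don)
    fo2 = _monod(o2, p.k_o2)

    r_ferm = p.vmax_ferm * x * _monod(glc, p.k_glc) * tower
    r_aa = p.vmax_aa * x * _monod(aa, p.k_aa) * tower
    r_ac = p.vmax_ac_o2 * x * _monod(ac, p.k_ac) * fo2
    r_form = p.vmax_form_o2 * x * _monod(form, p.k_form) * fo2
    r_succ = p.vmax_succ_o2 * x * _monod(succ, p.k_succ) * fo2
    r_no3 = p.vmax_no3 * x * _monod(no3, p.k_no) * fdon * tower
    r_no2 = p.vmax_no2 * x * _monod(no2, p.k_no) * fdon * tower
    r_n2o = p.vmax_n2o * x * _monod(n2o, p.k_no) * fdon * tower
    r_s0 = p.vmax_s0 * x * fo2

    o2_uptake = 2.0 * r_ac + 0.5 * r_form + 3.5 * r_succ
    # formate is the electron donor of the denitrification steps (2 e each)
    form_denit = r_no3 + r_no2 + r_n2o

    if p.headspace:
        c_eq = gas * p.c_eq_per_gas
        transfer = p.kla * (c_eq - o2)
        dgas = pulse - transfer - p.vent_rate * gas
        do2 = transfer - o2_uptake - D * o2
    else:
        dgas = 0.0
        do2 = pulse - p.strip_rate * o2 - o2_uptake - D * o2

    dno3 = D * (p.feed_no3 - no3) - r_no3
    dno2 = D * (p.feed_no2 - no2) + r_no3 - r_no2
    dn2o = 0.5 * r_no2 - r_n2o - p.strip_rate * 0.0 - D * n2o
    dn2 = r_n2o - D * n2
    dglc = D * (p.feed_glucose - glc) - r_ferm
    dac = D * (p.feed_acetate - ac) + 2.0 * r_ferm - r_ac
    dform = 2.0 * r_ferm - r_form - form_denit - D * form
    dsucc = r_aa - r_succ - D * succ
    daa = D * (p.feed_aa - aa) - r_aa
    ds0 = r_s0 - p.k_s0_decay * s0 * tower - D * s0

    c_resp = 2.0 * r_ac + r_form + 4.0 * r_succ + form_denit
    growth = p.y_resp * c_resp + p.y_ferm * 6.0 * r_ferm - D * x

    # electrons: feed donors supplied vs acceptors used
    ded = D * (24.0 * p.feed_glucose + 8.0 * p.feed_acetate + 14.0 * p.feed_aa)
    dea = 4.0 * o2_uptake + 2.0 * (r_no3 + r_no2 + r_n2o)

    return np.array([
        do2, dgas, dno3, dno2, dn2, dn2o, dglc, dac, dform, dsucc, daa,
        ds0, growth, ded, dea,
    ])


def simulate_cycle(
    params: Optional[ChemostatParams] = None,
    n_cycles: int = 2,
    points_per_hour: int = 60,
    initial: Optional[Dict[str, float]] = None,
    noise_sd: float = 0.0,
) -> SimulationOutput:
    """Integrate the tidal-cycle mass balances over ``n_cycles`` 12-h cycles.

    ``initial`` overrides initial concentrations by state name.  With
    ``noise_sd`` > 0, seeded multiplicative Gaussian measurement noise is
    applied to the concentration trajectories (not to the integrator).
    """
    p = params or ChemostatParams()
    y0 = np.zeros(len(STATE_NAMES))
    y0[STATE_NAMES.index("NO3")] = 0.01
    y0[STATE_NAMES.index("NO2")] = 0.005
    y0[STATE_NAMES.index("acetate")] = 0.1
    y0[STATE_NAMES.index("formate")] = 0.1
    y0[STATE_NAMES.index("biomass")] = p.biomass0
    if initial:
        for name, value in initial.items():
            y0[STATE_NAMES.index(name)] = value

    t_end = n_cycles * p.period
    t_eval = np.linspace(0.0, t_end, int(t_end * points_per_hour) + 1)
    # integrate pulse windows separately so the solver never steps across
    # the supply discontinuity
    breaks = [0.0]
    for k in range(n_cycles):
        breaks += [k * p.period + p.pulse_duration, (k + 1) * p.period]
    ts_all, ys_all = [], []
    y = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        if len(seg_eval) == 0 or seg_eval[0] > a:
            seg_eval = np.concatenate([[a], seg_eval])
        if seg_eval[-1] < b:
            seg_eval = np.concatenate([seg_eval, [b]])
        sol = solve_ivp(
            _rhs, (a, b), y, t_eval=seg_eval, args=(p,), method="LSODA",
            rtol=p.rtol, atol=p.atol,
        )
        if not sol.success:
            raise SimulationError(
                f"integrator failed on [{a}, {b}]: {sol.message}; state={y}"
            )
        y = sol.y[:, -1]
        ts_all.append(sol.t)
        ys_all.append(sol.y)
    t = np.concatenate(ts_all)
    ys = np.concatenate(ys_all, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t, ys = t[keep], ys[:, keep]

    states = {name: ys[i] for i, name in enumerate(STATE_NAMES)}
    if noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        for name in STATE_NAMES:
            if name.startswith("e_"):
                continue
            states[name] = states[name] * (
                1.0 + noise_sd * rng.standard_normal(len(t))
            )
    return SimulationOutput(params=p, time=t, states=states)


# ---------------------------------------------------------------------------
# ground-truth generators for the fitting and normalization stages


def generate_observations(
    network: Network,
    true_rates: Dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ConversionVector:
    """Observed conversion vector S v* (+ relative Gaussian noise) from a
    known rate vector over the network's reactions."""
    for rid, v in true_rates.items():
        if v < 0:
            raise SimulationError(f"true rate for {rid!r} must be >= 0")
    reactions = [r for r in network.reactions if r.id in true_rates]
    missing = set(true_rates) - {r.id for r in reactions}
    if missing:
        raise SimulationError(f"unknown reaction id(s): {sorted(missing)}")
    compounds = network.compound_ids(network.reactions)
    S = network.stoich_matrix(compounds, reactions)
    v = np.array([true_rates[r.id] for r in reactions])
    flux = S @ v
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flux = flux * (1.0 + noise_sd * rng.standard_normal(len(flux)))
    rates = {}
    biomass = 0.0
    for cid, f in zip(compounds, flux):
        if cid == "biomass":
            biomass = float(f)
        else:
            rates[cid] = float(f)
    return ConversionVector(rates, biomass_rate=biomass)


def generate_counts(
    true_activities: Dict[str, float],
    lengths: Dict[str, float],
    bins: Dict[str, str],
    depth: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial read-count table with known per-ORF activities.

    Within each bin, the probability of a read landing on an ORF is
    proportional to activity x length; each bin receives ``depth`` reads.
    """
    if depth < 1:
        raise SimulationError("sequencing depth must be >= 1")
    if set(true_activities) != set(lengths) or set(lengths) != set(bins):
        raise SimulationError("activities, lengths and bins must share keys")
    for orf, a in true_activities.items():
        if a < 0:
            raise SimulationError(f"activity of {orf!r} must be >= 0")
        if lengths[orf] <= 0:
            raise SimulationError(f"length of {orf!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    by_bin: Dict[str, list] = {}
    for orf in true_activities:
        by_bin.setdefault(bins[orf], []).append(orf)
    for bin_id in sorted(by_bin):
        orfs = by_bin[bin_id]
        w = np.array([true_activities[o] * lengths[o] for o in orfs], dtype=float)
        if w.sum() <= 0:
            raise SimulationError(f"bin {bin_id!r} has zero total activity")
        counts = rng.multinomial(depth, w / w.sum())
        for orf, n in zip(orfs, counts):
            rows.append(
                {"orf_id": orf, "bin_id": bin_id,
                 "length": lengths[orf], "count": int(n)}
            )
    return pd.DataFrame(rows)
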