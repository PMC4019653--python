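"""Core ODE model: right-hand side, stiff integration and the
repeated-cycle protocol with G1-variable resets.

The model couples a growth-signalling entry block (ERG/DRG -> cyclin D ->
Rb phosphorylation -> E2F release) to the mitotic-cyclin engine
(cyclin E/A/B, CKI, Wee1/Cdc25, Cdh1/Cdc20-APC/C, the intermediary enzyme
IEP and the G2 transcription factor TFAB).  All reactions are mass action
except the five activity switches (Wee1, Cdc25, Cdh1, Cdc20 activation,
IEP, TFAB), which use Michaelis-Menten (zero-order ultrasensitive)
interconversion -- the dynamic counterpart of the Goldbeter-Koshland
steady-state function implemented in :func:`goldbeter_koshland`.

Time is measured in fractions of the cell-cycle time Tc; concentrations
are in arbitrary units.  A cycle ends at a division event, defined as the
downward crossing of active CycB:Cdk1 through 10% of its running peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParameterSet, default_initial_state
from .species import DEFAULT_RESET_SPECIES, N_SPECIES, SPECIES_INDEX, SPECIES_NAMES

__all__ = [
    "goldbeter_koshland",
    "rhs",
    "simulate",
    "simulate_cycles",
    "Trajectory",
    "ResetSpec",
    "SolverError",
    "NonCyclingError",
]


class SolverError(RuntimeError):
    """Stiff integration failed (step-size collapse); carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class NonCyclingError(RuntimeError):
    """No division event was detected within the safety horizon."""


# --------------------------------------------------------------------------
# Goldbeter-Koshland switch
# --------------------------------------------------------------------------

def goldbeter_koshland(v_activate: float, v_inactivate: float,
                       J_activate: float, J_inactivate: float) -> float:
    """Steady-state modified fraction of a covalent-modification cycle.

    Solves ``v_a (1-f)/(J_a + 1-f) = v_i f/(J_i + f)`` for ``f`` in [0, 1]
    using the closed form; the result is continuous and nondecreasing in
    ``v_activate`` and ultrasensitive when both J's are small.
    """
    va, vi = float(v_activate), float(v_inactivate)
    Ja, Ji = float(J_activate), float(J_inactivate)
    if va < 0 or vi < 0:
        raise ValueError("activation/inactivation rates must be >= 0")
    if Ja <= 0 or Ji <= 0:
        raise ValueError("saturation constants must be > 0")
    if va == 0.0:
        return 0.0
    if vi == 0.0:
        return 1.0
    B = vi - va + Ja * vi + Ji * va
    disc = B * B + 4.0 * (va - vi) * va * Ji
    return 2.0 * va * Ji / (B + np.sqrt(disc))


# --------------------------------------------------------------------------
# right-hand side
# --------------------------------------------------------------------------

def _rhs_core(t, y, p):  # pragma: no cover - exercised through rhs()
    # parameter unpack (order fixed by params.PARAM_NAMES; regenerated with it)
    k_serg = p[0]
    k_derg = p[1]
    k_sdrg = p[2]
    k_sdrg_drg = p[3]
    J_drg = p[4]
    k_ddrg = p[5]
    k_sd = p[6]
    J_sd = p[7]
    k_dd = p[8]
    k_asd = p[9]
    k_did = p[10]
    k_dd_k = p[11]
    k_prb_d = p[12]
    k_prb_dk = p[13]
    k_prb_e = p[14]
    k_prb_a = p[15]
    k_dprb = p[16]
    k_prb2_e = p[17]
    k_prb2_a = p[18]
    k_dprb2 = p[19]
    k_as_fe = p[20]
    k_di_fe = p[21]
    k_de2f_rb = p[22]
    k_se2f_basal = p[23]
    k_se2f = p[24]
    J_se2f = p[25]
    k_pe2f_a = p[26]
    k_pe2f_b = p[27]
    k_dpe2f = p[28]
    k_de2f = p[29]
    k_de2f_p = p[30]
    k_de2f_20 = p[31]
    k_de2f_h1 = p[32]
    k_se_basal = p[33]
    k_se = p[34]
    k_de = p[35]
    k_de_a = p[36]
    k_ase = p[37]
    k_die = p[38]
    k_de_k = p[39]
    k_ski = p[40]
    k_dki = p[41]
    k_dki_d = p[42]
    k_dki_e = p[43]
    k_dki_a = p[44]
    k_dki_b = p[45]
    k_sa_basal = p[46]
    k_sa_e2f = p[47]
    k_sa_ab = p[48]
    k_da = p[49]
    k_da_20 = p[50]
    k_da_h1 = p[51]
    k_asa = p[52]
    k_dia = p[53]
    k_sb_basal = p[54]
    k_sb_e2f = p[55]
    k_sb_ab = p[56]
    k_sb_b = p[57]
    k_db = p[58]
    k_db_20 = p[59]
    k_db_h1 = p[60]
    k_wee_basal = p[61]
    k_wee_b = p[62]
    k_25_basal = p[63]
    k_25_b = p[64]
    k_aw = p[65]
    J_aw = p[66]
    k_iw_a = p[67]
    k_iw_b = p[68]
    J_iw = p[69]
    k_a25_b = p[70]
    k_a25_a = p[71]
    J_a25 = p[72]
    k_i25 = p[73]
    J_i25 = p[74]
    k_ah1 = p[75]
    k_ah1_20 = p[76]
    J_ah1 = p[77]
    k_ih1_basal = p[78]
    k_ih1_d = p[79]
    k_ih1_e = p[80]
    k_ih1_a = p[81]
    k_ih1_b = p[82]
    J_ih1 = p[83]
    k_s20_basal = p[84]
    k_s20_a = p[85]
    k_s20_b = p[86]
    k_d20 = p[87]
    k_a20 = p[88]
    J_a20 = p[89]
    k_i20 = p[90]
    J_i20 = p[91]
    k_d20a = p[92]
    k_aie = p[93]
    J_aie = p[94]
    k_iie = p[95]
    J_iie = p[96]
    k_atf = p[97]
    J_atf = p[98]
    k_itf = p[99]
    k_itf_b = p[100]
    k_itf_20 = p[101]
    J_itf = p[102]
    f_a2 = p[103]  # cyclin A synthesis fraction routed to Cdk2

    ERG = y[0]
    DRG = y[1]
    CycD = y[2]
    CycD_Kip = y[3]
    Rb = y[4]
    pRb = y[5]
    ppRb = y[6]
    E2F_Rb = y[7]
    E2F = y[8]
    pE2F = y[9]
    CycE = y[10]
    CycE_Kip = y[11]
    Kip1 = y[12]
    CycA2 = y[13]
    CycA1 = y[14]
    CycA_Kip = y[15]
    CycB = y[16]
    actCycB = y[17]
    Wee1 = y[18]
    Cdc25 = y[19]
    Cdh1 = y[20]
    Cdc20T = y[21]
    Cdc20A = y[22]
    IEP = y[23]
    TFAB = y[24]

    CycDt = CycD + CycD_Kip          # CycD:CKI complexes retain Rb-kinase activity
    CycAact = CycA2 + CycA1          # the two cyclin A pools act in unison

    Vrb1 = k_prb_d * CycD + k_prb_dk * CycD_Kip + k_prb_e * CycE + k_prb_a * CycAact
    Vrb2 = k_prb2_e * CycE + k_prb2_a * CycAact
    Vpe2f = k_pe2f_a * CycAact + k_pe2f_b * actCycB
    Vse = k_se_basal + k_se * E2F
    Vde = k_de + k_de_a * CycAact
    Vdki = k_dki + k_dki_d * CycDt + k_dki_e * CycE + k_dki_a * CycAact + k_dki_b * actCycB
    Vsa = k_sa_basal + k_sa_e2f * E2F + k_sa_ab * TFAB
    Vda = k_da + k_da_20 * Cdc20A + k_da_h1 * Cdh1
    Vsb = k_sb_basal + k_sb_e2f * E2F + k_sb_ab * TFAB + k_sb_b * actCycB
    Vdb = k_db + k_db_20 * Cdc20A + k_db_h1 * Cdh1
    Vwee = k_wee_basal + k_wee_b * Wee1
    V25 = k_25_basal + k_25_b * Cdc25

    dy = np.empty(25)
    dy[0] = k_serg - k_derg * ERG
    dy[1] = (k_sdrg * ERG
             + k_sdrg_drg * DRG * DRG / (J_drg * J_drg + DRG * DRG)
             - k_ddrg * DRG)
    dy[2] = (k_sd * DRG / (J_sd + DRG) - k_dd * CycD
             - k_asd * CycD * Kip1 + (k_did + Vdki) * CycD_Kip)
    dy[3] = k_asd * CycD * Kip1 - (k_did + k_dd_k + Vdki) * CycD_Kip
    dy[4] = (-Vrb1 * Rb + k_dprb * pRb
             - k_as_fe * E2F * Rb + (k_di_fe + k_de2f_rb) * E2F_Rb)
    dy[5] = (Vrb1 * (Rb + E2F_Rb) - k_dprb * pRb
             - Vrb2 * pRb + k_dprb2 * ppRb)
    dy[6] = Vrb2 * pRb - k_dprb2 * ppRb
    dy[7] = k_as_fe * E2F * Rb - (k_di_fe + Vrb1 + k_de2f_rb) * E2F_Rb
    dy[8] = (k_se2f_basal + k_se2f * E2F / (1.0 + E2F / J_se2f)
             - k_as_fe * E2F * Rb + (k_di_fe + Vrb1) * E2F_Rb
             - Vpe2f * E2F + k_dpe2f * pE2F - k_de2f * E2F)
    dy[9] = (Vpe2f * E2F - k_dpe2f * pE2F
             - (k_de2f_p + k_de2f_20 * Cdc20A + k_de2f_h1 * Cdh1) * pE2F)
    dy[10] = (Vse - Vde * CycE - k_ase * CycE * Kip1
              + (k_die + Vdki) * CycE_Kip)
    dy[11] = k_ase * CycE * Kip1 - (k_die + k_de_k + Vdki) * CycE_Kip
    dy[12] = (k_ski - Vdki * Kip1
              - k_asd * CycD * Kip1 - k_ase * CycE * Kip1 - k_asa * CycA2 * Kip1
              + (k_did + k_dd_k) * CycD_Kip
              + (k_die + k_de_k) * CycE_Kip
              + (k_dia + Vda) * CycA_Kip)
    dy[13] = (f_a2 * Vsa - Vda * CycA2
              - k_asa * CycA2 * Kip1 + (k_dia + Vdki) * CycA_Kip)
    dy[14] = (1.0 - f_a2) * Vsa - Vda * CycA1
    dy[15] = k_asa * CycA2 * Kip1 - (k_dia + Vda + Vdki) * CycA_Kip
    dy[16] = Vsb - Vdb * CycB
    dy[17] = (Vsb - Vdb * actCycB
              - Vwee * actCycB + V25 * (CycB - actCycB))
    dy[18] = (k_aw * (1.0 - Wee1) / (J_aw + 1.0 - Wee1)
              - (k_iw_a * CycAact + k_iw_b * actCycB) * Wee1 / (J_iw + Wee1))
    dy[19] = ((k_a25_b * actCycB + k_a25_a * CycAact)
              * (1.0 - Cdc25) / (J_a25 + 1.0 - Cdc25)
              - k_i25 * Cdc25 / (J_i25 + Cdc25))
    dy[20] = ((k_ah1 + k_ah1_20 * Cdc20A) * (1.0 - Cdh1) / (J_ah1 + 1.0 - Cdh1)
              - (k_ih1_basal + k_ih1_d * CycDt + k_ih1_e * CycE
                 + k_ih1_a * CycAact + k_ih1_b * actCycB)
              * Cdh1 / (J_ih1 + Cdh1))
    dy[21] = (k_s20_basal + k_s20_a * CycAact + k_s20_b * actCycB
              - k_d20 * (Cdc20T - Cdc20A) - k_d20a * Cdc20A)
    dy[22] = (k_a20 * IEP * (Cdc20T - Cdc20A) / (J_a20 + Cdc20T - Cdc20A)
              - k_i20 * Cdc20A / (J_i20 + Cdc20A) - k_d20a * Cdc20A)
    dy[23] = (k_aie * actCycB * (1.0 - IEP) / (J_aie + 1.0 - IEP)
              - k_iie * IEP / (J_iie + IEP))
    dy[24] = (k_atf * CycAact * (1.0 - TFAB) / (J_atf + 1.0 - TFAB)
              - (k_itf + k_itf_b * actCycB + k_itf_20 * Cdc20A)
              * TFAB / (J_itf + TFAB))
    return dy


try:  # JIT compile when numba is available; the pure-Python path is identical
    from numba import njit

    _rhs_compiled = njit(cache=True)(_rhs_core)
except ImportError:  # pragma: no cover
    _rhs_compiled = _rhs_core


def rhs(t: float, state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Time derivatives of the 25 state variables.

    For any species at zero the corresponding derivative is nonnegative
    (all removal terms are mass action), so the nonnegative orthant is
    forward-invariant.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(f"state must have exactly {N_SPECIES} components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    return _rhs_compiled(float(t), y, params.to_array())


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed model states over one or more cycles.

    ``times`` are in fractions of Tc and strictly increasing; ``states``
    has one row per time point in :data:`cdkcycle.species.SPECIES_NAMES`
    order.  ``division_times`` marks detected division events and
    ``periods`` the per-cycle period estimates.
    """

    times: np.ndarray
    states: np.ndarray
    division_times: list = field(default_factory=list)
    periods: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, N_SPECIES):
            raise ValueError("states must be (n_times, 25)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def species(self, name: str) -> np.ndarray:
        """Concentration series of one named species."""
        return self.states[:, SPECIES_INDEX[name]]

    def to_frame(self):
        """Trajectory as a pandas DataFrame (time_fraction + 25 species)."""
        import pandas as pd

        data = {"time_fraction": self.times}
        for i, n in enumerate(SPECIES_NAMES):
            data[n] = self.states[:, i]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ResetSpec:
    """Division-reset protocol for repeated cycles.

    ``resets`` maps state-variable names to the values they are set to at
    each division (the G1 entry variables by default); ``threshold_fraction``
    defines a division as the downward crossing of active CycB:Cdk1
    through this fraction of its running peak.
    """

    resets: dict[str, float]
    threshold_fraction: float = 0.1

    def __post_init__(self):
        unknown = set(self.resets) - set(SPECIES_NAMES)
        if unknown:
            raise ValueError(f"unknown state variable(s) in reset spec: {sorted(unknown)}")
        if any(v < 0 for v in self.resets.values()):
            raise ValueError("reset values must be >= 0")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")

    @classmethod
    def default(cls) -> "ResetSpec":
        init = default_initial_state()
        return cls({n: float(init[SPECIES_INDEX[n]]) for n in DEFAULT_RESET_SPECIES})


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def simulate(params: ParameterSet, init: np.ndarray | None = None,
             t_span: tuple[float, float] = (0.0, 1.0),
             n_out: int = 1001, method: str = "LSODA",
             rtol: float | None = None, atol: float | None = None) -> Trajectory:
    """Integrate the model over ``t_span`` with a stiff solver.

    ``init`` defaults to the packaged start-of-cycle state.  Output is on
    ``n_out`` uniformly spaced points (a zero-length span returns the
    initial state unchanged).
    """
    if init is None:
        init = default_initial_state()
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (N_SPECIES,):
        raise ValueError(f"init must have {N_SPECIES} components")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise ValueError("t_span must be nondecreasing")
    if t1 == t0:
        return Trajectory(np.array([t0]), y0[None, :].copy())

    p = params.to_array()
    sol = solve_ivp(
        _rhs_compiled, (t0, t1), y0, method=method,
        t_eval=np.linspace(t0, t1, int(n_out)),
        rtol=params.rtol if rtol is None else rtol,
        atol=params.atol if atol is None else atol,
        max_step=params.max_step, args=(p,),
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}", t_fail=float(sol.t[-1]) if sol.t.size else t0)
    states = np.clip(sol.y.T, 0.0, None)  # clamp solver undershoot below tolerance
    return Trajectory(sol.t, states)


def _find_division(times: np.ndarray, act: np.ndarray,
                   threshold_fraction: float) -> float | None:
    """First downward crossing of ``act`` through threshold_fraction x its
    running peak, searched after the global peak; linear interpolation
    between output points."""
    if times.size < 3:
        return None
    run_peak = np.maximum.accumulate(act)
    # arm detection only after activity has risen appreciably above its
    # start-of-cycle residual, so the post-division tail is not mistaken
    # for a new division
    armed = run_peak >= max(1.5 * act[0], 1e-6)
    crossing = armed & (act < threshold_fraction * run_peak)
    idx = np.nonzero(crossing)[0]
    if idx.size == 0 or idx[0] == 0:
        return None
    j = int(idx[0])
    thr = threshold_fraction * run_peak[j]
    t_lo, t_hi = times[j - 1], times[j]
    a_lo, a_hi = act[j - 1], act[j]
    if a_hi >= a_lo:
        return float(t_hi)
    return float(t_lo + (a_lo - thr) * (t_hi - t_lo) / (a_lo - a_hi))


def simulate_cycles(params: ParameterSet, n_cycles: int = 1,
                    reset: ResetSpec | None = None,
                    init: np.ndarray | None = None,
                    nominal_period: float = 1.0,
                    horizon_factor: float = 3.0,
                    n_out_per_cycle: int = 2000,
                    method: str = "LSODA") -> Trajectory:
    """Run ``n_cycles`` successive cycles with division-event resets.

    Each cycle is integrated until active CycB:Cdk1 falls through the
    reset threshold after its peak; the variables named in ``reset`` are
    then set to their reset values and integration continues.  If no
    division occurs within ``horizon_factor`` nominal periods a
    :class:`NonCyclingError` is raised.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if reset is None:
        reset = ResetSpec.default()
    y = default_initial_state() if init is None else np.asarray(init, dtype=float).copy()

    iact = SPECIES_INDEX["actCycB"]
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    division_times: list[float] = []
    periods: list[float] = []
    t_start = 0.0

    for cyc in range(n_cycles):
        horizon = horizon_factor * nominal_period
        tr = simulate(params, y, (t_start, t_start + horizon),
                      n_out=int(n_out_per_cycle * horizon_factor), method=method)
        t_div = _find_division(tr.times, tr.states[:, iact], reset.threshold_fraction)
        if t_div is None:
            raise NonCyclingError(
                f"no division event within {horizon_factor:g} nominal periods "
                f"(cycle {cyc + 1})")
        keep = tr.times <= t_div
        # state at division via linear interpolation on the dense output
        y_div = np.array([np.interp(t_div, tr.times, tr.states[:, i])
                          for i in range(N_SPECIES)])
        seg_t = np.append(tr.times[keep], t_div)
        seg_y = np.vstack([tr.states[keep], y_div])
        if all_t:  # drop duplicated segment-start point
            seg_t, seg_y = seg_t[1:], seg_y[1:]
        all_t.append(seg_t)
        all_y.append(seg_y)
        division_times.append(t_div)
        periods.append(t_div - t_start)
        # apply resets and continue from the division event
        y = y_div.copy()
        for name, value in reset.resets.items():
            y[SPECIES_INDEX[name]] = value
        t_start = t_div

    times = np.concatenate(all_t)
    states = np.concatenate(all_y)
    # enforce strict monotonicity in the face of interpolation-point ties
    keep = np.concatenate([[True], np.diff(times) > 0])
    return Trajectory(times[keep], states[keep],
                      division_times=division_times, periods=periods)
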