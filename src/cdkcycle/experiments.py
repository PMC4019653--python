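"""In-silico perturbation experiments and model-vs-reference comparison.

Gene "deletion" follows the classical in-silico protocol: the synthesis
rate constants of the targeted cyclin are set to zero while the species
and all other constants are untouched.  Deleting cyclin D removes the
growth-signal route to Rb phosphorylation, so E2F release must wait for
the slower cyclin E-driven positive feedback; deleting cyclins D and E
leaves only basal E2F accumulation, giving a still more profound G1
extension.  Both knockouts retain a complete, repeating cycle.

G1 duration is measured operationally: from the division event until
total cyclin A first becomes detectable (1% of its per-cycle maximum),
since cyclin A onset sits at or near the start of S phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NonCyclingError, ResetSpec, Trajectory, simulate_cycles
from .observables import (
    mitotic_onset,
    normalize_zero_one,
    observable_series,
    onset_time,
    trajectory_observables,
)
from .params import ParameterSet
from .synth import ReferenceDataset

__all__ = [
    "KnockoutSpec",
    "ExperimentReport",
    "apply_knockout",
    "g1_duration",
    "run_condition",
    "compare_to_reference",
    "CONDITIONS",
]

#: synthesis rate constants zeroed by each knockout target
KNOCKOUT_TARGETS: dict[str, tuple[str, ...]] = {
    "cyclinD": ("k_sd",),
    "cyclinE": ("k_se", "k_se_basal"),
}

#: condition label -> knockout targets
CONDITIONS: dict[str, tuple[str, ...]] = {
    "WT": (),
    "dD": ("cyclinD",),
    "dDdE": ("cyclinD", "cyclinE"),
}


@dataclass(frozen=True)
class KnockoutSpec:
    """A set of cyclin knockouts and the constants they zero."""

    targets: frozenset[str]

    def __init__(self, targets):
        object.__setattr__(self, "targets", frozenset(targets))
        unknown = self.targets - set(KNOCKOUT_TARGETS)
        if unknown:
            raise ValueError(
                f"unknown knockout target(s) {sorted(unknown)}; "
                f"supported: {sorted(KNOCKOUT_TARGETS)}")

    @property
    def zeroed_constants(self) -> tuple[str, ...]:
        out: list[str] = []
        for t in sorted(self.targets):
            out.extend(KNOCKOUT_TARGETS[t])
        return tuple(out)


@dataclass
class ExperimentReport:
    """Summary of one simulated condition."""

    condition: str
    period: float
    g1_fraction: float           # of the wild-type-normalized period
    g1_absolute: float
    committed_fraction: float    # period minus G1, as fraction of period
    no_s_entry: bool
    peaks: dict = field(default_factory=dict)  # channel -> (time frac, amplitude)
    period_drift: float = float("nan")
    amplitude_drift: float = float("nan")
    periods: list = field(default_factory=list)
    stalled: bool = False

    def to_dict(self) -> dict:
        return {
            "schema": "cdkcycle.experiment/1",
            "condition": self.condition,
            "period": self.period,
            "g1_fraction": self.g1_fraction,
            "g1_absolute": self.g1_absolute,
            "committed_fraction": self.committed_fraction,
            "no_s_entry": self.no_s_entry,
            "peaks": {k: list(v) for k, v in self.peaks.items()},
            "period_drift": self.period_drift,
            "amplitude_drift": self.amplitude_drift,
            "periods": list(self.periods),
            "stalled": self.stalled,
        }


def apply_knockout(params: ParameterSet, spec: KnockoutSpec) -> ParameterSet:
    """Zero the targeted synthesis constants; everything else unchanged.

    An empty target set returns an equal parameter set; the input is
    never mutated.
    """
    if not spec.targets:
        return params.with_overrides({})
    return params.with_overrides({k: 0.0 for k in spec.zeroed_constants})


def g1_duration(traj: Trajectory, detection_fraction: float = 0.01):
    """G1 length (in trajectory time units) of the first cycle.

    Measured from the cycle start (a division event) to the detectable
    onset of total cyclin A.  Returns ``(duration, no_s_entry)``: if
    cyclin A never rises, the whole first period is returned with the
    ``no_s_entry`` flag set.
    """
    if not traj.division_times:
        raise ValueError("trajectory must span at least one full cycle")
    t_end = traj.division_times[0]
    sel = traj.times <= t_end
    series = observable_series(traj, "cyclinA_total")
    sub = type(series)(series.channel, series.times[sel], series.values[sel])
    onset = onset_time(sub, detection_fraction, from_minimum=True)
    if onset is None:
        return float(t_end - traj.times[0]), True
    return float(onset - traj.times[0]), False


def _peaks(traj: Trajectory, c0: float, c1: float) -> dict:
    out = {}
    sel = (traj.times >= c0) & (traj.times <= c1)
    rel = (traj.times[sel] - c0) / (c1 - c0)
    for ch in ("cyclinA_total", "cyclinB_total", "cycB_cdk1_active"):
        v = observable_series(traj, ch).values[sel]
        i = int(np.argmax(v))
        out[ch] = (float(rel[i]), float(v[i]))
    return out


def run_condition(params: ParameterSet, condition: str,
                  n_cycles: int = 3, reset: ResetSpec | None = None,
                  wt_period: float = 1.0,
                  horizon_factor: float = 8.0) -> ExperimentReport:
    """Simulate one condition (WT, dD or dDdE) and summarize it.

    Durations are reported both in absolute model time and as fractions
    of the wild-type period (the WT cycle time is normalized to 1).  A
    condition that never divides within the safety horizon is reported
    with ``stalled=True`` rather than raising.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {sorted(CONDITIONS)}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    p = apply_knockout(params, KnockoutSpec(CONDITIONS[condition]))
    try:
        traj = simulate_cycles(p, n_cycles=n_cycles, reset=reset,
                               horizon_factor=horizon_factor)
    except NonCyclingError:
        return ExperimentReport(condition=condition, period=float("nan"),
                                g1_fraction=float("nan"), g1_absolute=float("nan"),
                                committed_fraction=float("nan"),
                                no_s_entry=True, stalled=True)
    period = traj.periods[0]
    g1_abs, no_s = g1_duration(traj)
    report = ExperimentReport(
        condition=condition,
        period=float(period),
        g1_absolute=float(g1_abs),
        g1_fraction=float(g1_abs / wt_period),
        committed_fraction=float((period - g1_abs) / period),
        no_s_entry=no_s,
        peaks=_peaks(traj, 0.0, traj.division_times[0]),
        periods=[float(x) for x in traj.periods],
    )
    if len(traj.periods) >= 3:
        p2, p3 = traj.periods[1], traj.periods[2]
        report.period_drift = abs(p3 - p2) / p2
        b = observable_series(traj, "cyclinB_total")
        amp = []
        bounds = [0.0] + list(traj.division_times)
        for c0, c1 in zip(bounds[1:-1], bounds[2:]):
            sel = (traj.times >= c0) & (traj.times <= c1)
            amp.append(float(b.values[sel].max()))
        report.amplitude_drift = abs(amp[1] - amp[0]) / amp[0]
    return report


def compare_to_reference(traj: Trajectory, data: ReferenceDataset) -> dict:
    """Per-channel RMSE and onset error of a trajectory against a dataset.

    Channels are aligned on cycle fraction (trajectory time divided by
    its first period) and normalized to [0, 1] before comparison.
    """
    if not traj.division_times:
        period = traj.times[-1] - traj.times[0]
    else:
        period = traj.periods[0]
    if period <= 0:
        raise ValueError("trajectory spans no time")
    frac = (traj.times - traj.times[0]) / period
    grid = data.times
    if grid[0] > frac[-1] or grid[-1] < frac[0]:
        raise ValueError("no overlap between trajectory and dataset time domains")
    obs = trajectory_observables(traj, normalized=True)
    a = np.interp(grid, frac, obs["cyclinA_total"].values)
    b = np.interp(grid, frac, obs["cyclinB_total"].values)
    onset = mitotic_onset(obs["cycB_cdk1_active"], 0.5)
    onset = 1.0 if onset is None else onset / period
    phh3 = data.PHH3
    data_onset = (float(grid[np.nonzero(phh3 >= 0.5 * phh3.max())[0][0]])
                  if phh3.max() > 0 else 1.0)
    return {
        "rmse": {
            "cyclinA": float(np.sqrt(np.mean((a - data.cyclinA2) ** 2))),
            "cyclinB": float(np.sqrt(np.mean((b - data.cyclinB1) ** 2))),
        },
        "onset_error": float(onset - data_onset),
    }
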