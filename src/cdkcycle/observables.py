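"""Mapping from raw trajectories to measured quantities.

Antibody-based cytometry does not discriminate free from bound or active
from inactive protein, so the measured channels are *totals*: every
cyclin A-containing species is summed for the cyclin A2 channel and
likewise for cyclin B1.  Phospho-histone H3 carries timing information
only, so active CycB:Cdk1 is compared to PHH3 by onset time, never by
shape.  Model outputs are normalized to [0, 1] per channel before
comparison, matching how the expression profiles are plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import Trajectory
from .species import CYCLIN_A_SPECIES, CYCLIN_B_SPECIES, SPECIES_INDEX

__all__ = [
    "ObservableSeries",
    "total_cyclin_a",
    "total_cyclin_b",
    "active_cycb_cdk1",
    "normalize_zero_one",
    "to_real_time",
    "mitotic_onset",
    "onset_time",
    "NO_ONSET",
    "observable_series",
    "trajectory_observables",
]

#: sentinel returned by onset detectors when the series never crosses
NO_ONSET = None

_CHANNELS = ("cyclinA_total", "cyclinB_total", "cycB_cdk1_active")


@dataclass(frozen=True)
class ObservableSeries:
    """One measured channel against cycle-time fraction."""

    channel: str
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have identical shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.normalized and self.values.size >= 2:
            lo, hi = self.values.min(), self.values.max()
            if not (abs(lo) < 1e-9 and abs(hi - 1.0) < 1e-9):
                raise ValueError("normalized series must have min 0 and max 1")


def _state_sum(state: np.ndarray, names: tuple[str, ...]) -> float:
    return float(sum(state[SPECIES_INDEX[n]] for n in names))


def total_cyclin_a(state: np.ndarray) -> float:
    """Total cyclin A (CycA:Cdk2 + CycA:Cdk1 + CKI-bound), bound and free,
    active and inactive."""
    return _state_sum(np.asarray(state, dtype=float), CYCLIN_A_SPECIES)


def total_cyclin_b(state: np.ndarray) -> float:
    """Total cyclin B (the CycB pool carries active plus Tyr15-phosphorylated
    CycB:Cdk1)."""
    return _state_sum(np.asarray(state, dtype=float), CYCLIN_B_SPECIES)


def active_cycb_cdk1(state: np.ndarray) -> float:
    """Active CycB:Cdk1 — the model proxy for PHH3 onset timing."""
    return float(np.asarray(state, dtype=float)[SPECIES_INDEX["actCycB"]])


def normalize_zero_one(series: ObservableSeries) -> ObservableSeries:
    """Affine map of the series onto [0, 1]; order-preserving and idempotent."""
    if series.values.size < 2:
        raise ValueError("need at least 2 points to normalize")
    lo, hi = float(series.values.min()), float(series.values.max())
    if hi <= lo:
        raise ValueError(f"cannot normalize a constant series (value {lo!r})")
    return replace(series, values=(series.values - lo) / (hi - lo), normalized=True)


def to_real_time(fractions, Tc_hours: float):
    """Convert cycle-time fractions to hours given the cell-cycle time Tc."""
    if Tc_hours <= 0:
        raise ValueError("Tc_hours must be > 0")
    return np.asarray(fractions, dtype=float) * float(Tc_hours)


def onset_time(series: ObservableSeries, threshold_fraction: float = 0.01,
               from_minimum: bool = True):
    """First time the series rises through ``threshold_fraction`` of its
    maximum (detectable-expression onset).

    With ``from_minimum`` the search starts at the series minimum, so a
    decaying residual inherited from the previous cycle is not mistaken
    for expression onset.  Returns :data:`NO_ONSET` if never crossed.
    """
    v = series.values
    thr = threshold_fraction * v.max()
    start = int(np.argmin(v)) if from_minimum else 0
    idx = np.nonzero(v[start:] > thr)[0]
    if idx.size == 0:
        return NO_ONSET
    j = start + idx[0]
    if j == 0 or v[j - 1] > thr:
        return float(series.times[j])
    # linear interpolation inside the bracketing interval
    t0, t1, v0, v1 = series.times[j - 1], series.times[j], v[j - 1], v[j]
    return float(t0 + (thr - v0) * (t1 - t0) / (v1 - v0))


def mitotic_onset(series: ObservableSeries, threshold_fraction: float = 0.5):
    """First upward crossing of a normalized activity series through
    ``threshold_fraction``, by linear interpolation between samples.

    Returns :data:`NO_ONSET` (not an error) if the series never crosses.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    v = series.values
    if v.max() <= 0.0:  # silent channel: no onset, distinct from an error
        return NO_ONSET
    if not series.normalized:
        raise ValueError("mitotic_onset expects a normalized series")
    idx = np.nonzero(v > threshold_fraction)[0]
    if idx.size == 0:
        return NO_ONSET
    j = int(idx[0])
    if j == 0:
        return float(series.times[0])
    t0, t1, v0, v1 = series.times[j - 1], series.times[j], v[j - 1], v[j]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold_fraction - v0) * (t1 - t0) / (v1 - v0))


def observable_series(traj: Trajectory, channel: str) -> ObservableSeries:
    """Extract one named channel from a trajectory."""
    if channel == "cyclinA_total":
        vals = sum(traj.species(n) for n in CYCLIN_A_SPECIES)
    elif channel == "cyclinB_total":
        vals = sum(traj.species(n) for n in CYCLIN_B_SPECIES)
    elif channel == "cycB_cdk1_active":
        vals = traj.species("actCycB")
    else:
        raise ValueError(f"unknown channel {channel!r}; expected one of {_CHANNELS}")
    return ObservableSeries(channel, traj.times.copy(), np.asarray(vals, dtype=float))


def trajectory_observables(traj: Trajectory, normalized: bool = False):
    """All three measured channels, optionally normalized to [0, 1]."""
    out = {}
    for ch in _CHANNELS:
        s = observable_series(traj, ch)
        out[ch] = normalize_zero_one(s) if normalized else s
    return out


def export_observables(traj: Trajectory, path, normalized: bool = False) -> None:
    """Write the observable channels as CSV (time_fraction + 3 channels)."""
    import pandas as pd

    series = trajectory_observables(traj, normalized=normalized)
    df = pd.DataFrame({"time_fraction": traj.times})
    for ch in _CHANNELS:
        df[ch] = series[ch].values
    df.to_csv(path, index=False)
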