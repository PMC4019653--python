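"""Synthetic reference expression profiles.

The generator emulates the qualitative structure of cytometry-derived
cell-cycle expression profiles of an asynchronous K562-like population,
mapped onto cycle-time fraction:

* cyclin A2 — undetectable through G1 (the first ~21% of the cycle),
  then a two-phase rise: approximately linear through S, followed by a
  rapid convex increase in G2, and an abrupt decay early in mitosis;
* cyclin B1 — detectable onset *earlier* than cyclin A2, a nonlinear
  (convex) primary rise through S, a secondary G2 rise steeper than
  cyclin A2's, and a decay that begins *later* in mitosis than A2's;
* PHH3 — a near-step mitotic marker: ~0 until mitotic onset, elevated
  through to cytokinesis;
* DNA content — 2C through G1, ramping to 4C across S, 4C thereafter.

Channels are normalized to [0, 1] on the noiseless backbone (DNA is in
C-equivalents on [2, 4]); measurement noise is additive Gaussian,
truncated at zero, with a seedable generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NonCyclingError, ResetSpec, simulate_cycles
from .observables import mitotic_onset, normalize_zero_one, trajectory_observables
from .params import ParameterSet

__all__ = [
    "PhaseBoundaries",
    "ReferenceDataset",
    "generate_reference_profiles",
    "generate_from_model",
    "check_backbone_shape",
]

CHANNELS = ("cyclinA2", "cyclinB1", "PHH3", "DNA")


@dataclass(frozen=True)
class PhaseBoundaries:
    """Cell-cycle phase boundaries as cycle-time fractions.

    Defaults: G1/S at 0.21 (G1 is 21% of Tc); G2/M at 0.97 (mitosis
    occupies the final ~3% of the cycle); S/G2 at 0.72 — not directly
    measurable from the reference profiles, chosen so S is longer than
    G2 as is typical of transformed lines, and configurable.
    """

    g1s: float = 0.21
    sg2: float = 0.72
    g2m: float = 0.97

    def __post_init__(self):
        if not 0.0 < self.g1s < self.sg2 < self.g2m < 1.0:
            raise ValueError(
                f"phase boundaries must satisfy 0 < g1s < sg2 < g2m < 1, "
                f"got ({self.g1s}, {self.sg2}, {self.g2m})")


@dataclass
class ReferenceDataset:
    """Expression channels on a common cycle-time grid."""

    times: np.ndarray
    cyclinA2: np.ndarray
    cyclinB1: np.ndarray
    PHH3: np.ndarray
    DNA: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None
    boundaries: PhaseBoundaries = field(default_factory=PhaseBoundaries)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for ch in CHANNELS:
            arr = np.asarray(getattr(self, ch), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"channel {ch} shape mismatch")
            setattr(self, ch, arr)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_fraction": self.times,
                             **{ch: getattr(self, ch) for ch in CHANNELS}})


# --------------------------------------------------------------------------
# noiseless backbones
# --------------------------------------------------------------------------

#: value of a channel at its detectable onset, as a fraction of its maximum.
#: Kept just above the 1% detection floor and below cytometric noise.
ONSET_LEVEL = 0.02

#: cyclin B1 detectable onset precedes cyclin A2's by this fraction of Tc
CYCB_ONSET_LEAD = 0.05


def _cyclin_a_backbone(t: np.ndarray, b: PhaseBoundaries,
                       s_level: float = 0.35,
                       decay_delay: float = 0.005,
                       decay_rate: float = 100.0) -> np.ndarray:
    """Baseline 0 in G1; linear through S; convex (quadratic) rapid rise in
    G2; abrupt exponential decay starting just after mitotic onset."""
    y = np.zeros_like(t)
    s = (t >= b.g1s) & (t < b.sg2)
    y[s] = ONSET_LEVEL + (s_level - ONSET_LEVEL) * (t[s] - b.g1s) / (b.sg2 - b.g1s)
    g2 = (t >= b.sg2) & (t < b.g2m)
    u = (t[g2] - b.sg2) / (b.g2m - b.sg2)
    y[g2] = s_level + (1.0 - s_level) * u ** 2
    m_start = b.g2m + decay_delay
    m = (t >= b.g2m) & (t < m_start)
    y[m] = 1.0
    dec = t >= m_start
    y[dec] = np.exp(-decay_rate * (t[dec] - m_start))
    return y


def _cyclin_b_backbone(t: np.ndarray, b: PhaseBoundaries,
                       s_level: float = 0.30,
                       decay_delay: float = 0.020,
                       decay_rate: float = 60.0) -> np.ndarray:
    """Onset earlier than cyclin A2; convex primary rise; steeper G2 rise;
    decay onset strictly later than cyclin A2's."""
    onset = b.g1s - CYCB_ONSET_LEAD
    y = np.zeros_like(t)
    s = (t >= onset) & (t < b.sg2)
    u = (t[s] - onset) / (b.sg2 - onset)
    y[s] = ONSET_LEVEL + (s_level - ONSET_LEVEL) * u ** 2
    g2 = (t >= b.sg2) & (t < b.g2m)
    u = (t[g2] - b.sg2) / (b.g2m - b.sg2)
    y[g2] = s_level + (1.0 - s_level) * u ** 2.5
    m_start = b.g2m + decay_delay
    m = (t >= b.g2m) & (t < m_start)
    y[m] = 1.0
    dec = t >= m_start
    y[dec] = np.exp(-decay_rate * (t[dec] - m_start))
    return y


def _phh3_backbone(t: np.ndarray, b: PhaseBoundaries,
                   width: float = 0.003) -> np.ndarray:
    """Abrupt sigmoidal rise at mitotic onset, elevated through cytokinesis."""
    return 1.0 / (1.0 + np.exp(-(t - b.g2m) / width))


def _dna_backbone(t: np.ndarray, b: PhaseBoundaries) -> np.ndarray:
    """2C through G1, smooth monotone ramp to 4C across S, 4C thereafter."""
    u = np.clip((t - b.g1s) / (b.sg2 - b.g1s), 0.0, 1.0)
    smooth = u * u * (3.0 - 2.0 * u)
    return 2.0 + 2.0 * smooth


def _add_noise(rng: np.random.Generator, y: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0.0:
        return y.copy()
    return np.clip(y + rng.normal(0.0, sd, size=y.shape), 0.0, None)


def generate_reference_profiles(boundaries: PhaseBoundaries | None = None,
                                n_points: int = 501,
                                noise_sd: float = 0.02,
                                seed: int = 0,
                                cyclinA_s_level: float = 0.35,
                                cyclinB_s_level: float = 0.30) -> ReferenceDataset:
    """Generate a K562-style reference dataset on a uniform cycle-time grid.

    Deterministic for a given ``seed``.  ``noise_sd`` is the standard
    deviation of the additive truncated Gaussian noise in normalized
    units (applied to the DNA channel in C-equivalents as well).
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    b = boundaries or PhaseBoundaries()
    t = np.linspace(0.0, 1.0, int(n_points))
    rng = np.random.default_rng(seed)
    return ReferenceDataset(
        times=t,
        cyclinA2=_add_noise(rng, _cyclin_a_backbone(t, b, cyclinA_s_level), noise_sd),
        cyclinB1=_add_noise(rng, _cyclin_b_backbone(t, b, cyclinB_s_level), noise_sd),
        PHH3=_add_noise(rng, _phh3_backbone(t, b), noise_sd),
        DNA=_add_noise(rng, _dna_backbone(t, b), noise_sd),
        noise_sd=noise_sd, seed=seed, boundaries=b,
    )


# --------------------------------------------------------------------------
# model-derived datasets (for parameter-recovery experiments)
# --------------------------------------------------------------------------

def generate_from_model(params: ParameterSet, noise_sd: float = 0.0,
                        seed: int = 0, n_points: int = 501,
                        reset: ResetSpec | None = None) -> ReferenceDataset:
    """Dataset of normalized model observables over one detected cycle.

    The cyclin channels are the normalized totals interpolated onto a
    uniform cycle-fraction grid; PHH3 is the thresholded onset step of
    normalized active CycB:Cdk1.  A DNA ramp is synthesized between the
    cyclin A onset (G1/S surrogate) and the default S/G2 boundary.
    Noise as in :func:`generate_reference_profiles`.  Raises
    :class:`cdkcycle.model.NonCyclingError` if the model does not cycle.
    """
    traj = simulate_cycles(params, n_cycles=1, reset=reset)
    period = traj.periods[0]
    frac = traj.times / period
    obs = trajectory_observables(traj, normalized=True)
    t = np.linspace(0.0, 1.0, int(n_points))
    a = np.interp(t, frac, obs["cyclinA_total"].values)
    bb = np.interp(t, frac, obs["cyclinB_total"].values)
    act = np.interp(t, frac, obs["cycB_cdk1_active"].values)
    onset = mitotic_onset(obs["cycB_cdk1_active"], 0.5)
    onset = 1.0 if onset is None else onset / period
    phh3 = (t >= onset).astype(float)
    # DNA surrogate: ramp from the cyclin A detectable onset to the nominal
    # S/G2 boundary scaled into this cycle
    a_on_idx = np.nonzero(a > 0.01)[0]
    g1s = float(t[a_on_idx[0]]) if a_on_idx.size else 0.21
    b = PhaseBoundaries(g1s=min(max(g1s, 0.01), 0.70), sg2=0.72,
                        g2m=min(max(onset, 0.73), 0.999))
    dna = _dna_backbone(t, b)
    rng = np.random.default_rng(seed)
    return ReferenceDataset(
        times=t,
        cyclinA2=_add_noise(rng, a, noise_sd),
        cyclinB1=_add_noise(rng, bb, noise_sd),
        PHH3=_add_noise(rng, phh3, noise_sd),
        DNA=_add_noise(rng, dna, noise_sd),
        noise_sd=noise_sd, seed=seed, boundaries=b,
    )


# --------------------------------------------------------------------------
# shape-clause checker
# --------------------------------------------------------------------------

def check_backbone_shape(ds: ReferenceDataset, atol: float = 1e-9) -> dict:
    """Assert the qualitative profile features on a *noiseless* dataset.

    Returns a dict of named boolean checks; raises ``AssertionError`` on
    the first violated clause.  Intended for property tests and as a
    guard when generating datasets with nondefault boundaries.
    """
    t, b = ds.times, ds.boundaries
    a, cb, phh3, dna = ds.cyclinA2, ds.cyclinB1, ds.PHH3, ds.DNA
    checks = {}

    def record(name, ok):
        checks[name] = bool(ok)
        assert ok, f"shape clause violated: {name}"

    pre_g1s = t < b.g1s - 1e-12
    record("cyclinA2_baseline_through_G1", np.all(a[pre_g1s] <= atol))
    onset_b = np.nonzero(cb > 0.01 * cb.max())[0][0]
    onset_a = np.nonzero(a > 0.01 * a.max())[0][0]
    record("cyclinB1_onset_before_cyclinA2", t[onset_b] < t[onset_a])

    def max_slope(y, lo, hi):
        m = (t >= lo) & (t <= hi)
        return np.max(np.diff(y[m]) / np.diff(t[m]))

    record("cyclinA2_biphasic_rise",
           max_slope(a, b.sg2, b.g2m) > 2.0 * max_slope(a, b.g1s + 0.01, b.sg2))
    record("cyclinB1_G2_steeper_than_cyclinA2",
           max_slope(cb, b.sg2, b.g2m) > max_slope(a, b.sg2, b.g2m))

    def decay_start(y):
        ipk = int(np.argmax(y))
        below = np.nonzero(y[ipk:] < 0.99 * y[ipk])[0]
        return t[ipk + below[0]] if below.size else np.inf

    record("cyclinB1_decays_after_cyclinA2", decay_start(cb) > decay_start(a))
    record("PHH3_low_before_G2M", np.all(phh3[t < b.g2m - 0.02] < 0.05))
    record("PHH3_elevated_through_M", np.all(phh3[t > b.g2m + 0.02] > 0.95))
    record("DNA_2C_in_G1", np.all(np.abs(dna[pre_g1s] - 2.0) < 1e-6))
    record("DNA_4C_after_S", np.all(np.abs(dna[t > b.sg2] - 4.0) < 1e-6))
    record("DNA_monotone_through_S", np.all(np.diff(dna) >= -1e-12))
    return checks
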