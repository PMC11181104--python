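"""Circular phase metrics: PLV/PE, phase stationarity, and P1-alpha alignment.

All angles in this package follow the cosine convention in degrees: 0 deg is
the oscillation peak, 180 deg the trough, and every reported angle lies in
[0, 360). Signed circular differences are wrapped to (-180, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_RESULTANT_FLOOR = 1e-12


def wrap360(angles):
    """Wrap angles (degrees) into [0, 360)."""
    return np.asarray(angles, dtype=float) % 360.0


def wrap180(angles):
    """Wrap angles (degrees) into (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


def circular_mean_deg(angles) -> float:
    """Direction of the mean resultant vector, in [0, 360); nan if undefined."""
    z = np.exp(1j * np.radians(np.asarray(angles, dtype=float)))
    m = z.mean()
    if np.abs(m) < _RESULTANT_FLOOR:
        return float("nan")
    return float(np.degrees(np.angle(m)) % 360.0)


def resultant_length(angles) -> float:
    z = np.exp(1j * np.radians(np.asarray(angles, dtype=float)))
    return float(np.abs(z.mean()))


def circular_sd_deg(angles) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    r = resultant_length(angles)
    if r <= 0.0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(min(r, 1.0)))))


def circular_separation(a: float, b: float) -> float:
    """Unsigned circular distance between two angles in degrees, in [0, 180]."""
    return float(np.abs(wrap180(a - b)))


def angular_lead(phase: float, reference: float = 0.0) -> float:
    """Angular lead of ``phase`` to the next occurrence of ``reference``.

    Under the cosine convention a phase advancing at the alpha rate reaches the
    reference angle after ``(reference - phase) mod 360`` further degrees of
    rotation; e.g. a mean onset phase of 308 deg leads the true peak (0/360
    deg) by 52 deg.
    """
    return float((reference - phase) % 360.0)


@dataclass
class CircularSample:
    """A sample of angles in degrees, wrapped into [0, 360)."""

    angles: np.ndarray

    def __post_init__(self):
        self.angles = wrap360(np.atleast_1d(np.asarray(self.angles, dtype=float)))

    def __len__(self) -> int:
        return self.angles.size

    @property
    def resultant(self) -> float:
        return resultant_length(self.angles)

    @property
    def mean_direction(self) -> float:
        """Circular mean in [0, 360); nan when the resultant vanishes."""
        return circular_mean_deg(self.angles)

    @property
    def sd(self) -> float:
        return circular_sd_deg(self.angles)

    def differences(self, other) -> np.ndarray:
        """Signed circular differences self - other, wrapped to (-180, 180]."""
        other_angles = other.angles if isinstance(other, CircularSample) else other
        return wrap180(self.angles - np.asarray(other_angles, dtype=float))


@dataclass
class PhaseLocking:
    plv: float
    pe_deg: float
    n_trials: int
    pe_defined: bool = True


def phase_locking_metrics(actual, target) -> PhaseLocking:
    """Phase-locking value and phase error of delivered vs. target phases.

    ``plv`` is the resultant length of the per-trial circular errors
    Delta = actual - target; ``pe_deg`` is their circular mean, signed as
    actual - target (negative means the stimulus fired early) and wrapped to
    (-180, 180]. With a vanishing resultant the phase error is undefined and
    flagged.
    """
    actual = np.atleast_1d(np.asarray(
        actual.angles if isinstance(actual, CircularSample) else actual, dtype=float))
    target = np.asarray(
        target.angles if isinstance(target, CircularSample) else target, dtype=float)
    target = np.broadcast_to(np.atleast_1d(target), actual.shape)
    if actual.size < 1:
        raise ValueError("phase_locking_metrics needs at least one trial")
    delta = np.radians(actual - target)
    m = np.exp(1j * delta).mean()
    plv = float(np.abs(m))
    if plv < _RESULTANT_FLOOR:
        return PhaseLocking(plv=plv, pe_deg=float("nan"),
                            n_trials=actual.size, pe_defined=False)
    pe = float(wrap180(np.degrees(np.angle(m))))
    return PhaseLocking(plv=plv, pe_deg=pe, n_trials=actual.size)


def circ_corr(a, b) -> float:
    """Circular-circular correlation coefficient (Jammalamadaka & SenGupta).

    r = sum sin(a - abar) sin(b - bbar) / sqrt(sum sin^2 (a - abar) *
    sum sin^2 (b - bbar)); angles in degrees. Returns nan (with a warning) for
    constant samples, where the coefficient is undefined.
    """
    a = np.radians(np.asarray(a, dtype=float))
    b = np.radians(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("samples must have matching lengths")
    abar = np.angle(np.exp(1j * a).mean())
    bbar = np.angle(np.exp(1j * b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom < _RESULTANT_FLOOR:
        warnings.warn("circular correlation undefined for (near-)constant angles")
        return float("nan")
    return float(np.sum(sa * sb) / denom)


@dataclass
class StationarityResult:
    correlation: float           # group value in [0, 1]
    per_subject: np.ndarray      # |r| per subject
    n_undefined: int = 0


def phase_stationarity(pre, post) -> StationarityResult:
    """Correlation between pre- and post-stimulus alpha half-cycle phases.

    ``pre`` and ``post`` are matched per-trial phase samples (degrees), or
    sequences of such samples (one per subject). Per subject the circular
    correlation is computed, Fisher z-transformed, and its absolute value
    taken so each subject contributes a value in [0, 1]; subject values are
    averaged in z-space and transformed back.
    """
    pre_list, post_list = _as_subject_lists(pre, post)
    rs = []
    n_undef = 0
    for p, q in zip(pre_list, post_list):
        r = circ_corr(p, q)
        if np.isnan(r):
            n_undef += 1
            continue
        rs.append(abs(r))
    if not rs:
        return StationarityResult(float("nan"), np.array([]), n_undefined=n_undef)
    rs = np.clip(np.asarray(rs), 0.0, 1.0 - 1e-12)
    group = float(np.tanh(np.mean(np.arctanh(rs))))
    return StationarityResult(group, rs, n_undefined=n_undef)


def _as_subject_lists(pre, post):
    pre0 = np.asarray(pre[0]) if len(pre) else np.array([])
    if pre0.ndim == 0:  # single subject given as flat arrays
        return [np.asarray(pre, dtype=float)], [np.asarray(post, dtype=float)]
    if len(pre) != len(post):
        raise ValueError("pre and post must have matching subject counts")
    return [np.asarray(p, dtype=float) for p in pre], \
           [np.asarray(q, dtype=float) for q in post]


@dataclass
class P1Alignment:
    """Alignment of the P1 potential with the post-stimulus alpha phase."""

    mean_phase_deg: float
    sd_deg: float
    lead_deg: float              # angular lead to the expected landmark
    reference_deg: float         # 0 (peak) for trough delivery, 180 for peak
    n_trials: int
    n_excluded: int = 0
    per_trial: np.ndarray = field(default_factory=lambda: np.array([]))


_P1_REFERENCE = {"trough": 0.0, "peak": 180.0}


def p1_phase_alignment(trial_phases, condition: str) -> P1Alignment:
    """Circular summary of the alpha phase coinciding with the P1 latency.

    ``trial_phases`` holds, per trial, the (causally estimated) alpha phase at
    t = P1 latency after sound onset. For trough-locked delivery the P1 is
    expected near the true peak (0 deg); for peak-locked delivery near the
    true trough (180 deg). The reported lead is the angular distance the phase
    still has to advance to reach that landmark.
    """
    if condition not in _P1_REFERENCE:
        raise ValueError(f"condition must be 'trough' or 'peak', got {condition!r}")
    phases = np.asarray(trial_phases, dtype=float)
    valid = np.isfinite(phases)
    n_excluded = int((~valid).sum())
    phases = wrap360(phases[valid])
    if phases.size == 0:
        raise ValueError("no trials with a defined phase at the P1 latency")
    ref = _P1_REFERENCE[condition]
    mean = circular_mean_deg(phases)
    return P1Alignment(
        mean_phase_deg=mean,
        sd_deg=circular_sd_deg(phases),
        lead_deg=angular_lead(mean, ref),
        reference_deg=ref,
        n_trials=phases.size,
        n_excluded=n_excluded,
        per_trial=phases,
    )


def phase_at_latency(phase: np.ndarray, onsets: Sequence[int],
                     latency: float, fs: float) -> np.ndarray:
    """Per-trial phase (degrees) at ``latency`` seconds after each onset sample.

    ``phase`` is a per-sample phase series over the continuous recording (nan
    where undefined, e.g. during tracker warm-up). Trials whose lookup sample
    falls outside the series yield nan.
    """
    phase = np.asarray(phase, dtype=float)
    idx = np.asarray(onsets, dtype=int) + int(round(latency * fs))
    out = np.full(idx.shape, np.nan)
    ok = (idx >= 0) & (idx < phase.size)
    out[ok] = phase[idx[ok]]
    return out
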