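"""Virtual-subject EEG generator with ground-truth alpha phase.

Emulates the three task regimes of the closed-loop experiment: an eyes-closed
baseline with strong alpha, a random-phase task with low alpha, and a
trough/peak phase-locked task with high alpha and slow quasiperiodic sound
delivery. Signals are a 1/f aperiodic background plus a narrowband alpha
oscillator at a configurable individual alpha frequency (IAF); the oscillator's
instantaneous phase (cosine convention, degrees) is carried alongside the
signal as ground truth, so every downstream phase estimate can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .phase_metrics import wrap360

DEFAULT_FS = 501.0
IAF_RANGE = (7.5, 16.0)
BASELINE_S = 30.0

# ISI grids (seconds): discrete uniform draws at the stated increment.
ISI_GRIDS = {
    "random": np.round(np.arange(0.878, 1.634 + 1e-9, 0.001), 3),
    "trough_peak": np.round(np.arange(1.628, 1.650 + 1e-9, 0.010), 3),
}

CONDITIONS = ("trough", "peak", "random")


@dataclass
class Recording:
    """Continuous multichannel EEG-like recording in microvolts.

    ``truth_phase`` (per channel, degrees in [0, 360)) and ``truth_iaf`` are
    only present for synthetic data and carry the hidden oscillator state.
    """

    signal: np.ndarray                      # (n_channels, n_samples)
    fs: float = DEFAULT_FS
    channels: tuple = ("Fpz",)
    truth_phase: np.ndarray | None = None   # (n_channels, n_samples)
    truth_iaf: float | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError("channel labels must match signal rows")
        if self.truth_phase is not None:
            self.truth_phase = np.atleast_2d(np.asarray(self.truth_phase, dtype=float))
            if self.truth_phase.shape != self.signal.shape:
                raise ValueError("truth_phase must match the signal shape")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class EventTable:
    """Stimulus onsets with condition labels and target/true/estimated phases.

    Phases are degrees in [0, 360); nan marks an absent value (e.g. the true
    phase of a non-synthetic recording). Onsets are strictly increasing sample
    indices.
    """

    onset_sample: np.ndarray
    condition: np.ndarray
    target_phase: np.ndarray | None = None
    true_phase: np.ndarray | None = None
    estimated_phase: np.ndarray | None = None
    flagged: np.ndarray | None = None

    def __post_init__(self):
        self.onset_sample = np.asarray(self.onset_sample, dtype=int)
        self.condition = np.asarray(self.condition, dtype=object)
        n = self.onset_sample.size
        if self.condition.size != n:
            raise ValueError("condition must match onset count")
        if n > 1 and np.any(np.diff(self.onset_sample) <= 0):
            raise ValueError("onsets must be strictly increasing")
        for name in ("target_phase", "true_phase", "estimated_phase"):
            val = getattr(self, name)
            if val is None:
                setattr(self, name, np.full(n, np.nan))
            else:
                val = np.asarray(val, dtype=float)
                if val.size != n:
                    raise ValueError(f"{name} must match onset count")
                finite = np.isfinite(val)
                val[finite] = wrap360(val[finite])
                setattr(self, name, val)
        self.flagged = (np.zeros(n, dtype=bool) if self.flagged is None
                        else np.asarray(self.flagged, dtype=bool))

    def __len__(self) -> int:
        return self.onset_sample.size

    def select(self, condition: str) -> "EventTable":
        return self.subset(self.condition == condition)

    def subset(self, mask) -> "EventTable":
        mask = np.asarray(mask)
        return EventTable(
            onset_sample=self.onset_sample[mask],
            condition=self.condition[mask],
            target_phase=self.target_phase[mask],
            true_phase=self.true_phase[mask],
            estimated_phase=self.estimated_phase[mask],
            flagged=self.flagged[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(len(self)),
            "onset_sample": self.onset_sample,
            "condition": self.condition,
            "target_phase_deg": self.target_phase,
            "estimated_phase_deg": self.estimated_phase,
            "true_phase_deg": self.true_phase,
            "flagged": self.flagged.astype(int),
        })


# ---------------------------------------------------------------------------
# Evoked-response templates

#: Component search windows in seconds, shared with the ERP module.
COMPONENT_WINDOWS = {
    "Pa": (0.001, 0.045),
    "P1": (0.045, 0.080),
    "N1": (0.080, 0.150),
    "P2": (0.150, 0.220),
    "N2": (0.220, 0.400),
}

_POSITIVE = {"Pa", "P1", "P2"}


@dataclass
class ErpTemplate:
    """Stereotyped auditory evoked response as a sum of component deflections.

    Each component is a half-cosine under a Gaussian taper: peak value equals
    the signed amplitude at the component latency, with support |t - latency|
    <= width. ``phase_gain`` maps condition -> per-component multiplicative
    gain, which is how the generator injects alpha-phase-dependent modulation.
    """

    latency: Mapping[str, float]       # s
    amplitude: Mapping[str, float]     # µV, signed
    width: Mapping[str, float]         # s (half-support)
    phase_gain: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        names = list(COMPONENT_WINDOWS)
        lats = [self.latency[c] for c in names]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("component latencies must be strictly increasing")
        for c in names:
            lo, hi = COMPONENT_WINDOWS[c]
            if not lo <= self.latency[c] <= hi:
                raise ValueError(f"{c} latency outside its window {lo}-{hi} s")
            amp = self.amplitude[c]
            if c in _POSITIVE and amp < 0:
                raise ValueError(f"{c} amplitude must be >= 0")
            if c not in _POSITIVE and amp > 0:
                raise ValueError(f"{c} amplitude must be <= 0")

    @property
    def support(self) -> float:
        """Duration from stimulus onset to the end of the last deflection."""
        return max(self.latency[c] + self.width[c] for c in COMPONENT_WINDOWS)

    def gain(self, condition: str, component: str) -> float:
        return float(self.phase_gain.get(condition, {}).get(component, 1.0))

    def waveform(self, fs: float, condition: str = "random",
                 duration: float | None = None) -> np.ndarray:
        """Sampled post-onset response for one condition (first sample = t 0)."""
        duration = self.support if duration is None else duration
        t = np.arange(int(round(duration * fs)) + 1) / fs
        out = np.zeros_like(t)
        for c in COMPONENT_WINDOWS:
            lat, amp, w = self.latency[c], self.amplitude[c], self.width[c]
            amp = amp * self.gain(condition, c)
            u = t - lat
            m = np.abs(u) <= w
            sigma = w / 2.0
            out[m] += amp * np.cos(np.pi * u[m] / (2 * w)) * \
                np.exp(-u[m] ** 2 / (2 * sigma**2))
        return out


def default_template() -> ErpTemplate:
    """Template with component latencies/amplitudes at realistic adult values
    and trough/peak gains reproducing the reported phase-dependent modulation
    (Pa smaller, P1/N1/P2 larger for trough vs. peak delivery)."""
    return ErpTemplate(
        latency={"Pa": 0.025, "P1": 0.060, "N1": 0.102, "P2": 0.160, "N2": 0.260},
        amplitude={"Pa": 1.5, "P1": 2.0, "N1": -0.9, "P2": 2.4, "N2": -0.9},
        width={"Pa": 0.012, "P1": 0.015, "N1": 0.022, "P2": 0.028, "N2": 0.060},
        phase_gain={
            "trough": {"Pa": 1.69, "P1": 1.57, "N1": 2.71, "P2": 1.50, "N2": 2.33},
            "peak": {"Pa": 2.30, "P1": 0.61, "N1": 1.13, "P2": 1.04, "N2": 2.57},
        },
    )


# ---------------------------------------------------------------------------
# Background synthesis


def _powerlaw_noise(n: int, exponent: float, rms: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f^exponent, given RMS."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def make_background(duration: float, fs: float = DEFAULT_FS, *,
                    iaf: float = 10.0, alpha_amp: float = 8.0,
                    aperiodic_exponent: float = 1.0, noise_amp: float = 3.0,
                    seed: int = 0, phase0: float | None = None,
                    envelope_mod_depth: float = 0.0,
                    envelope_mod_freq: float = 0.1,
                    fz_scale: float | None = None,
                    fz_lag_deg: float = 10.0) -> Recording:
    """Generate a background recording: 1/f noise plus an alpha oscillator.

    The oscillator is ``alpha_amp * cos(phase(t))`` with phase advancing at
    360 * iaf deg/s from a seed-drawn (or given) start phase; the unwrapped
    phase is stored as ground truth. ``envelope_mod_depth`` > 0 adds a slow
    sinusoidal waxing/waning of the alpha amplitude (off by default so tests
    stay deterministic in amplitude). When ``fz_scale`` is given, a second
    channel "Fz" is added as a scaled copy of Fpz lagging by ``fz_lag_deg``
    degrees of alpha phase, mimicking the small inter-electrode phase shift.
    """
    for name, val in [("duration", duration), ("fs", fs), ("iaf", iaf),
                      ("alpha_amp", alpha_amp), ("noise_amp", noise_amp),
                      ("aperiodic_exponent", aperiodic_exponent)]:
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not IAF_RANGE[0] <= iaf <= IAF_RANGE[1]:
        raise ValueError(f"iaf must lie in {IAF_RANGE}, got {iaf}")
    if alpha_amp < 0 or noise_amp < 0:
        raise ValueError("amplitudes must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    start = rng.uniform(0.0, 360.0) if phase0 is None else float(phase0)
    phase = (start + 360.0 * iaf * t) % 360.0
    env = 1.0 + envelope_mod_depth * np.sin(2 * np.pi * envelope_mod_freq * t)
    alpha = alpha_amp * env * np.cos(np.radians(phase))
    sig = alpha + _powerlaw_noise(n, aperiodic_exponent, noise_amp, rng)

    if fz_scale is None:
        return Recording(signal=sig[None, :], fs=fs, channels=("Fpz",),
                         truth_phase=phase[None, :], truth_iaf=iaf)

    lag = int(round(fz_lag_deg / (360.0 * iaf) * fs))
    fz = fz_scale * np.roll(sig, lag)
    fz_phase = (phase - fz_lag_deg) % 360.0
    return Recording(signal=np.vstack([sig, fz]), fs=fs,
                     channels=("Fpz", "Fz"),
                     truth_phase=np.vstack([phase, fz_phase]), truth_iaf=iaf)


def schedule_events(task: str, duration: float, seed: int = 0, *,
                    baseline: float = BASELINE_S,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw stimulus onset times (seconds) for one task run.

    ISIs come from the task's discrete uniform grid: 878-1,634 ms at 1 ms
    increments for the random-phase task, 1,628-1,650 ms at 10 ms increments
    for the trough/peak task. The first onset falls one ISI after the
    baseline; all onsets lie before ``duration``.
    """
    if task not in ISI_GRIDS:
        raise ValueError(f"task must be one of {sorted(ISI_GRIDS)}, got {task!r}")
    if duration < baseline:
        raise ValueError("duration must cover at least the baseline")
    rng = np.random.default_rng(seed) if rng is None else rng
    grid = ISI_GRIDS[task]
    onsets = []
    t = baseline + float(rng.choice(grid))
    while t < duration:
        onsets.append(t)
        t += float(rng.choice(grid))
    if not onsets:
        warnings.warn("duration too short to schedule any event")
    return np.asarray(onsets)


def embed_responses(rec: Recording, events: EventTable,
                    template: ErpTemplate | None = None) -> Recording:
    """Add the evoked-response template at each event onset (all channels).

    Component amplitudes are scaled by the template's per-condition phase
    gain. Events whose response would run past the end of the recording are
    dropped (with a warning). The ground-truth oscillator phase at each kept
    onset is written into ``events.true_phase`` in place.
    """
    template = default_template() if template is None else template
    sig = rec.signal.copy()
    support_n = int(round(template.support * rec.fs)) + 1
    keep = events.onset_sample + support_n <= rec.n_samples
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} event(s) past recording end")
    waveforms = {c: template.waveform(rec.fs, c) for c in set(events.condition)}
    for onset, cond, kept in zip(events.onset_sample, events.condition, keep):
        if not kept:
            continue
        w = waveforms[cond]
        sig[:, onset:onset + w.size] += w[None, :]
    if rec.truth_phase is not None:
        events.true_phase[:] = np.where(
            keep, rec.truth_phase[0, np.clip(events.onset_sample, 0,
                                             rec.n_samples - 1)], np.nan)
    events.flagged |= ~keep
    return replace(rec, signal=sig)


def _snap_to_phase(truth_phase: np.ndarray, start: int, target: float,
                   fs: float, iaf: float) -> int:
    """First sample at/after ``start`` where the truth phase reaches target."""
    # phase advances 360*iaf/fs deg/sample; search one full cycle
    span = int(np.ceil(fs / iaf)) + 2
    seg = truth_phase[start:start + span]
    if seg.size == 0:
        return -1
    dphi = (target - seg) % 360.0
    step = 360.0 * iaf / fs
    hits = np.flatnonzero(dphi <= step / 2.0 + 1e-9)
    if hits.size:
        return start + int(hits[0])
    return start + int(np.argmin(dphi))


def generate_dataset(profile, task: str, duration: float, seed: int = 0, *,
                     fs: float = DEFAULT_FS, alpha_amp: float | None = None,
                     noise_amp: float = 3.0, aperiodic_exponent: float = 1.0,
                     template: ErpTemplate | None = None,
                     delivery: str = "ideal", baseline: float = BASELINE_S,
                     fz_scale: float | None = 0.8,
                     embed: bool = True) -> tuple[Recording, EventTable]:
    """Compose a full virtual-subject task run with known ground truth.

    ``profile`` is a :class:`~alphalock.targeting.SubjectProfile`. The
    trough/peak task uses high alpha amplitude with trough/peak conditions
    randomly interleaved at the subject's individualized target phases; the
    random task uses low alpha with a uniform random target per trial
    (mirroring the task-dependent prestimulus alpha levels of the paradigm).
    ``delivery='ideal'`` snaps each scheduled onset to the next ground-truth
    occurrence of the target phase — a perfect phase-locking device; use the
    closed-loop tracker in :mod:`alphalock.echt` for realistic delivery.
    """
    if task not in ISI_GRIDS:
        raise ValueError(f"task must be one of {sorted(ISI_GRIDS)}, got {task!r}")
    if delivery not in ("ideal", "scheduled"):
        raise ValueError("delivery must be 'ideal' or 'scheduled'")
    if alpha_amp is None:
        alpha_amp = 8.0 if task == "trough_peak" else 1.5
    rng = np.random.default_rng(seed)
    rec = make_background(duration, fs, iaf=profile.iaf, alpha_amp=alpha_amp,
                          aperiodic_exponent=aperiodic_exponent,
                          noise_amp=noise_amp,
                          seed=int(rng.integers(2**31 - 1)),
                          fz_scale=fz_scale)
    onsets_s = schedule_events(task, duration, rng=rng, baseline=baseline)
    n_ev = onsets_s.size
    if task == "trough_peak":
        conds = rng.permuted(
            np.array(["trough", "peak"], dtype=object)[np.arange(n_ev) % 2])
        targets = np.where(conds == "trough", profile.trough_onset_phase,
                           profile.peak_onset_phase).astype(float)
    else:
        conds = np.full(n_ev, "random", dtype=object)
        targets = rng.uniform(0.0, 360.0, size=n_ev)

    onset_samples = np.round(onsets_s * fs).astype(int)
    if delivery == "ideal":
        snapped = []
        for s, tgt in zip(onset_samples, targets):
            s2 = _snap_to_phase(rec.truth_phase[0], s, tgt, fs, profile.iaf)
            snapped.append(s2 if s2 >= 0 else s)
        onset_samples = np.asarray(snapped, dtype=int)
    ok = np.ones(n_ev, dtype=bool)
    ok[1:] = np.diff(onset_samples) > 0
    events = EventTable(onset_sample=onset_samples[ok], condition=conds[ok],
                        target_phase=targets[ok])
    if embed:
        rec = embed_responses(rec, events, template)
    elif rec.truth_phase is not None:
        events.true_phase[:] = rec.truth_phase[0, events.onset_sample]
    return rec, events
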