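"""Individualized trough/peak sound-onset phase targeting.

The target onset phase is chosen so that the auditory P1 potential, arriving
``p1_latency`` seconds after sound onset while the alpha phase advances at the
individual alpha frequency (IAF), lands on the true peak (0 deg, trough-locked
delivery) or the true trough (180 deg, peak-locked delivery):

    onset_phase_trough = mod(-360 * p1_latency * IAF, 360)
    onset_phase_peak   = mod(onset_phase_trough + 180, 360)

All angles are cosine-convention degrees in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

_LATENCY_MAX = 0.2  # s; generous upper bound, typical P1 latencies are 45-80 ms


def onset_phase(iaf: float, p1_latency: float, mode: str = "trough") -> float:
    """Individualized sound-onset phase in degrees, in [0, 360).

    Parameters
    ----------
    iaf : individual alpha frequency in Hz (> 0).
    p1_latency : P1 component latency in seconds (0 <= latency <= 0.2).
    mode : "trough" aligns the P1 to the following alpha peak; "peak" is the
        same phase advanced by 180 deg, aligning the P1 to the trough.
    """
    if not np.isfinite(iaf) or iaf <= 0:
        raise ValueError(f"iaf must be positive and finite, got {iaf}")
    if not np.isfinite(p1_latency) or not 0.0 <= p1_latency <= _LATENCY_MAX:
        raise ValueError(
            f"p1_latency must lie in [0, {_LATENCY_MAX}] s, got {p1_latency}")
    if mode not in ("trough", "peak"):
        raise ValueError(f"mode must be 'trough' or 'peak', got {mode!r}")
    phase = (-360.0 * p1_latency * iaf) % 360.0
    if mode == "peak":
        phase = (phase + 180.0) % 360.0
    return float(phase)


@dataclass
class SubjectProfile:
    """Per-subject parameters driving the closed-loop run.

    The trough/peak onset phases are derived from IAF and P1 latency at
    construction unless given explicitly.
    """

    iaf: float
    p1_latency: float
    trough_onset_phase: float = field(default=None)  # type: ignore[assignment]
    peak_onset_phase: float = field(default=None)    # type: ignore[assignment]

    def __post_init__(self):
        if self.trough_onset_phase is None:
            self.trough_onset_phase = onset_phase(self.iaf, self.p1_latency,
                                                  "trough")
        if self.peak_onset_phase is None:
            self.peak_onset_phase = onset_phase(self.iaf, self.p1_latency,
                                                "peak")
        self.trough_onset_phase = float(self.trough_onset_phase) % 360.0
        self.peak_onset_phase = float(self.peak_onset_phase) % 360.0
        sep = (self.peak_onset_phase - self.trough_onset_phase) % 360.0
        if not np.isclose(sep, 180.0):
            raise ValueError("peak phase must be trough phase + 180 (mod 360)")

    def target(self, condition: str) -> float:
        return {"trough": self.trough_onset_phase,
                "peak": self.peak_onset_phase}[condition]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "iaf_hz": float(self.iaf),
            "p1_latency_s": float(self.p1_latency),
            "trough_phase_deg": float(self.trough_onset_phase),
            "peak_phase_deg": float(self.peak_onset_phase),
        }, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SubjectProfile":
        d = yaml.safe_load(Path(path).read_text())
        return cls(iaf=d["iaf_hz"], p1_latency=d["p1_latency_s"],
                   trough_onset_phase=d.get("trough_phase_deg"),
                   peak_onset_phase=d.get("peak_phase_deg"))
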