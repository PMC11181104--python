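"""Plain-text persistence for recordings, events, and spectral arrays.

Recordings use a two-file exchange format: ``<prefix>_signal.tsv`` holds one
column per channel (µV, one row per sample; ground-truth phase columns are
appended as ``phase_<channel>_deg`` when present) and ``<prefix>_meta.json``
holds the sampling rate, channel order, and oscillator ground truth. Event
tables are single TSV files with the documented column set. Spectral arrays
are persisted as ``.npy`` with a JSON sidecar carrying axes and units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import EventTable, Recording

EVENT_COLUMNS = ["trial", "onset_sample", "condition", "target_phase_deg",
                 "estimated_phase_deg", "true_phase_deg", "flagged"]


def save_recording(rec: Recording, prefix) -> tuple[Path, Path]:
    """Write a recording to ``<prefix>_signal.tsv`` + ``<prefix>_meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cols = {ch: rec.signal[i] for i, ch in enumerate(rec.channels)}
    if rec.truth_phase is not None:
        for i, ch in enumerate(rec.channels):
            cols[f"phase_{ch}_deg"] = rec.truth_phase[i]
    signal_path = prefix.with_name(prefix.name + "_signal.tsv")
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    pd.DataFrame(cols).to_csv(signal_path, sep="\t", index=False,
                              float_format="%.6g")
    meta = {"fs_hz": rec.fs, "channels": list(rec.channels),
            "truth_iaf_hz": rec.truth_iaf,
            "has_truth_phase": rec.truth_phase is not None,
            "units": "uV"}
    meta_path.write_text(json.dumps(meta, indent=1))
    return signal_path, meta_path


def load_recording(prefix) -> Recording:
    prefix = Path(prefix)
    meta = json.loads(
        prefix.with_name(prefix.name + "_meta.json").read_text())
    df = pd.read_csv(prefix.with_name(prefix.name + "_signal.tsv"), sep="\t")
    channels = tuple(meta["channels"])
    signal = np.vstack([df[ch].to_numpy() for ch in channels])
    truth = None
    if meta.get("has_truth_phase"):
        truth = np.vstack([df[f"phase_{ch}_deg"].to_numpy()
                           for ch in channels])
    return Recording(signal=signal, fs=meta["fs_hz"], channels=channels,
                     truth_phase=truth, truth_iaf=meta.get("truth_iaf_hz"))


def save_events(events: EventTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_frame()[EVENT_COLUMNS].to_csv(path, sep="\t", index=False,
                                            float_format="%.4f")
    return path


def load_events(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(
        onset_sample=df["onset_sample"].to_numpy(),
        condition=df["condition"].to_numpy(dtype=object),
        target_phase=df["target_phase_deg"].to_numpy(),
        true_phase=df["true_phase_deg"].to_numpy(),
        estimated_phase=df["estimated_phase_deg"].to_numpy(),
        flagged=df["flagged"].to_numpy(dtype=bool),
    )


def save_array(arr, path, **axes) -> tuple[Path, Path]:
    """Persist an array with a JSON sidecar listing its axes (e.g. freqs,
    times) and units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), np.asarray(arr))
    sidecar = {k: (np.asarray(v).tolist() if not isinstance(v, str) else v)
               for k, v in axes.items()}
    sidecar["shape"] = list(np.asarray(arr).shape)
    side_path = path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar))
    return path.with_suffix(".npy"), side_path


def save_psd(curve, path) -> Path:
    """PSD curve TSV: freq_hz, power, detrended_power, method."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    det = (curve.detrended_power if curve.detrended_power is not None
           else np.full_like(curve.power, np.nan))
    pd.DataFrame({"freq_hz": curve.freqs, "power": curve.power,
                  "detrended_power": det,
                  "method": curve.method or ""}).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
    return path
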