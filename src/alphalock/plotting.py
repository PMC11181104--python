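"""Minimal plotting helpers: radial phase histograms and ERP/ERO curves."""

from __future__ import annotations

import numpy as np

from .phase_metrics import circular_mean_deg, resultant_length


def plot_phase_histogram(angles_deg, ax=None, bin_deg: float = 20.0,
                         color="C0", label=None):
    """Polar histogram of phases (cosine convention: 0 deg = peak at the
    right, angles counterclockwise) with the mean resultant vector overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(angles, bins=edges)
    centers = np.radians(edges[:-1] + bin_deg / 2.0)
    ax.bar(centers, counts, width=np.radians(bin_deg), alpha=0.5,
           color=color, label=label)
    mean = circular_mean_deg(angles)
    if np.isfinite(mean):
        r = resultant_length(angles) * max(counts.max(), 1)
        ax.annotate("", xy=(np.radians(mean), r), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="-|>", color=color, lw=2))
    return ax


def plot_erp(times, erps: dict, ax=None, components=None):
    """Overlay condition ERPs (times in s, amplitudes in µV); optionally
    shade component windows."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, erp in erps.items():
        ax.plot(times, erp, label=cond)
    if components:
        for lo, hi in components.values():
            ax.axvspan(lo, hi, color="0.9", zorder=0)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (µV)")
    ax.legend()
    return ax
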