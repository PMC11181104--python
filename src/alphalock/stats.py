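"""Nonparametric statistics: cluster-based permutation tests, circular tests,
the Wald-Wolfowitz runs test, and Benjamini-Hochberg adjustment.

The cluster permutation test follows the within-subject label-swap scheme:
for each of ``n_perm`` iterations the paired condition means are swapped
randomly per subject, the observed mean difference is z-scored against the
resulting permutation distribution per point, and contiguous supra-threshold
runs form clusters. The corrected cluster threshold is the 95th percentile of
per-permutation maximum cluster sizes; observed clusters above it are
significant, controlling the family-wise error rate at ~0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pingouin
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ClusterResult:
    observed_z: np.ndarray
    pointwise_p: np.ndarray
    cluster_masks: np.ndarray        # True where in a significant cluster
    cluster_threshold: float         # corrected size threshold (95th pct)
    clusters: list = field(default_factory=list)  # (start, stop, size) runs
    n_permutations: int = 0
    seed: int | None = None


def _run_lengths_2d(supra: np.ndarray) -> np.ndarray:
    """Max run length of True per row of a 2-D boolean array."""
    n_rows, n_cols = supra.shape
    run = np.zeros(n_rows, dtype=np.int64)
    best = np.zeros(n_rows, dtype=np.int64)
    for j in range(n_cols):
        run = (run + 1) * supra[:, j]
        np.maximum(best, run, out=best)
    return best


def _observed_clusters(supra: np.ndarray, weight: np.ndarray | None = None):
    """Contiguous True runs as (start, stop, size) with optional mass weight."""
    padded = np.concatenate([[False], supra, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    out = []
    for s, e in zip(edges[::2], edges[1::2]):
        size = float(e - s) if weight is None else float(weight[s:e].sum())
        out.append((int(s), int(e), size))
    return out


def cluster_permutation(cond_a, cond_b, n_perm: int = 1000,
                        voxel_alpha: float = 0.05, seed: int | None = None,
                        stat: str = "extent") -> ClusterResult:
    """Paired cluster-based permutation test on subject x point matrices.

    ``cond_a`` and ``cond_b`` are (n_subjects, n_points) subject-level
    averages for the two conditions (points may be a flattened
    time-frequency grid, in which case cluster contiguity is along the
    flattened axis). ``stat='extent'`` sizes clusters by their point count;
    ``'mass'`` by the summed |z| inside the cluster.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conditions must share shape")
    if a.shape[0] < 2:
        raise ValueError("paired cluster test needs >= 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation distribution")
    if stat not in ("extent", "mass"):
        raise ValueError("stat must be 'extent' or 'mass'")
    rng = np.random.default_rng(seed)
    diffs = a - b                                   # (n_subj, T)
    n_subj, n_pts = diffs.shape
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    perm = signs @ diffs / n_subj                   # (n_perm, T)
    obs = diffs.mean(axis=0)
    mu = perm.mean(axis=0)
    sd = perm.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z_obs = np.where(sd > 0, (obs - mu) / safe, 0.0)
    z_perm = np.where(sd > 0, (perm - mu) / safe, 0.0)
    pointwise_p = (1.0 + np.sum(np.abs(z_perm) >= np.abs(z_obs), axis=0)) \
        / (n_perm + 1.0)
    z_crit = scipy.stats.norm.ppf(1.0 - voxel_alpha / 2.0)
    supra_obs = np.abs(z_obs) > z_crit
    supra_perm = np.abs(z_perm) > z_crit
    if stat == "extent":
        max_sizes = _run_lengths_2d(supra_perm).astype(float)
        clusters = _observed_clusters(supra_obs)
    else:
        abs_zp = np.where(supra_perm, np.abs(z_perm), 0.0)
        # max cluster mass per permutation row
        max_sizes = np.empty(n_perm)
        for i in range(n_perm):
            runs = _observed_clusters(supra_perm[i], weight=abs_zp[i])
            max_sizes[i] = max((r[2] for r in runs), default=0.0)
        clusters = _observed_clusters(supra_obs, weight=np.abs(z_obs))
    threshold = float(np.percentile(max_sizes, 95))
    masks = np.zeros(n_pts, dtype=bool)
    significant = []
    for s, e, size in clusters:
        if size > threshold:
            masks[s:e] = True
            significant.append((s, e, size))
    return ClusterResult(observed_z=z_obs, pointwise_p=pointwise_p,
                         cluster_masks=masks, cluster_threshold=threshold,
                         clusters=significant, n_permutations=n_perm,
                         seed=seed)


# ---------------------------------------------------------------------------
# Circular tests


def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of circular non-uniformity; returns (z, p)."""
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    z, p = pingouin.circ_rayleigh(angles)
    return float(z), float(p)


def watson_u2(sample_a, sample_b, n_perm: int | None = None,
              seed: int | None = None) -> tuple[float, float]:
    """Watson's two-sample U² test for a difference between circular samples.

    The statistic follows Watson (1962); the p-value uses the asymptotic
    series  p = 2 * sum_{m>=1} (-1)^(m-1) exp(-2 m² pi² U²)  unless
    ``n_perm`` requests a permutation null (forced for small samples).
    Angles in degrees.
    """
    a = np.sort(np.asarray(sample_a, dtype=float) % 360.0)
    b = np.sort(np.asarray(sample_b, dtype=float) % 360.0)
    n, m = a.size, b.size
    if min(n, m) < 5 and n_perm is None:
        n_perm = 2000  # permutation fallback for tiny samples
    u2 = _watson_u2_stat(a, b)
    if n_perm is None:
        p = _watson_series_p(u2)
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _watson_u2_stat(perm[:n], perm[n:]) >= u2 - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return float(u2), float(min(max(p, 0.0), 1.0))


def _watson_u2_stat(a, b) -> float:
    n, m = a.size, b.size
    big_n = n + m
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    is_a = np.concatenate([np.ones(n, bool), np.zeros(m, bool)])[order]
    cum_a = np.cumsum(is_a) / n
    cum_b = np.cumsum(~is_a) / m
    d = cum_a - cum_b
    return float(n * m / big_n**2 * (np.sum(d**2) - np.sum(d) ** 2 / big_n))


def _watson_series_p(u2: float, terms: int = 50) -> float:
    ms = np.arange(1, terms + 1)
    return float(2.0 * np.sum((-1.0) ** (ms - 1)
                              * np.exp(-2.0 * ms**2 * np.pi**2 * u2)))


def circular_tests(sample_a, sample_b=None, **kwargs) -> tuple[float, float]:
    """One sample: Rayleigh non-uniformity. Two samples: Watson's U²."""
    if sample_b is None:
        return rayleigh_test(sample_a)
    return watson_u2(sample_a, sample_b, **kwargs)


# ---------------------------------------------------------------------------
# Sequence randomness and multiplicity


def runs_test(labels) -> tuple[float, float]:
    """Wald-Wolfowitz runs test for randomness of a two-label sequence.

    The observed run count is z-scored against the exact null mean and
    variance for the label counts; the p-value is two-sided normal. Sequences
    with a single distinct label are rejected.
    """
    labels = np.asarray(labels)
    values = np.unique(labels)
    if values.size < 2:
        raise ValueError("runs test needs at least two distinct labels")
    if values.size > 2:
        raise ValueError("runs test is defined for two-label sequences")
    x = labels == values[0]
    n1 = int(x.sum())
    n2 = int((~x).sum())
    n = n1 + n2
    runs = 1 + int(np.sum(x[1:] != x[:-1]))
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        raise ValueError("degenerate label counts for the runs test")
    z = (runs - mu) / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def paired_tests_bh(values_a, values_b) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise paired t-tests (A vs B across subjects) with BH
    adjustment; returns (t statistics, adjusted p-values)."""
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    t, p = scipy.stats.ttest_rel(a, b, axis=0)
    return np.atleast_1d(t), bh_adjust(np.atleast_1d(p))
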