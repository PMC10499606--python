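"""Cluster-based permutation inference and trial-learning analyses.

The paired test treats channels as the paired observations: a paired
t-statistic is computed at each time–frequency voxel between two
per-channel trial-averaged maps, the null is built by per-channel sign
flips of the difference maps (algebraically identical to shuffling the
condition labels within each channel), voxelwise two-sided p-values
come from the rank of |t| in the null with the +1 correction, clusters
of contiguous voxels with p < α are formed separately by sign under
4-connectivity, and family-wise significance requires an observed
cluster size strictly greater than the 95th percentile of the
per-permutation *maximum* cluster sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .containers import ValidationError

__all__ = [
    "ClusterResult",
    "LearningResult",
    "paired_cluster_perm_test",
    "unpaired_perm_test",
    "trial_learning_correlation",
]

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    voxels: np.ndarray  # boolean map, freq × time
    size: int
    sign: int


@dataclass
class ClusterResult:
    t_map: np.ndarray
    p_map: np.ndarray
    clusters: list[Cluster]
    null_sizes: np.ndarray
    size_threshold: float
    significant: list[Cluster]
    n_permutations: int
    exhaustive: bool
    seed: int | None


def _paired_t(d_mean: np.ndarray, d_sq_mean: np.ndarray, n: int) -> np.ndarray:
    """Paired t from the mean and mean-square of per-channel differences."""
    var = (d_sq_mean - d_mean**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d_mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def _clusters_from_mask(sig: np.ndarray, t_map: np.ndarray) -> list[Cluster]:
    out: list[Cluster] = []
    for sign in (1, -1):
        mask = sig & ((t_map > 0) if sign > 0 else (t_map < 0))
        labelled, n = ndimage.label(mask, structure=_STRUCTURE_4)
        for k in range(1, n + 1):
            vox = labelled == k
            out.append(Cluster(voxels=vox, size=int(vox.sum()), sign=sign))
    return out


def _max_cluster_size(sig: np.ndarray, t_map: np.ndarray) -> int:
    best = 0
    for sign in (1, -1):
        mask = sig & ((t_map > 0) if sign > 0 else (t_map < 0))
        labelled, n = ndimage.label(mask, structure=_STRUCTURE_4)
        if n:
            best = max(best, int(np.bincount(labelled.ravel())[1:].max()))
    return best


def paired_cluster_perm_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    alpha_voxel: float = 0.05,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int | None = None,
    valid_mask: np.ndarray | None = None,
) -> ClusterResult:
    """Paired cluster-based permutation test on channel-aligned TF maps.

    ``maps_a`` and ``maps_b`` are (channels × freq × time); channels are
    the unit of observation.  When ``n_perm`` meets or exceeds the
    2^n_channels distinct sign patterns, the null is enumerated
    exhaustively instead (with a warning) and p-values are exact.
    """
    maps_a = np.asarray(maps_a, dtype=np.float64)
    maps_b = np.asarray(maps_b, dtype=np.float64)
    if maps_a.shape != maps_b.shape or maps_a.ndim != 3:
        raise ValidationError("maps must be channel-aligned (ch × freq × time)")
    n_ch = maps_a.shape[0]
    if n_ch < 2:
        raise ValidationError("need ≥ 2 channels for a paired test")
    d = maps_a - maps_b
    grid = d.shape[1:]
    d_flat = d.reshape(n_ch, -1)
    sq_mean = (d_flat**2).mean(axis=0)  # invariant under sign flips
    t_obs = _paired_t(d_flat.mean(axis=0), sq_mean, n_ch)

    exhaustive = n_perm >= 2**n_ch
    if exhaustive:
        warnings.warn(
            f"n_perm={n_perm} ≥ 2^{n_ch} sign patterns; using exhaustive enumeration"
        )
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_ch)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_ch))
    null_means = signs @ d_flat / n_ch
    t_null = _paired_t(null_means, sq_mean[None, :], n_ch)

    abs_null = np.abs(t_null)
    n_null = t_null.shape[0]
    exceed = (abs_null >= np.abs(t_obs)[None, :]).sum(axis=0)
    if exhaustive:
        p_flat = exceed / n_null  # identity pattern included → p ≥ 1/n
    else:
        p_flat = (exceed + 1.0) / (n_null + 1.0)
    p_map = p_flat.reshape(grid)
    t_map = t_obs.reshape(grid)

    valid = np.ones(grid, dtype=bool) if valid_mask is None else valid_mask
    sig_obs = (p_map < alpha_voxel) & valid
    clusters = _clusters_from_mask(sig_obs, t_map)

    # per-voxel critical |t| for thresholding the permuted maps: the
    # (1 − α) quantile of the null |t|, consistent with the rank p-value
    crit = np.quantile(abs_null, 1 - alpha_voxel, axis=0)
    null_sizes = np.empty(n_null)
    t_null_maps = t_null.reshape(n_null, *grid)
    sig_null = (np.abs(t_null_maps) >= crit.reshape(grid)[None]) & valid[None]
    for b in range(n_null):
        null_sizes[b] = _max_cluster_size(sig_null[b], t_null_maps[b])
    size_threshold = float(np.quantile(null_sizes, 1 - alpha_cluster))
    significant = [c for c in clusters if c.size > size_threshold]
    return ClusterResult(
        t_map=t_map, p_map=p_map, clusters=clusters, null_sizes=null_sizes,
        size_threshold=size_threshold, significant=significant,
        n_permutations=n_null, exhaustive=exhaustive, seed=seed,
    )


def unpaired_perm_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    sided: str = "two",
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test on the difference of group means.

    Returns ``(p, observed mean(x) − mean(y))``.  The null shuffles the
    pooled group labels; the +1-corrected p is used for Monte-Carlo
    sampling, and the exact count when the relabellings are enumerated
    (which happens automatically whenever that is cheaper than
    ``n_perm`` draws).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need ≥ 2 observations per group")
    pooled = np.concatenate([x, y])
    obs = x.mean() - y.mean()
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate pooled sample (all values identical); p = 1")
        return 1.0, float(obs)

    from math import comb

    n, nx = pooled.size, x.size
    n_distinct = comb(n, nx)
    if n_distinct <= n_perm:
        stats_null = np.array([
            pooled[list(ix)].mean() - np.delete(pooled, list(ix)).mean()
            for ix in itertools.combinations(range(n), nx)
        ])
        denom = n_distinct
        add = 0
    else:
        rng = np.random.default_rng(seed)
        stats_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            stats_null[b] = pooled[perm[:nx]].mean() - pooled[perm[nx:]].mean()
        denom = n_perm + 1
        add = 1
    tol = 1e-12 * max(1.0, np.abs(stats_null).max())
    if sided == "two":
        count = int((np.abs(stats_null) >= abs(obs) - tol).sum())
    elif sided in {"greater", "one"}:
        count = int((stats_null >= obs - tol).sum())
    elif sided == "less":
        count = int((stats_null <= obs + tol).sum())
    else:
        raise ValidationError(f"unknown sidedness {sided!r}")
    return (count + add) / denom, float(obs)


@dataclass
class LearningResult:
    r: float
    p_r: float
    mean_first: float | None
    mean_last: float | None
    p_perm: float | None
    n_trials: int
    first_last_n: int
    seed: int | None
    pooled_channels: bool = False


def trial_learning_correlation(
    power: np.ndarray,
    trial_index: np.ndarray,
    first_last_n: int = 20,
    n_perm: int = 1000,
    sided: str = "two",
    seed: int | None = None,
    pooled_channels: bool = False,
) -> LearningResult:
    """Correlate per-trial cluster power with trial number.

    Pearson r with its parametric p, plus an unpaired permutation
    comparison of the first vs last ``first_last_n`` trials.  When
    observations are pooled across channels, ``trial_index`` repeats
    per channel and the first/last grouping follows the index.
    """
    power = np.asarray(power, dtype=np.float64).ravel()
    trial_index = np.asarray(trial_index).ravel()
    if power.size != trial_index.size:
        raise ValidationError("power and trial_index must align")
    if power.size < 3:
        raise ValidationError("need ≥ 3 trials")
    if np.ptp(power) == 0 or np.ptp(trial_index) == 0:
        warnings.warn("zero variance in power or trial index; r set to 0")
        r, p_r = 0.0, 1.0
    else:
        r, p_r = stats.pearsonr(power, trial_index)

    order = np.unique(trial_index)
    mean_first = mean_last = p_perm = None
    if order.size >= 2 * first_last_n:
        first_ids = order[:first_last_n]
        last_ids = order[-first_last_n:]
        first = power[np.isin(trial_index, first_ids)]
        last = power[np.isin(trial_index, last_ids)]
        p_perm, _ = unpaired_perm_test(last, first, n_perm=n_perm, sided=sided,
                                       seed=seed)
        mean_first = float(first.mean())
        mean_last = float(last.mean())
    else:
        warnings.warn(
            f"fewer than {2 * first_last_n} distinct trials; "
            "first/last comparison skipped"
        )
    return LearningResult(
        r=float(r), p_r=float(p_r), mean_first=mean_first, mean_last=mean_last,
        p_perm=p_perm, n_trials=int(order.size), first_last_n=first_last_n,
        seed=seed, pooled_channels=pooled_channels,
    )
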