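"""Tractography-derived connectivity metrics and the cohort battery.

The connectivity index normalizes the log streamline count by the log
of the maximum attainable count: CI = log(waytotal) / log(n_samples ×
Vseed), where each of the Vseed seed voxels emits n_samples (5,000 by
default) streamlines.  CI is 0 when a single streamline reaches the
target and 1 when every streamline does; the formula is base-invariant
(natural log used).

Hippocampal segmentation is 1-D k-means (k = 2) on the per-voxel
streamline probabilities of the group-average map — no spatial
features, matching a parcellation free of external spatial
constraints.  A between/within variance-ratio floor operationalizes
the failure mode where no two distinct clusters exist.

The group battery mirrors the clinical analysis chain: Tukey outlier
removal per metric, Shapiro–Wilk normality gate, Student's t (or
Mann–Whitney fallback), and a multivariate logistic regression with
AIC-driven backward elimination plus VIF collinearity diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import StreamlineMap, ValidationError

__all__ = [
    "connectivity_index",
    "group_average_map",
    "kmeans_segment",
    "SegmentationResult",
    "compare_subregion_streamlines",
    "roi_rsfc",
    "tukey_remove_outliers",
    "group_compare",
    "GroupCompareResult",
    "logistic_backward_elimination",
    "LogisticModelReport",
]


# --------------------------------------------------------------------
# connectivity index


def connectivity_index(waytotal: float, v_seed: int,
                       n_samples_per_voxel: int = 5000) -> float:
    """CI = log(waytotal) / log(n_samples_per_voxel × v_seed)."""
    if v_seed < 1:
        raise ValidationError("v_seed must be ≥ 1")
    denom_arg = n_samples_per_voxel * v_seed
    if denom_arg <= 1:
        raise ValidationError("n_samples_per_voxel × v_seed must exceed 1")
    if waytotal < 1:
        if waytotal == 0:
            warnings.warn("waytotal = 0: connectivity index undefined (log 0)")
            return float("nan")
        raise ValidationError("waytotal must be ≥ 1 (or 0 for missing)")
    return float(np.log(waytotal) / np.log(denom_arg))


def group_average_map(maps: list[StreamlineMap],
                      weights: np.ndarray | None = None) -> StreamlineMap:
    """Voxelwise (weighted) mean probability across subjects."""
    if not maps:
        raise ValidationError("no maps given")
    ref = maps[0]
    for m in maps[1:]:
        if m.grid_shape != ref.grid_shape or not np.array_equal(m.seed_mask,
                                                                ref.seed_mask):
            raise ValidationError("maps must share grid and seed mask")
    w = np.ones(len(maps)) if weights is None else np.asarray(weights, dtype=float)
    if w.size != len(maps) or np.any(w < 0) or w.sum() == 0:
        raise ValidationError("weights must be non-negative with positive sum")
    stacked = np.stack([m.probability for m in maps])
    avg = np.tensordot(w / w.sum(), stacked, axes=1)
    return StreamlineMap(
        grid_shape=ref.grid_shape, seed_mask=ref.seed_mask, probability=avg,
        n_samples_per_voxel=ref.n_samples_per_voxel, affine=ref.affine,
    )


# --------------------------------------------------------------------
# segmentation


@dataclass
class SegmentationResult:
    labels: np.ndarray | None  # per seed voxel, hotspot = 1
    hotspot_mask: np.ndarray | None  # grid-shaped boolean
    separation: float
    converged: bool
    cluster_means: tuple[float, float] | None = None


def kmeans_segment(smap: StreamlineMap, k: int = 2, n_init: int = 10,
                   separation_min: float = 2.0, seed: int = 0) -> SegmentationResult:
    """Two-cluster k-means on per-voxel streamline probability.

    Returns ``converged=False`` (and no hotspot) when the between- to
    within-cluster variance ratio falls below ``separation_min`` —
    near-uniform maps do not segment into two distinct clusters.
    """
    values = smap.seed_values
    if values.size < k:
        raise ValidationError(f"need ≥ {k} seed voxels")
    if np.ptp(values) == 0:
        return SegmentationResult(labels=None, hotspot_mask=None,
                                  separation=0.0, converged=False)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(values[:, None])
    centers = km.cluster_centers_.ravel()
    hot = int(np.argmax(centers))
    labels = (labels == hot).astype(int)

    within = sum(((values[labels == g] - values[labels == g].mean()) ** 2).sum()
                 for g in (0, 1))
    grand = values.mean()
    between = sum((labels == g).sum() * (values[labels == g].mean() - grand) ** 2
                  for g in (0, 1))
    separation = float(between / within) if within > 0 else float("inf")
    if separation < separation_min:
        return SegmentationResult(labels=None, hotspot_mask=None,
                                  separation=separation, converged=False)
    hotspot = np.zeros(smap.grid_shape, dtype=bool)
    hotspot[smap.seed_mask] = labels == 1
    means = (float(values[labels == 0].mean()), float(values[labels == 1].mean()))
    return SegmentationResult(labels=labels, hotspot_mask=hotspot,
                              separation=separation, converged=True,
                              cluster_means=means)


# --------------------------------------------------------------------
# paired subregion comparison and rsFC


def compare_subregion_streamlines(a: np.ndarray, b: np.ndarray, paired: bool = True,
                                  test: str = "auto",
                                  alpha_normality: float = 0.05) -> dict:
    """Compare normalized streamline counts between two subregions.

    ``normalized count`` = waytotal / (n_samples × v_seed), the
    fraction of streamlines reaching the target.  With ``test='auto'``
    a Shapiro–Wilk gate chooses between the t-test and the rank test
    (Wilcoxon signed-rank when paired, Mann–Whitney U otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size and paired:
        raise ValidationError("paired comparison needs equal-length samples")
    if min(a.size, b.size) < 3:
        raise ValidationError("need n ≥ 3 per subregion")
    if test == "auto":
        if paired:
            d = a - b
            normal = np.ptp(d) > 0 and stats.shapiro(d).pvalue >= alpha_normality
        else:
            normal = (stats.shapiro(a).pvalue >= alpha_normality
                      and stats.shapiro(b).pvalue >= alpha_normality)
        test = "t" if normal else ("wilcoxon" if paired else "mann_whitney")
    if test == "t":
        res = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
    elif test == "wilcoxon":
        res = stats.wilcoxon(a, b)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValidationError(f"unknown test {test!r}")
    return {"test": test, "statistic": float(res.statistic),
            "p": float(res.pvalue), "paired": paired}


def roi_rsfc(ts_a: np.ndarray, ts_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of two ROI mean time series, Fisher-z transformed.

    Returns ``(r, z)``; |r| = 1 is clipped to 1 − 1e−7 before atanh.
    """
    ts_a = np.asarray(ts_a, dtype=float)
    ts_b = np.asarray(ts_b, dtype=float)
    if ts_a.size != ts_b.size or ts_a.size < 10:
        raise ValidationError("need equal-length series of ≥ 10 samples")
    if not (np.all(np.isfinite(ts_a)) and np.all(np.isfinite(ts_b))):
        raise ValidationError("series must be finite")
    if np.ptp(ts_a) == 0 or np.ptp(ts_b) == 0:
        warnings.warn("zero-variance series; rsFC undefined")
        return float("nan"), float("nan")
    r = float(stats.pearsonr(ts_a, ts_b).statistic)
    r_c = r
    if abs(r_c) >= 1.0 - 1e-7:
        warnings.warn("|r| ≈ 1 clipped before Fisher transform")
        r_c = np.sign(r_c) * (1.0 - 1e-7)
    return r, float(np.arctanh(r_c))


# --------------------------------------------------------------------
# outliers and group comparison


def tukey_remove_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation of order statistics (type 7).
    Returns ``(kept values, removed indices)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("Tukey fences need n ≥ 4")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], np.flatnonzero(~keep)


@dataclass
class GroupCompareResult:
    metric: str
    test: str
    statistic: float
    p: float
    n_per_group: tuple[int, int]
    removed_per_group: tuple[int, int]
    group_means: tuple[float, float]
    conventions: dict = field(default_factory=dict)


def group_compare(cohort: pd.DataFrame, metric: str, group_col: str = "group",
                  alpha_normality: float = 0.05,
                  tukey: bool = True) -> GroupCompareResult:
    """Two-group comparison of one connectivity metric.

    Pipeline: Tukey filter per metric (fences from the pooled cohort
    values; removal counts reported per group) → Shapiro–Wilk per
    group → two-sided Student's t, or Mann–Whitney U when normality is
    rejected in either group.  Pooled fences keep the null test
    calibrated — per-group trimming at these sample sizes shrinks the
    within-group variance and inflates the type-I error.
    """
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    all_vals = cohort[metric].to_numpy(dtype=float)
    group_labels = cohort[group_col].to_numpy()
    if tukey:
        if all_vals.size < 4:
            raise ValidationError(
                f"cohort too small to outlier-filter (n = {all_vals.size})"
            )
        _, removed_idx = tukey_remove_outliers(all_vals)
    else:
        removed_idx = np.empty(0, dtype=int)
    keep = np.ones(all_vals.size, dtype=bool)
    keep[removed_idx] = False
    samples, removed = [], []
    for g in groups:
        in_g = group_labels == g
        kept = all_vals[in_g & keep]
        if kept.size < 3:
            raise ValidationError(f"group {g!r} extinguished by outlier filtering")
        samples.append(kept)
        removed.append(int((in_g & ~keep).sum()))
    normal = all(stats.shapiro(s).pvalue >= alpha_normality for s in samples)
    if normal:
        res = stats.ttest_ind(samples[0], samples[1])
        test = "t"
    else:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test = "mann_whitney"
    return GroupCompareResult(
        metric=metric, test=test, statistic=float(res.statistic),
        p=float(res.pvalue), n_per_group=(samples[0].size, samples[1].size),
        removed_per_group=tuple(removed),
        group_means=(float(samples[0].mean()), float(samples[1].mean())),
        conventions={"quartiles": "type-7 linear interpolation",
                     "tukey": tukey, "fences": "pooled per metric",
                     "alpha_normality": alpha_normality},
    )


# --------------------------------------------------------------------
# logistic regression with backward elimination


@dataclass
class LogisticModelReport:
    retained: list[str]
    coefficients: dict
    p_values: dict
    vif: dict
    aic: float
    aic_path: list[float]
    eliminated: list[str]
    separation_flagged: list[str]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    # IRLS with pseudo-inverse is robust to the near-singular Hessians
    # that transient quasi-separation produces during stepwise search
    import statsmodels.api as sm

    exog = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, exog, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        res.aic  # force lazy llf evaluation while warnings are muted
        return res


def _separates(y: np.ndarray, x: np.ndarray) -> bool:
    """True when a single threshold on x perfectly splits the outcome."""
    return (x[y == 1].min() > x[y == 0].max()
            or x[y == 0].min() > x[y == 1].max())


def logistic_backward_elimination(
    cohort: pd.DataFrame,
    candidates: list[str],
    outcome_col: str = "group",
    positive_class: str | None = None,
) -> LogisticModelReport:
    """AIC-driven backward elimination of a multivariate logistic model.

    Starting from the full candidate set, the variable whose removal
    most reduces the AIC is dropped, until no removal reduces it.
    Variables perfectly separating the outcome are flagged and removed
    before fitting.  VIF_j = 1/(1 − R²_j) is reported for the retained
    set (computed on the predictors with an intercept).
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    df = cohort.dropna(subset=[*candidates, outcome_col])
    levels = sorted(df[outcome_col].unique())
    if len(levels) != 2:
        raise ValidationError(f"outcome must be binary, got {levels}")
    pos = positive_class if positive_class is not None else levels[1]
    y = (df[outcome_col] == pos).to_numpy(dtype=float)
    if len(df) <= len(candidates):
        raise ValidationError("need more observations than candidate variables")

    flagged = [v for v in candidates
               if _separates(y, df[v].to_numpy(dtype=float))]
    if flagged:
        warnings.warn(f"perfect separation flagged for {flagged}; removed")
    current = [v for v in candidates if v not in flagged]
    eliminated: list[str] = list(flagged)

    fit = _fit_logit(y, df[current])
    aic_path = [float(fit.aic)]
    while len(current) > 1:
        best_var, best_aic = None, fit.aic
        for v in current:
            reduced = [c for c in current if c != v]
            cand_fit = _fit_logit(y, df[reduced])
            if cand_fit.aic < best_aic:
                best_var, best_aic = v, cand_fit.aic
        if best_var is None:
            break
        current = [c for c in current if c != best_var]
        eliminated.append(best_var)
        fit = _fit_logit(y, df[current])
        aic_path.append(float(fit.aic))

    exog = sm.add_constant(df[current], has_constant="add")
    vif = {}
    if len(current) >= 2:
        for j, v in enumerate(current):
            vif[v] = float(variance_inflation_factor(exog.to_numpy(), j + 1))
    elif current:
        vif[current[0]] = 1.0
    return LogisticModelReport(
        retained=list(current),
        coefficients={v: float(fit.params[v]) for v in current},
        p_values={v: float(fit.pvalues[v]) for v in current},
        vif=vif,
        aic=float(fit.aic),
        aic_path=aic_path,
        eliminated=eliminated,
        separation_flagged=flagged,
    )
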