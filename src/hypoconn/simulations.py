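"""Seeded simulation studies exercising the pipeline end to end.

Each function generates synthetic data under planted (or null)
conditions, runs the full analysis chain, and returns the measured
operating characteristics — family-wise error, detection rate and
localization overlap, learning-analysis power, parameter recovery,
type-I calibration, variable-selection behaviour.  Problem sizes are
scaled to single-CPU batch use: 125 Hz task recordings, 30-frequency
wavelet grids over 3–30 Hz, 200-permutation nulls; the statistics
being calibrated are invariant to these scalings.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import synth
from .cluster import paired_cluster_perm_test, trial_learning_correlation
from .connectome import group_compare, logistic_backward_elimination
from .containers import ParadigmSpec, WaveletSpec
from .crp import EvokedEpochs, crp_fit
from .preprocess import detect_artifact_trials, epoch
from .spectral import band_power_trace, channel_average_maps, morlet_tfr, \
    prestim_z_normalize
from .synth import CohortSpec, EPEffectSpec, LFPEffectSpec, gen_cohort_table, \
    gen_evoked_trials, gen_task_lfp, planted_tf_mask

__all__ = [
    "cluster_run",
    "fwe_calibration",
    "effect_recovery",
    "learning_runs",
    "crp_recovery",
    "crp_null_rate",
    "cohort_type1",
    "selection_recovery",
]

_PARADIGM = ParadigmSpec()
_WAVELET = WaveletSpec(f_min=3.0, f_max=30.0, voices_per_octave=9)
_WAVELET_LOW = WaveletSpec(f_min=3.0, f_max=10.0, voices_per_octave=9)


def cluster_run(seed: int, effect_z: float, n_channels: int = 34,
                n_trials_per_condition: int = 8, n_perm: int = 200,
                rate_hz: float = 125.0) -> tuple[bool, float]:
    """One generate→preprocess→TFR→z→cluster-test run.

    Returns ``(any significant cluster, best Jaccard overlap of a
    significant cluster with the planted voxel set)``.
    """
    spec = LFPEffectSpec(effect_z=effect_z, learning_slope=0.0)
    rec, events, _ = gen_task_lfp(spec, _PARADIGM, n_channels,
                                  n_trials_per_condition, rate_hz, seed=seed)
    eps = detect_artifact_trials(epoch(rec, events, _PARADIGM)).crop(-2.0, 3.0)
    tf = prestim_z_normalize(morlet_tfr(eps, _WAVELET, decim=4), _PARADIGM)
    maps_a = channel_average_maps(tf, spec.effect_condition)
    maps_b = channel_average_maps(tf, spec.neutral_condition)
    tsel = (tf.times >= -1.0) & (tf.times <= 2.0)
    res = paired_cluster_perm_test(
        maps_a[:, :, tsel], maps_b[:, :, tsel], n_perm=n_perm,
        seed=seed + 50_000, valid_mask=tf.valid_mask[:, tsel],
    )
    planted = planted_tf_mask(tf.freqs, tf.times[tsel], spec.band_hz,
                              spec.window_s)
    best_jac = 0.0
    for c in res.significant:
        jac = (c.voxels & planted).sum() / (c.voxels | planted).sum()
        best_jac = max(best_jac, jac)
    return len(res.significant) > 0, best_jac


def fwe_calibration(n_reps: int = 200, seed: int = 0, **kwargs) -> float:
    """Family-wise rate of ≥ 1 significant cluster under the null."""
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            hits += cluster_run(seed + r, effect_z=0.0, **kwargs)[0]
    return hits / n_reps


def effect_recovery(n_runs: int = 50, seed: int = 0, effect_z: float = 1.0,
                    jaccard_min: float = 0.3) -> tuple[float, list[float]]:
    """Detection rate (significant cluster overlapping the planted set)."""
    hits = 0
    jaccards = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_runs):
            _, jac = cluster_run(seed + r, effect_z=effect_z,
                                 n_trials_per_condition=20)
            jaccards.append(jac)
            hits += jac >= jaccard_min
    return hits / n_runs, jaccards


def learning_run(seed: int, learning_slope: float, n_channels: int = 4,
                 n_trials_per_condition: int = 40, rate_hz: float = 100.0,
                 first_last_n: int = 20):
    """Per-trial cluster-power learning analysis on one synthetic run.

    Trial power is pooled across channels with the within-condition
    presentation index repeated per channel.
    """
    spec = LFPEffectSpec(effect_z=1.0, learning_slope=learning_slope)
    rec, events, _ = gen_task_lfp(spec, _PARADIGM, n_channels,
                                  n_trials_per_condition, rate_hz, seed=seed)
    eps = detect_artifact_trials(epoch(rec, events, _PARADIGM)).crop(-2.0, 3.0)
    tf = prestim_z_normalize(morlet_tfr(eps, _WAVELET_LOW, decim=4), _PARADIGM)
    scal = band_power_trace(tf, band_hz=spec.band_hz, window_s=spec.window_s)
    rows = tf.trials_of(spec.effect_condition)
    power = scal[:, rows]
    within = np.argsort(np.argsort(tf.trial_index[rows])) + 1
    # the learning hypothesis is directional (power increases as the
    # cue-reward association is learned), so the first/last comparison
    # is one-sided
    return trial_learning_correlation(
        power.ravel(), np.tile(within, (power.shape[0], 1)).ravel(),
        first_last_n=first_last_n, sided="greater", seed=seed + 1,
        pooled_channels=True,
    )


def learning_runs(n_runs: int, learning_slope: float, seed: int = 0) -> dict:
    """Detection rates of the correlation and first/last-20 analyses."""
    corr_hits = perm_hits = both = 0
    rs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_runs):
            res = learning_run(seed + r, learning_slope)
            rs.append(res.r)
            c = (res.r > 0) and (res.p_r < 0.05)
            p = res.p_perm is not None and res.p_perm < 0.05
            corr_hits += c
            perm_hits += p
            both += c and p
    return {"corr_rate": corr_hits / n_runs, "perm_rate": perm_hits / n_runs,
            "both_rate": both / n_runs, "mean_r": float(np.mean(rs))}


def _one_crp(seed: int, spec: EPEffectSpec, rate_hz: float = 500.0):
    trials, times, truth = gen_evoked_trials(spec, rate_hz, seed=seed)
    ep = EvokedEpochs(data=trials, rate=rate_hz, times=times,
                      channel_id="synthetic")
    res = crp_fit(ep, seed=seed)
    return res, truth, times


def crp_recovery(n_runs: int = 50, seed: int = 0) -> dict:
    """Magnitude/duration/shape recovery under the default planted response."""
    spec = EPEffectSpec()
    mags, taus, coss, snrs, sig = [], [], [], [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_runs):
            res, truth, times = _one_crp(seed + r, spec)
            mags.append(res.mean_magnitude)
            taus.append(res.tau)
            snrs.append(res.snr)
            sig += res.significant
            sel = times >= res.shape_times[0] - 1e-12
            s_true = truth["shape"][sel][:res.canonical_shape.size]
            denom = np.linalg.norm(s_true) * np.linalg.norm(res.canonical_shape)
            coss.append(abs(float(np.dot(s_true, res.canonical_shape))) / denom)
    return {
        "mean_magnitude": float(np.mean(mags)),
        "true_magnitude": spec.alpha_mean,
        "mean_tau": float(np.mean(taus)),
        "true_tau": spec.duration_s,
        "mean_shape_cosine": float(np.mean(coss)),
        "mean_snr": float(np.mean(snrs)),
        "significant_rate": sig / n_runs,
    }


def crp_null_rate(n_runs: int = 50, seed: int = 0) -> float:
    """Fraction of pure-noise inputs declared significant."""
    spec = EPEffectSpec(alpha_mean=0.0, alpha_sd=0.0)
    sig = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_runs):
            res, _, _ = _one_crp(seed + r, spec)
            sig += res.significant
    return sig / n_runs


def cohort_type1(n_cohorts: int = 500, seed: int = 0,
                 metric: str = "rsfc_lh_dlhpc") -> float:
    """Empirical type-I error of group_compare over null cohorts."""
    spec = CohortSpec(effect_delta=0.0)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_cohorts):
            df, _ = gen_cohort_table(spec, seed=seed + r)
            hits += group_compare(df, metric).p < 0.05
    return hits / n_cohorts


def selection_recovery(n_runs: int = 100, seed: int = 0,
                       effect_delta: float = -1.5) -> dict:
    """Backward-elimination behaviour when one metric carries the signal."""
    signal = "rsfc_lh_dlhpc"
    candidates = synth.CONNECTIVITY_METRICS + synth.BEHAVIOURAL_COVARIATES
    spec = CohortSpec(effect_delta=effect_delta, effect_metrics=(signal,))
    kept_signal = clean = joint = 0
    n_noise = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_runs):
            df, _ = gen_cohort_table(spec, seed=seed + r)
            rep = logistic_backward_elimination(df, candidates)
            s = signal in rep.retained
            noise = [v for v in rep.retained if v != signal]
            kept_signal += s
            clean += not noise
            joint += s and not noise
            n_noise.append(len(noise))
    return {"signal_retained_rate": kept_signal / n_runs,
            "all_noise_dropped_rate": clean / n_runs,
            "joint_rate": joint / n_runs,
            "mean_noise_retained": float(np.mean(n_noise))}
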