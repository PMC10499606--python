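"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: two-condition
task-locked LFP with a plantable low-frequency post-cue power effect
and a linear learning trend, stimulation-evoked trials of the form
weight × shape + noise, a hippocampus-shaped voxel map with a
dorsolateral streamline hotspot, and a two-group cohort table with a
planted connectivity difference.

Background LFP noise is 1/f^β coloured Gaussian noise (β = 1.5 by
default); oscillatory bursts are Hann-windowed sinusoids with random
phase; injected artifacts are 50 ms biphasic transients at 8–12× the
background standard deviation, guaranteed to trip the ±4·sd artifact
rule while staying local in time.  All generators are deterministic
given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EventTable, ParadigmSpec, Recording, StreamlineMap, ValidationError

__all__ = [
    "LFPEffectSpec",
    "EPEffectSpec",
    "MapEffectSpec",
    "CohortSpec",
    "gen_task_lfp",
    "gen_evoked_trials",
    "gen_streamline_map",
    "gen_cohort_table",
    "planted_tf_mask",
]


# --------------------------------------------------------------------
# task LFP

#: calibration constant mapping effect_z to burst amplitude so that the
#: planted band/window z-score elevation matches effect_z (convention:
#: amplitude = C * sqrt(effect_z) * band-limited background RMS)
_EFFECT_AMP_C = 2.9


@dataclass
class LFPEffectSpec:
    """Planted low-frequency power effect for the cued-anticipation task."""

    band_hz: tuple[float, float] = (4.0, 6.0)
    window_s: tuple[float, float] = (0.0, 1.0)  # relative to cue onset
    effect_z: float = 1.0
    learning_slope: float = 0.015  # per within-condition trial
    background_beta: float = 1.5
    background_sd: float = 20.0  # μV
    artifact_rate: float = 0.0
    effect_condition: str = "sweet_fat"
    neutral_condition: str = "taste_neutral"

    def __post_init__(self) -> None:
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise ValidationError("band_hz must be an increasing positive interval")
        if self.effect_z < 0:
            raise ValidationError("effect_z must be ≥ 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValidationError("artifact_rate must lie in [0, 1]")
        if self.background_sd <= 0:
            raise ValidationError("background_sd must be positive")


def _colored_noise(rng: np.random.Generator, n: int, beta: float, sd: float,
                   rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1/f^β Gaussian noise with exact sample sd; returns (x, freqs, weights)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-beta / 2.0)
    spec *= weights
    x = np.fft.irfft(spec, n=n)
    scale = sd / x.std()
    return x * scale, freqs, weights * scale


def _band_rms(freqs: np.ndarray, weights: np.ndarray, band: tuple[float, float],
              total_sd: float) -> float:
    """RMS of the background restricted to ``band`` (from the shaping weights)."""
    w2 = weights**2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    frac = w2[sel].sum() / w2.sum()
    return float(total_sd * np.sqrt(frac))


def gen_task_lfp(
    spec: LFPEffectSpec,
    paradigm: ParadigmSpec,
    n_channels: int,
    n_trials_per_condition: int,
    rate_hz: float,
    seed: int,
    gap_s: float = 1.0,
) -> tuple[Recording, EventTable, dict]:
    """Generate a continuous recording with interleaved randomized trials.

    The effect condition carries a Hann-windowed oscillatory burst in
    ``band_hz`` during ``window_s`` after cue onset, with amplitude
    scaling as ``(1 + learning_slope × trial_index)`` where the index
    counts presentations within the condition.
    """
    if rate_hz <= 2 * spec.band_hz[1]:
        raise ValidationError("rate_hz must exceed twice the upper band edge")
    if spec.window_s[1] > paradigm.total_s - paradigm.prestim_s:
        raise ValidationError("effect window extends past the end of the trial")

    rng = np.random.default_rng(seed)
    n_trials = 2 * n_trials_per_condition
    trial_len = paradigm.total_s + gap_s
    lead_s = gap_s
    total_s = lead_s + n_trials * trial_len
    n_samples = int(round(total_s * rate_hz))

    labels = np.array(
        [spec.effect_condition] * n_trials_per_condition
        + [spec.neutral_condition] * n_trials_per_condition
    )
    labels = labels[rng.permutation(n_trials)]
    # cue onsets (the event marker); trials start prestim_s earlier
    cue_onsets = lead_s + np.arange(n_trials) * trial_len + paradigm.prestim_s

    samples = np.empty((n_channels, n_samples))
    band_rms = None
    for ch in range(n_channels):
        x, freqs, weights = _colored_noise(
            rng, n_samples, spec.background_beta, spec.background_sd, rate_hz
        )
        samples[ch] = x
        if band_rms is None:
            band_rms = _band_rms(freqs, weights, spec.band_hz, spec.background_sd)

    # planted bursts (same per-trial amplitude on every channel; phase
    # and carrier frequency drawn per channel-trial)
    effect_rows = np.flatnonzero(labels == spec.effect_condition)
    within_idx = np.arange(1, effect_rows.size + 1)
    base_amp = _EFFECT_AMP_C * np.sqrt(spec.effect_z) * band_rms
    trial_amps = base_amp * (1.0 + spec.learning_slope * within_idx)

    w0, w1 = spec.window_s
    n_win = int(round((w1 - w0) * rate_hz))
    hann = np.hanning(n_win)
    t_win = np.arange(n_win) / rate_hz
    for amp, row in zip(trial_amps, effect_rows):
        start = int(round((cue_onsets[row] + w0) * rate_hz))
        for ch in range(n_channels):
            f = rng.uniform(*spec.band_hz)
            phase = rng.uniform(0, 2 * np.pi)
            samples[ch, start:start + n_win] += (
                amp * hann * np.sin(2 * np.pi * f * t_win + phase)
            )

    # injected artifacts: 50 ms biphasic transient on one random channel
    artifact_trials = np.flatnonzero(rng.random(n_trials) < spec.artifact_rate)
    n_art = int(round(0.05 * rate_hz))
    t_art = np.arange(n_art) / rate_hz
    biphasic = np.sin(2 * np.pi * t_art / 0.05)  # one full cycle
    for row in artifact_trials:
        ch = rng.integers(n_channels)
        mult = rng.uniform(8.0, 12.0)
        trial_start = int(round((cue_onsets[row] - paradigm.prestim_s) * rate_hz))
        offset = rng.integers(0, int(paradigm.total_s * rate_hz) - n_art)
        samples[ch, trial_start + offset:trial_start + offset + n_art] += (
            mult * spec.background_sd * biphasic
        )

    rec = Recording(
        samples=samples,
        rate=rate_hz,
        channel_ids=[f"HPC{i + 1}" for i in range(n_channels)],
        channel_geometry=[[f"HPC{i + 1}" for i in range(n_channels)]],
    )
    events = EventTable(onsets=cue_onsets, labels=list(labels))
    ground_truth = {
        "band_hz": spec.band_hz,
        "window_s": spec.window_s,
        "effect_z": spec.effect_z,
        "labels": list(labels),
        "effect_trial_rows": effect_rows,
        "within_condition_index": within_idx,
        "trial_amplitudes": trial_amps,
        "artifact_trial_rows": artifact_trials,
        "background_band_rms": band_rms,
    }
    return rec, events, ground_truth


def planted_tf_mask(freqs: np.ndarray, times: np.ndarray,
                    band_hz: tuple[float, float],
                    window_s: tuple[float, float]) -> np.ndarray:
    """Boolean (freq × time) mask of the planted effect voxels."""
    f_in = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    t_in = (times >= window_s[0]) & (times <= window_s[1])
    return np.outer(f_in, t_in)


# --------------------------------------------------------------------
# evoked trials


@dataclass
class EPEffectSpec:
    """Ground truth for stimulation-evoked trials: weight × shape + noise.

    The canonical waveform is a sum of two exponentially decaying
    sinusoids — a sharp early deflection followed by a slower return to
    baseline — truncated at ``duration_s`` with a short cosine taper.
    It is unit-normalized so ∫s²dt = 1, hence the per-trial weights
    carry μV·√s.
    """

    f1_hz: float = 12.0
    tau1_s: float = 0.03
    amp1: float = 1.0
    f2_hz: float = 0.83
    tau2_s: float = 0.6
    amp2: float = 0.8
    polarity: int = -1
    duration_s: float = 0.3
    alpha_mean: float = 45.0  # μV·√s
    alpha_sd: float = 5.0
    noise_sd: float = 60.0  # μV per sample
    n_trials: int = 49

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.alpha_sd < 0 or self.noise_sd < 0:
            raise ValidationError("alpha_sd and noise_sd must be ≥ 0")


def canonical_waveform(spec: EPEffectSpec, times: np.ndarray) -> np.ndarray:
    """Unit-energy canonical shape over the epoch time axis (1/√s)."""
    dt = float(times[1] - times[0])
    s = np.zeros_like(times)
    support = (times >= 0) & (times < spec.duration_s)
    t = times[support]
    raw = spec.polarity * (
        spec.amp1 * np.exp(-t / spec.tau1_s) * np.sin(2 * np.pi * spec.f1_hz * t)
        + spec.amp2 * np.exp(-t / spec.tau2_s) * np.sin(2 * np.pi * spec.f2_hz * t)
    )
    # cosine taper over the last 10 % of the support avoids a step edge
    n_tap = max(int(0.1 * t.size), 1)
    taper = np.ones(t.size)
    taper[-n_tap:] = 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_tap)))
    raw = raw * taper
    energy = np.sum(raw**2) * dt
    s[support] = raw / np.sqrt(energy)
    return s


def gen_evoked_trials(
    spec: EPEffectSpec,
    rate_hz: float,
    epoch_bounds: tuple[float, float] = (-0.5, 2.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate trials = α_k · s(t) + noise.

    Returns ``(trials, times, ground_truth)`` with ``trials`` of shape
    (n_trials, n_times) in μV and ``times`` in s (stimulus at 0).
    """
    if spec.duration_s > epoch_bounds[1]:
        raise ValidationError("response duration exceeds the post-stimulus epoch")
    rng = np.random.default_rng(seed)
    n_t = int(round((epoch_bounds[1] - epoch_bounds[0]) * rate_hz))
    times = epoch_bounds[0] + np.arange(n_t) / rate_hz
    s = canonical_waveform(spec, times)
    alpha = spec.alpha_mean + spec.alpha_sd * rng.standard_normal(spec.n_trials)
    trials = alpha[:, None] * s[None, :]
    if spec.noise_sd > 0:
        trials = trials + spec.noise_sd * rng.standard_normal(trials.shape)
    ground_truth = {"shape": s, "alpha": alpha, "duration_s": spec.duration_s,
                    "times": times}
    return trials, times, ground_truth


# --------------------------------------------------------------------
# streamline maps


@dataclass
class MapEffectSpec:
    """Hippocampus-shaped seed mask with a dorsolateral streamline hotspot."""

    grid_shape: tuple[int, int, int] = (16, 12, 10)
    semi_axes: tuple[float, float, float] = (6.5, 3.5, 2.5)
    hotspot_offset: float = 3.0  # hotspot = mask voxels with x ≥ centre + offset
    p_hot: float = 0.8
    p_bg: float = 0.1
    noise_sd: float = 0.0
    n_samples_per_voxel: int = 5000

    def __post_init__(self) -> None:
        if not 0 <= self.p_bg < self.p_hot <= 1:
            raise ValidationError("need 0 ≤ p_bg < p_hot ≤ 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")


def gen_streamline_map(spec: MapEffectSpec, seed: int = 0) -> tuple[StreamlineMap, dict]:
    """Two-level streamline-probability map with a planted hotspot."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ax, ay, az = spec.semi_axes
    mask = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2 <= 1.0
    hotspot = mask & (ii >= cx + spec.hotspot_offset)
    if not hotspot.any() or not (mask & ~hotspot).any():
        raise ValidationError("hotspot geometry degenerate for this grid")

    prob = np.zeros(spec.grid_shape)
    prob[mask] = spec.p_bg
    prob[hotspot] = spec.p_hot
    if spec.noise_sd > 0:
        prob[mask] += spec.noise_sd * rng.standard_normal(int(mask.sum()))
    prob[mask] = np.clip(prob[mask], 0.0, 1.0)
    smap = StreamlineMap(
        grid_shape=spec.grid_shape,
        seed_mask=mask,
        probability=prob,
        n_samples_per_voxel=spec.n_samples_per_voxel,
    )
    return smap, {"hotspot_mask": hotspot}


# --------------------------------------------------------------------
# cohort tables

CONNECTIVITY_METRICS = [
    "rsfc_lh_dlhpc",
    "rsfc_lh_non_dlhpc",
    "ci_lh_dlhpc_left",
    "ci_lh_dlhpc_right",
]

BEHAVIOURAL_COVARIATES = [
    "age",
    "bdi",
    "bai",
    "binge_frequency",
    "debq_restrained",
    "debq_emotional",
    "debq_external",
]


@dataclass
class CohortSpec:
    """Two-group cohort (lean vs overweight/obese) with planted Δ.

    ``effect_delta`` is the group mean difference on each metric in
    ``effect_metrics``, in units of the shared within-group sd
    (obese minus lean; negative = reduced connectivity in obesity).
    """

    n_per_group: int = 17
    effect_metrics: tuple[str, ...] = ("rsfc_lh_dlhpc",)
    effect_delta: float = -1.0
    outlier_rate: float = 0.0

    metric_means: dict = field(default_factory=lambda: {
        "rsfc_lh_dlhpc": 0.30, "rsfc_lh_non_dlhpc": 0.25,
        "ci_lh_dlhpc_left": 0.55, "ci_lh_dlhpc_right": 0.55,
    })
    metric_sds: dict = field(default_factory=lambda: {
        "rsfc_lh_dlhpc": 0.10, "rsfc_lh_non_dlhpc": 0.10,
        "ci_lh_dlhpc_left": 0.05, "ci_lh_dlhpc_right": 0.05,
    })

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be ≥ 2")
        unknown = set(self.effect_metrics) - set(CONNECTIVITY_METRICS)
        if unknown:
            raise ValidationError(f"unknown effect metrics: {sorted(unknown)}")


def gen_cohort_table(spec: CohortSpec, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """One row per subject: group, connectivity metrics, covariates."""
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    group = np.array(["lean"] * n + ["overweight_obese"] * n)
    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(2 * n)],
        "group": group,
    })
    for m in CONNECTIVITY_METRICS:
        mu, sd = spec.metric_means[m], spec.metric_sds[m]
        vals = mu + sd * rng.standard_normal(2 * n)
        if m in spec.effect_metrics:
            vals[n:] += spec.effect_delta * sd
        df[m] = vals
    df["age"] = np.clip(26 + 5.6 * rng.standard_normal(2 * n), 18, 65)
    df["bdi"] = np.clip(12 + 8 * rng.standard_normal(2 * n), 0, 63)
    df["bai"] = np.clip(10 + 7 * rng.standard_normal(2 * n), 0, 63)
    df["binge_frequency"] = np.clip(2.7 + 1.4 * rng.standard_normal(2 * n), 0.5, 14)
    for c in ("debq_restrained", "debq_emotional", "debq_external"):
        df[c] = np.clip(3.0 + 0.7 * rng.standard_normal(2 * n), 1, 5)

    injected: list[tuple[int, str]] = []
    for m in CONNECTIVITY_METRICS:
        if rng.random() < spec.outlier_rate:
            row = int(rng.integers(2 * n))
            q1, q3 = np.percentile(df[m], [25, 75])
            df.loc[row, m] = np.median(df[m]) + 10 * (q3 - q1)
            injected.append((row, m))
    ground_truth = {"effect_metrics": spec.effect_metrics,
                    "effect_delta": spec.effect_delta,
                    "injected_outliers": injected}
    return df, ground_truth
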