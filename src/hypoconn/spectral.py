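"""Morlet time–frequency decomposition and prestimulus normalization.

The transform is a continuous wavelet transform with the analytic
Morlet mother wavelet (centre parameter ω₀ = 6), evaluated in the
frequency domain: the signal is reflect-padded, Fourier transformed,
multiplied by the scaled wavelet spectrum e^{−(aω−ω₀)²/2} (zero for
negative frequencies), and inverse transformed at each scale.  Scales
map to frequencies through the wavelet centre frequency, f = ω₀/(2πa),
on a log-spaced axis with ``voices_per_octave`` scales per octave.

The wavelet spectrum is normalized to unity at its centre frequency,
so a pure sinusoid of amplitude A yields |W|² = A²/4 at its own
frequency — convenient for ground-truth checks.  Samples within one
envelope standard deviation (a seconds) of an epoch edge are marked
invalid and excluded from all statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .containers import ParadigmSpec, ValidationError, WaveletSpec
from .preprocess import TrialEpochs

__all__ = [
    "TFMap",
    "morlet_tfr",
    "prestim_z_normalize",
    "condition_difference_map",
    "channel_average_maps",
    "band_power_trace",
]


@dataclass
class TFMap:
    """Per-channel, per-trial time–frequency power."""

    power: np.ndarray  # channels × trials × frequencies × time
    freqs: np.ndarray  # Hz, log-spaced
    times: np.ndarray  # s relative to cue onset
    normalization: str  # raw | prestim_z | recording_z
    conditions: list[str]
    trial_index: np.ndarray
    channel_ids: list[str]
    valid_mask: np.ndarray  # frequencies × time, True away from edges

    def __post_init__(self) -> None:
        if self.power.shape[2:] != (self.freqs.size, self.times.size):
            raise ValidationError("power axes do not match frequency/time axes")
        if self.normalization == "raw" and np.any(self.power < 0):
            raise ValidationError("raw power must be non-negative")

    def trials_of(self, condition: str) -> np.ndarray:
        rows = np.array([c == condition for c in self.conditions])
        if not rows.any():
            raise ValidationError(f"condition {condition!r} has no trials")
        return rows


def morlet_tfr(epochs: TrialEpochs, spec: WaveletSpec, decim: int = 1,
               chunk_bytes: int = 64_000_000) -> TFMap:
    """Raw Morlet wavelet power for every unflagged trial.

    ``decim`` strides the output time axis (power is computed at full
    resolution first, so no aliasing of the power envelope at the
    decimation rates used here).
    """
    if spec.f_max >= epochs.rate / 2:
        raise ValidationError(
            f"f_max {spec.f_max} Hz must be below Nyquist ({epochs.rate / 2} Hz)"
        )
    good = epochs.good() if epochs.artifact_flag.any() else epochs
    n_ch, n_tr, n_t = good.data.shape
    freqs = spec.frequencies()
    scales = spec.omega0 / (2 * np.pi * freqs)  # seconds

    pad = n_t // 2
    n_fft = next_fast_len(n_t + 2 * pad)
    x = good.data.reshape(n_ch * n_tr, n_t)
    xp = np.pad(x, [(0, 0), (pad, n_fft - n_t - pad)], mode="reflect")
    omega = 2 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / good.rate)

    t_sel = np.arange(0, n_t, decim)
    power = np.empty((n_ch * n_tr, freqs.size, t_sel.size))
    n_chunk = max(1, chunk_bytes // (16 * n_fft))
    for lo in range(0, x.shape[0], n_chunk):
        hi = min(lo + n_chunk, x.shape[0])
        X = fft(xp[lo:hi], axis=1)
        for fi, a in enumerate(scales):
            psi = np.exp(-0.5 * (a * omega - spec.omega0) ** 2)
            psi[omega < 0] = 0.0
            W = ifft(X * psi, axis=1)[:, pad:pad + n_t]
            power[lo:hi, fi] = np.abs(W[:, t_sel]) ** 2

    margin = np.ceil(scales * good.rate).astype(int)  # one envelope sd
    idx = np.arange(n_t)
    valid = (idx[None, :] >= margin[:, None]) & (idx[None, :] < n_t - margin[:, None])
    return TFMap(
        power=power.reshape(n_ch, n_tr, freqs.size, t_sel.size),
        freqs=freqs,
        times=good.times[t_sel],
        normalization="raw",
        conditions=list(good.conditions),
        trial_index=good.trial_index,
        channel_ids=list(good.channel_ids),
        valid_mask=valid[:, t_sel],
    )


def prestim_z_normalize(tf: TFMap, paradigm: ParadigmSpec,
                        mode: str = "condition_specific") -> TFMap:
    """z-score power against the prestimulus (or whole-recording) pool.

    ``condition_specific``: for each channel × frequency × condition,
    μ and σ are computed over the pooled prestimulus samples (the final
    ``normalization_window_s`` before cue onset) of all trials in that
    condition; each trial of the condition is then standardized.
    ``whole_recording``: the pool is every valid sample of every trial,
    regardless of condition.
    """
    if mode not in {"condition_specific", "whole_recording"}:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    if tf.normalization != "raw":
        raise ValidationError("input must be raw power")
    win = (tf.times >= -paradigm.normalization_window_s - 1e-9) & (tf.times < 0)
    if mode == "condition_specific" and not win.any():
        raise ValidationError("no prestimulus samples available for normalization")

    n_ch, n_tr, n_f, n_t = tf.power.shape
    z = np.empty_like(tf.power)
    conditions = np.asarray(tf.conditions)
    groups = ([conditions == c for c in dict.fromkeys(tf.conditions)]
              if mode == "condition_specific" else [np.ones(n_tr, dtype=bool)])
    n_zero = 0
    for rows in groups:
        for fi in range(n_f):
            pool_t = (win & tf.valid_mask[fi]) if mode == "condition_specific" \
                else tf.valid_mask[fi]
            if not pool_t.any():
                pool_t = win if mode == "condition_specific" else np.ones(n_t, bool)
            pool = tf.power[:, rows][:, :, fi][:, :, pool_t]  # ch × trials × t
            mu = pool.reshape(n_ch, -1).mean(axis=1)
            sd = pool.reshape(n_ch, -1).std(axis=1)
            zero = sd == 0
            n_zero += int(zero.sum())
            sd = np.where(zero, 1.0, sd)
            zi = (tf.power[:, rows][:, :, fi] - mu[:, None, None]) / sd[:, None, None]
            zi[zero] = 0.0
            z[:, rows, fi] = zi
    if n_zero:
        warnings.warn(f"{n_zero} (channel × frequency) strata had zero "
                      "baseline variance; set to 0")
    tag = "prestim_z" if mode == "condition_specific" else "recording_z"
    return TFMap(
        power=z, freqs=tf.freqs, times=tf.times, normalization=tag,
        conditions=list(tf.conditions), trial_index=tf.trial_index,
        channel_ids=list(tf.channel_ids), valid_mask=tf.valid_mask,
    )


def channel_average_maps(tf: TFMap, condition: str) -> np.ndarray:
    """Trial-averaged map per channel for one condition (ch × f × t)."""
    rows = tf.trials_of(condition)
    return tf.power[:, rows].mean(axis=1)


def condition_difference_map(tf: TFMap, cond_a: str, cond_b: str) -> np.ndarray:
    """Trial-averaged A-minus-B difference map, channels × freq × time."""
    return channel_average_maps(tf, cond_a) - channel_average_maps(tf, cond_b)


def band_power_trace(tf: TFMap, band_hz: tuple[float, float] = (4.0, 6.0),
                     window_s: tuple[float, float] | None = None,
                     per_trial: bool = True) -> np.ndarray:
    """Mean power over a frequency band.

    Returns channels × trials × time (``per_trial``) or channels × time
    (trial-averaged).  With ``window_s`` the time axis is additionally
    averaged over the window (∩ the validity mask), yielding one scalar
    per (channel, trial).
    """
    sel = (tf.freqs >= band_hz[0]) & (tf.freqs <= band_hz[1])
    if not sel.any():
        raise ValidationError(
            f"band {band_hz} does not intersect the frequency axis "
            f"[{tf.freqs[0]:.3g}, {tf.freqs[-1]:.3g}] Hz"
        )
    trace = tf.power[:, :, sel].mean(axis=2)  # ch × tr × t
    if window_s is not None:
        t_in = (tf.times >= window_s[0]) & (tf.times <= window_s[1])
        t_in &= tf.valid_mask[sel].all(axis=0)
        if not t_in.any():
            raise ValidationError(f"window {window_s} has no valid samples")
        trace = trace[:, :, t_in].mean(axis=2)  # ch × tr
    if not per_trial:
        trace = trace.mean(axis=1)
    return trace
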