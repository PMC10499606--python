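"""Signal conditioning and epoching for task recordings.

The chain order is fixed: polyphase resampling → zero-phase notch at
the line frequency and its 2nd–3rd harmonics → Laplacian rereference
along each electrode shaft → epoching around cue onset → amplitude
artifact flagging.  Artifact exclusion is the single downstream gate:
every statistic consumes only unflagged trials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EventTable, ParadigmSpec, Recording, ValidationError

__all__ = [
    "TrialEpochs",
    "resample",
    "notch_filter",
    "laplacian_reref",
    "epoch",
    "detect_artifact_trials",
]

logger = logging.getLogger(__name__)


@dataclass
class TrialEpochs:
    """Channels × trials × time epochs (μV) with per-trial metadata."""

    data: np.ndarray
    rate: float
    times: np.ndarray  # s relative to cue onset (onset at 0)
    conditions: list[str]
    trial_index: np.ndarray  # 1-based presentation order
    channel_ids: list[str]
    artifact_flag: np.ndarray | None = None
    reref_scheme: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("data must be channels × trials × time")
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size != self.data.shape[2]:
            raise ValidationError("time axis does not match data")
        step = np.diff(self.times)
        if step.size and not np.allclose(step, 1.0 / self.rate, rtol=1e-6):
            raise ValidationError("time axis must be uniform at 1/rate")
        if self.artifact_flag is None:
            self.artifact_flag = np.zeros(self.data.shape[1], dtype=bool)
        self.artifact_flag = np.asarray(self.artifact_flag, dtype=bool)
        self.trial_index = np.asarray(self.trial_index, dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def good(self) -> "TrialEpochs":
        """The unflagged trials only."""
        keep = ~self.artifact_flag
        return TrialEpochs(
            data=self.data[:, keep],
            rate=self.rate,
            times=self.times,
            conditions=[c for c, k in zip(self.conditions, keep) if k],
            trial_index=self.trial_index[keep],
            channel_ids=list(self.channel_ids),
            artifact_flag=np.zeros(int(keep.sum()), dtype=bool),
            reref_scheme=self.reref_scheme,
        )

    def crop(self, t_min: float, t_max: float) -> "TrialEpochs":
        sel = (self.times >= t_min - 1e-9) & (self.times <= t_max + 1e-9)
        return TrialEpochs(
            data=self.data[:, :, sel],
            rate=self.rate,
            times=self.times[sel],
            conditions=list(self.conditions),
            trial_index=self.trial_index,
            channel_ids=list(self.channel_ids),
            artifact_flag=self.artifact_flag,
            reref_scheme=self.reref_scheme,
        )


# --------------------------------------------------------------------


def resample(rec: Recording, target_hz: float) -> Recording:
    """Anti-aliased polyphase downsampling (e.g. 1,024 → 1,000 Hz)."""
    if target_hz > rec.rate:
        raise ValidationError(
            f"upsampling not supported (rate {rec.rate} → {target_hz})"
        )
    if target_hz == rec.rate:
        return rec
    frac = Fraction(target_hz / rec.rate).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    logger.info("resampled %.6g Hz → %.6g Hz (%d/%d)", rec.rate, target_hz,
                frac.numerator, frac.denominator)
    return rec.copy_with(samples=out, rate=float(target_hz))


def notch_filter(rec: Recording, line_hz: float = 60.0,
                 harmonics: tuple[int, ...] = (2, 3),
                 width_hz: float = 1.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop at the line frequency and harmonics."""
    nyq = rec.rate / 2.0
    targets = [line_hz * h for h in (1, *harmonics)]
    if max(targets) + width_hz >= nyq:
        raise ValidationError(
            f"notch at {max(targets)} Hz is at or above Nyquist ({nyq} Hz)"
        )
    out = rec.samples
    for f0 in targets:
        sos = signal.butter(order, [f0 - width_hz, f0 + width_hz],
                            btype="bandstop", fs=rec.rate, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=1)
    return rec.copy_with(samples=out)


def laplacian_reref(rec: Recording) -> Recording:
    """Rereference each contact to the mean of its shaft neighbours.

    Interior contacts: x_i − (x_prev + x_next)/2, where prev/next are
    the nearest *good* contacts along the shaft (bad channels are
    skipped).  Shaft-edge contacts fall back to a bipolar reference
    against their single neighbour.  Shafts with fewer than two good
    contacts are dropped with a warning.
    """
    if rec.reref_scheme != "none":
        raise ValidationError(
            f"recording already rereferenced ({rec.reref_scheme}); refusing to stack schemes"
        )
    if rec.channel_geometry is None:
        raise ValidationError("laplacian_reref requires channel_geometry")
    out_samples = []
    out_ids = []
    for shaft in rec.channel_geometry:
        good = [c for c in shaft if c not in rec.bad_channels]
        if len(good) < 2:
            warnings.warn(f"shaft {shaft}: fewer than 2 good contacts; dropped")
            continue
        idx = [rec.channel_index(c) for c in good]
        x = rec.samples[idx]
        for pos, cid in enumerate(good):
            if pos == 0:
                ref = x[1]
            elif pos == len(good) - 1:
                ref = x[-2]
            else:
                ref = 0.5 * (x[pos - 1] + x[pos + 1])
            out_samples.append(x[pos] - ref)
            out_ids.append(cid)
    if not out_samples:
        raise ValidationError("no shaft with ≥ 2 good contacts")
    return Recording(
        samples=np.array(out_samples),
        rate=rec.rate,
        channel_ids=out_ids,
        channel_geometry=[[c for c in shaft if c in out_ids]
                          for shaft in rec.channel_geometry],
        reref_scheme="laplacian",
    )


def epoch(rec: Recording, events: EventTable, paradigm: ParadigmSpec) -> TrialEpochs:
    """Cut [−prestim_s, trial_end] epochs around each cue onset.

    Trials whose full window falls outside the recording are dropped
    with a warning (and the count logged).
    """
    n_pre = int(round(paradigm.prestim_s * rec.rate))
    n_post = int(round((paradigm.total_s - paradigm.prestim_s) * rec.rate))
    n_len = n_pre + n_post
    times = (np.arange(n_len) - n_pre) / rec.rate

    data, conds, tidx = [], [], []
    dropped = 0
    for onset, label, index in zip(events.onsets, events.labels, events.trial_index):
        start = int(round(onset * rec.rate)) - n_pre
        if start < 0 or start + n_len > rec.n_samples:
            dropped += 1
            continue
        data.append(rec.samples[:, start:start + n_len])
        conds.append(label)
        tidx.append(index)
    if dropped:
        warnings.warn(f"{dropped} trial(s) truncated at recording edge; dropped")
        logger.info("epoch: dropped %d truncated trial(s)", dropped)
    arr = (np.stack(data, axis=1) if data
           else np.empty((rec.n_channels, 0, n_len)))
    return TrialEpochs(
        data=arr,
        rate=rec.rate,
        times=times,
        conditions=conds,
        trial_index=np.array(tidx, dtype=np.int64),
        channel_ids=list(rec.channel_ids),
        reref_scheme=rec.reref_scheme,
    )


def detect_artifact_trials(epochs: TrialEpochs, k_sd: float = 4.0) -> TrialEpochs:
    """Flag trials containing any sample outside mean ± k·sd.

    The threshold band is computed per channel over all of that
    channel's trials concatenated (spikes included, matching a
    normalization to the recorded signal itself rather than a robust
    estimator).  A trial is flagged if any sample on any channel falls
    strictly outside the band.  Zero-variance channels contribute no
    flags (warning).
    """
    n_ch, n_tr, n_t = epochs.data.shape
    flags = np.zeros(n_tr, dtype=bool)
    for ch in range(n_ch):
        x = epochs.data[ch]  # trials × time
        mu = x.mean()
        sd = x.std()
        if sd == 0:
            warnings.warn(
                f"channel {epochs.channel_ids[ch]}: zero variance; no artifact flags"
            )
            continue
        lo, hi = mu - k_sd * sd, mu + k_sd * sd
        flags |= np.any((x < lo) | (x > hi), axis=1)
    out = TrialEpochs(
        data=epochs.data,
        rate=epochs.rate,
        times=epochs.times,
        conditions=list(epochs.conditions),
        trial_index=epochs.trial_index,
        channel_ids=list(epochs.channel_ids),
        artifact_flag=flags,
        reref_scheme=epochs.reref_scheme,
    )
    logger.info("artifact rule: flagged %d / %d trials", int(flags.sum()), n_tr)
    return out
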