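"""Minimal EDF writer (16-bit European Data Format).

Clinical iEEG systems export EDF, so the pipeline accepts it as an
interchange format.  Reading goes through MNE; writing — needed for
round-trip tests and for exporting synthetic recordings — is
implemented here directly against the EDF specification: a 256-byte
fixed header, 256 bytes of per-signal header fields, then data records
of little-endian 16-bit integers with a per-signal linear
physical/digital mapping.  Only the subset the pipeline needs is
implemented (continuous recordings, one physical dimension, no
annotations).
"""

from __future__ import annotations

import datetime
import warnings

import numpy as np

__all__ = ["write_edf", "read_edf_labels"]

# symmetric digital range: digital 0 decodes to exactly 0.0 μV
_DIG_MIN, _DIG_MAX = -32767, 32767


def _field(value: str, width: int) -> bytes:
    b = str(value).encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(path, samples: np.ndarray, rate: float, channel_ids, *,
              physical_dim: str = "uV", record_s: float = 1.0) -> None:
    """Write ``samples`` (channels × timepoints, μV) to an EDF file.

    The physical range of each channel is set to its symmetric absolute
    maximum, so quantization error is at most ``max|x| / 32767`` per
    channel.  Signals whose length is not a whole number of records are
    zero-padded to the record boundary (with a warning).
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise ValueError("samples must be channels × timepoints")
    n_ch, n_t = samples.shape
    spr = rate * record_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(
            f"rate {rate} Hz is not an integer number of samples per "
            f"{record_s} s record"
        )
    spr = int(round(spr))
    n_rec = int(np.ceil(n_t / spr))
    if n_rec * spr != n_t:
        warnings.warn(
            f"signal length {n_t} padded with zeros to {n_rec} records "
            f"of {spr} samples"
        )
        pad = np.zeros((n_ch, n_rec * spr - n_t))
        samples = np.concatenate([samples, pad], axis=1)

    # physical range per channel: symmetric, with the bound taken from
    # its own 8-char ASCII header field so encoder and reader use the
    # identical linear map (the header text is the source of truth);
    # degenerate (constant-zero) channels get a unit range
    pmax_raw = np.abs(samples).max(axis=1)
    pmax_raw = np.where(pmax_raw > 0, pmax_raw, 1.0)
    pmax_txt = [f"{v:.5g}" for v in pmax_raw]
    if any(len(t) > 7 for t in pmax_txt):
        raise ValueError("physical range too wide for an 8-char EDF field")
    pmax = np.array([float(t) for t in pmax_txt])
    pmin = -pmax
    digital = np.round(samples / pmax[:, None] * _DIG_MAX)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field(repr(float(record_s)).rstrip("0").rstrip("."), 8),
            _field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(c, 16) for c in channel_ids),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(physical_dim, 8) for _ in range(n_ch)),
            b"".join(_field("-" + pmax_txt[i], 8) for i in range(n_ch)),
            b"".join(_field(pmax_txt[i], 8) for i in range(n_ch)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    # data records: record-major, signal-minor
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())


def read_edf_labels(path) -> list[str]:
    """Read just the channel labels from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header ({len(head)} bytes)")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header (signal count)") from exc
        raw = fh.read(16 * n_ch)
    if len(raw) < 16 * n_ch:
        raise ValueError(f"{path}: truncated EDF signal header")
    return [raw[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
            for i in range(n_ch)]
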