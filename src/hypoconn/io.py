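"""Readers and writers for the standard on-disk formats.

Signals travel as EDF (clinical interchange, quantized to 16 bits) or
as an HDF5 container (lossless, the internal format); events and
tabular results as TSV; voxel maps as NIfTI; results as JSON.  All
downstream stages consume only the in-memory containers — no stage
reads files directly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._edf import read_edf_labels, write_edf
from .containers import (
    DEFAULT_VOCABULARY,
    EventTable,
    Recording,
    StreamlineMap,
    ValidationError,
)

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_voxelmap",
    "write_voxelmap",
]


class FormatError(IOError):
    """A file did not parse under its declared standard."""


# --------------------------------------------------------------------
# recordings


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".h5", ".hdf5", ".hc5"}:
        return "hdf5"
    raise FormatError(f"cannot infer signal format from suffix {suffix!r}")


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read an EDF or HDF5-container recording; samples returned in μV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _detect_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "hdf5":
        return _read_h5(path)
    raise FormatError(f"unknown format {fmt!r}")


def _read_edf(path: Path) -> Recording:
    try:
        labels = read_edf_labels(path)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ValidationError(f"duplicate channel labels in {path}: {dupes}")
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for bad records
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    return Recording(
        samples=data_uv,
        rate=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
    )


def _read_h5(path: Path) -> Recording:
    try:
        with h5py.File(path, "r") as fh:
            grp = fh["recording"]
            samples = grp["samples"][()]
            rate = float(grp.attrs["rate"])
            channel_ids = [c.decode() if isinstance(c, bytes) else str(c)
                           for c in grp["channel_ids"][()]]
            bad = [c.decode() if isinstance(c, bytes) else str(c)
                   for c in grp["bad_channels"][()]] if "bad_channels" in grp else []
            geometry = (json.loads(grp.attrs["channel_geometry"])
                        if "channel_geometry" in grp.attrs else None)
            scheme = grp.attrs.get("reref_scheme", "none")
    except (KeyError, OSError) as exc:
        raise FormatError(f"unreadable container {path}: {exc}") from exc
    return Recording(
        samples=samples,
        rate=rate,
        channel_ids=channel_ids,
        channel_geometry=geometry,
        bad_channels=set(bad),
        reref_scheme=str(scheme),
    )


def write_recording(rec: Recording, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "edf":
        write_edf(path, rec.samples, rec.rate, rec.channel_ids)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("recording")
            grp.create_dataset("samples", data=rec.samples)
            grp.attrs["rate"] = rec.rate
            grp.create_dataset("channel_ids",
                               data=np.array(rec.channel_ids, dtype="S"))
            grp.create_dataset("bad_channels",
                               data=np.array(sorted(rec.bad_channels), dtype="S"))
            if rec.channel_geometry is not None:
                grp.attrs["channel_geometry"] = json.dumps(rec.channel_geometry)
            grp.attrs["reref_scheme"] = rec.reref_scheme
    else:
        raise FormatError(f"unknown format {fmt!r}")


# --------------------------------------------------------------------
# events


def read_events(path, vocabulary: frozenset[str] = DEFAULT_VOCABULARY) -> EventTable:
    """Read a TSV with columns ``onset``, ``label`` (optional ``trial_index``)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return EventTable(onsets=np.empty(0), labels=[])
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(np.sort(onsets)) == 0):
        warnings.warn("duplicate event onsets; keeping stable file order")
    table = EventTable(
        onsets=onsets,
        labels=df["label"].astype(str).tolist(),
        trial_index=(df["trial_index"].to_numpy(dtype=int)
                     if "trial_index" in df.columns else None),
    )
    table.validate_vocabulary(vocabulary)
    return table


def write_events(events: EventTable, path) -> None:
    pd.DataFrame(
        {
            "onset": events.onsets,
            "label": events.labels,
            "trial_index": events.trial_index,
        }
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------
# voxel maps


def read_voxelmap(path, mask_path=None, n_samples_per_voxel: int = 5000) -> StreamlineMap:
    """Read a NIfTI streamline-probability map (plus optional seed mask).

    Without a companion mask, the seed mask defaults to the map's
    nonzero voxels.  All computation downstream is in 0-based voxel
    indices; the affine is carried for provenance only.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.squeeze(np.asanyarray(mask_img.dataobj)) > 0
        if mask.shape != data.shape:
            raise ValidationError(
                f"mask grid {mask.shape} does not match map grid {data.shape}"
            )
    else:
        mask = data != 0
        if not mask.any():
            raise ValidationError(
                "all-zero map with no companion mask: seed mask undefined"
            )
    return StreamlineMap(
        grid_shape=data.shape,
        seed_mask=mask,
        probability=data,
        n_samples_per_voxel=n_samples_per_voxel,
        affine=np.asarray(img.affine),
    )


def write_voxelmap(smap: StreamlineMap, path, mask_path=None) -> None:
    import nibabel as nib

    affine = smap.affine if smap.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(smap.probability.astype(np.float64), affine), str(path))
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(smap.seed_mask.astype(np.uint8), affine), str(mask_path)
        )
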