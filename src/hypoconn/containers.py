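"""Core in-memory containers shared by every pipeline stage.

Conventions enforced throughout the package:

* signal samples are microvolts (μV), channels × timepoints;
* time is seconds relative to recording start; epoch time is seconds
  relative to cue / stimulus onset with the onset at t = 0;
* voxel coordinates are 0-based integer indices (the NIfTI affine is
  retained for provenance only, never used in computation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Recording",
    "EventTable",
    "ParadigmSpec",
    "WaveletSpec",
    "PermutationSpec",
    "RunConfig",
    "StreamlineMap",
    "DEFAULT_VOCABULARY",
    "ValidationError",
]

#: condition labels the pipeline knows about out of the box
DEFAULT_VOCABULARY = frozenset(
    {
        "sweet_fat",
        "taste_neutral",
        "gain",
        "loss",
        "zero_gain",
        "zero_loss",
        "stim_pulse",
    }
)


class ValidationError(ValueError):
    """An input violated a container invariant."""


@dataclass
class Recording:
    """A continuous multichannel recording in μV.

    Parameters
    ----------
    samples
        ``(n_channels, n_timepoints)`` float array, microvolts.
    rate
        Sampling frequency in Hz.
    channel_ids
        Ordered unique channel labels.
    channel_geometry
        Optional list of shafts; each shaft is the ordered list of
        channel labels along that electrode (innermost contact first).
        Required by the Laplacian rereference.
    bad_channels
        Labels excluded from rereferencing neighbourhoods and common
        averages.
    reref_scheme
        One of ``none | laplacian | common_average | bipolar``.
    """

    samples: np.ndarray
    rate: float
    channel_ids: list[str]
    channel_geometry: list[list[str]] | None = None
    bad_channels: set[str] = field(default_factory=set)
    reref_scheme: str = "none"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (channels × timepoints)")
        if self.rate <= 0:
            raise ValidationError(f"rate must be positive, got {self.rate}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            dupes = {c for c in self.channel_ids if self.channel_ids.count(c) > 1}
            raise ValidationError(f"duplicate channel labels: {sorted(dupes)}")
        self.bad_channels = set(self.bad_channels)
        unknown = self.bad_channels - set(self.channel_ids)
        if unknown:
            raise ValidationError(f"bad_channels not in channel_ids: {sorted(unknown)}")
        if self.channel_geometry is not None:
            geom = [list(map(str, shaft)) for shaft in self.channel_geometry]
            flat = [c for shaft in geom for c in shaft]
            unknown = set(flat) - set(self.channel_ids)
            if unknown:
                raise ValidationError(
                    f"channel_geometry names unknown channels: {sorted(unknown)}"
                )
            self.channel_geometry = geom
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        return self.channel_ids.index(label)

    def copy_with(self, **kwargs) -> "Recording":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EventTable:
    """Trial onsets (s from recording start) with condition labels."""

    onsets: np.ndarray
    labels: list[str]
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        self.labels = [str(l) for l in self.labels]
        if self.onsets.ndim != 1 or len(self.labels) != self.onsets.size:
            raise ValidationError("onsets and labels must have equal length")
        order = np.argsort(self.onsets, kind="stable")
        self.onsets = self.onsets[order]
        self.labels = [self.labels[i] for i in order]
        if self.trial_index is None:
            self.trial_index = np.arange(1, self.onsets.size + 1)
        else:
            self.trial_index = np.asarray(self.trial_index, dtype=np.int64)[order]

    def __len__(self) -> int:
        return self.onsets.size

    def validate_vocabulary(self, vocabulary: frozenset[str] = DEFAULT_VOCABULARY) -> None:
        unknown = set(self.labels) - set(vocabulary)
        if unknown:
            raise ValidationError(
                f"unknown condition labels {sorted(unknown)}; "
                f"declared vocabulary: {sorted(vocabulary)}"
            )


@dataclass
class ParadigmSpec:
    """Trial segment durations (s) for the cued-incentive paradigms.

    The sweet-fat default is 2 s fixation, 1 s cue, 2 s post-cue
    fixation, 3 s delivery, 2 s consumption — a 10 s trial.  The
    monetary variant uses a 2 s cue.
    """

    prestim_s: float = 2.0
    cue_s: float = 1.0
    postcue_fix_s: float = 2.0
    delivery_s: float = 3.0
    consume_s: float = 2.0
    normalization_window_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("prestim_s", "cue_s", "postcue_fix_s", "delivery_s", "consume_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be ≥ 0")
        if not 0 < self.normalization_window_s <= self.prestim_s:
            raise ValidationError(
                "normalization_window_s must lie within the prestimulus segment"
            )

    @classmethod
    def monetary(cls) -> "ParadigmSpec":
        return cls(prestim_s=2.0, cue_s=2.0, postcue_fix_s=2.0, delivery_s=2.0, consume_s=2.0)

    @property
    def total_s(self) -> float:
        return self.prestim_s + self.cue_s + self.postcue_fix_s + self.delivery_s + self.consume_s

    @property
    def anticipation_s(self) -> float:
        """Cue plus post-cue fixation — the analysis window of interest."""
        return self.cue_s + self.postcue_fix_s


@dataclass
class WaveletSpec:
    """Analytic-Morlet decomposition parameters.

    ``voices_per_octave`` controls the density of the log-spaced
    frequency axis (consecutive frequencies differ by ``2**(1/voices)``).
    """

    f_min: float = 3.0
    f_max: float = 250.0
    voices_per_octave: int = 32
    omega0: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValidationError("need 0 < f_min < f_max")
        if self.voices_per_octave < 1:
            raise ValidationError("voices_per_octave must be ≥ 1")

    def frequencies(self) -> np.ndarray:
        """Log-spaced axis f_min · 2^(k/voices) up to f_max (inclusive)."""
        n = int(np.floor(self.voices_per_octave * np.log2(self.f_max / self.f_min))) + 1
        return self.f_min * 2.0 ** (np.arange(n) / self.voices_per_octave)


@dataclass
class PermutationSpec:
    n_permutations: int = 1000
    alpha_voxel: float = 0.05
    alpha_cluster: float = 0.05
    adjacency: str = "4-connectivity"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be ≥ 1")
        for a in (self.alpha_voxel, self.alpha_cluster):
            if not 0 < a < 1:
                raise ValidationError("alpha must be in (0, 1)")


@dataclass
class RunConfig:
    """Run configuration chaining every pipeline stage.

    All randomness flows from named entries in ``seeds``; no operation
    draws from a global generator.
    """

    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    permutation: PermutationSpec = field(default_factory=PermutationSpec)
    seeds: dict[str, int] = field(default_factory=dict)
    output_dir: str = "."

    def seed_for(self, stage: str, default: int = 0) -> int:
        return int(self.seeds.get(stage, default))

    def to_yaml(self, path) -> None:
        doc = {
            "paradigm": dataclasses.asdict(self.paradigm),
            "wavelet": dataclasses.asdict(self.wavelet),
            "permutation": dataclasses.asdict(self.permutation),
            "seeds": dict(self.seeds),
            "output_dir": self.output_dir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            paradigm=ParadigmSpec(**doc.get("paradigm", {})),
            wavelet=WaveletSpec(**doc.get("wavelet", {})),
            permutation=PermutationSpec(**doc.get("permutation", {})),
            seeds={k: int(v) for k, v in (doc.get("seeds") or {}).items()},
            output_dir=doc.get("output_dir", "."),
        )


@dataclass
class StreamlineMap:
    """Voxelwise streamline-probability map for one seed structure.

    ``probability[v]`` is the fraction of the ``n_samples_per_voxel``
    streamlines seeded in voxel ``v`` that reached the target;
    ``waytotal`` is the total number of target-reaching streamlines
    summed over the seed mask.
    """

    grid_shape: tuple[int, int, int]
    seed_mask: np.ndarray  # boolean, grid_shape
    probability: np.ndarray  # float, grid_shape (zero outside mask)
    n_samples_per_voxel: int = 5000
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        self.probability = np.asarray(self.probability, dtype=np.float64)
        if self.seed_mask.shape != self.grid_shape:
            raise ValidationError(
                f"mask grid {self.seed_mask.shape} != map grid {self.grid_shape}"
            )
        if self.probability.shape != self.grid_shape:
            raise ValidationError(
                f"probability grid {self.probability.shape} != map grid {self.grid_shape}"
            )
        if not self.seed_mask.any():
            raise ValidationError("seed mask is empty")
        vals = self.probability[self.seed_mask]
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError("streamline probabilities must lie in [0, 1]")

    @property
    def v_seed(self) -> int:
        return int(self.seed_mask.sum())

    @property
    def seed_values(self) -> np.ndarray:
        return self.probability[self.seed_mask]

    @property
    def waytotal(self) -> int:
        return int(np.round(self.seed_values * self.n_samples_per_voxel).sum())

    def voxel_waytotals(self) -> np.ndarray:
        return np.round(self.seed_values * self.n_samples_per_voxel).astype(np.int64)
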