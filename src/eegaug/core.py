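"""Domain containers for paired EEG/stimulus data.

An :class:`EEGSegment` is one epoch of multi-channel EEG, shaped
``[channels, time]`` (axis 0 = channels, axis 1 = time, everywhere in the
package).  Segments are bundled with either a mel-spectrogram reconstruction
target or an integer class label into a :class:`DatasetBundle`, the unit all
training and evaluation code consumes.  Bundles round-trip through HDF5
(primary) or NPZ (fallback) containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np

__all__ = [
    "EEGSegment",
    "StimulusTarget",
    "DatasetBundle",
    "zscore_normalize",
    "split_for_augmentation",
    "save_bundle",
    "load_bundle",
]

Task = Literal["reconstruction", "classification"]


@dataclass
class EEGSegment:
    """One EEG epoch: ``data[channels, time]`` at sampling rate ``fs`` Hz."""

    data: np.ndarray
    fs: float = 64.0
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"EEG segment must be 2-D [channels, time], got ndim={self.data.ndim}")
        c, t = self.data.shape
        if c < 1:
            raise ValueError("EEG segment needs at least one channel")
        if t < 10:
            raise ValueError("EEG segment needs at least 10 time samples "
                             "(block-based augmentations split the epoch into 10 segments)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG segment contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EEGSegment":
        return EEGSegment(self.data.copy(), fs=self.fs, subject_id=self.subject_id)


@dataclass
class StimulusTarget:
    """Reconstruction target (``spec[mel_bins, frames]``) or class ``label``."""

    spec: np.ndarray | None = None
    label: int | None = None

    def __post_init__(self):
        if (self.spec is None) == (self.label is None):
            raise ValueError("StimulusTarget needs exactly one of spec or label")
        if self.spec is not None:
            self.spec = np.asarray(self.spec, dtype=np.float64)
            if self.spec.ndim != 2 or self.spec.shape[0] < 1:
                raise ValueError("spectrogram target must be 2-D [mel_bins, frames]")
        else:
            self.label = int(self.label)
            if self.label < 0:
                raise ValueError("class label must be non-negative")


@dataclass
class DatasetBundle:
    """Matched segments and targets for one task."""

    segments: list[EEGSegment]
    targets: list[StimulusTarget]
    task: Task = "reconstruction"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.segments) != len(self.targets):
            raise ValueError(f"{len(self.segments)} segments but {len(self.targets)} targets")
        shapes = {s.data.shape for s in self.segments}
        if len(shapes) > 1:
            raise ValueError(f"heterogeneous segment shapes in bundle: {sorted(shapes)}")
        for t in self.targets:
            if self.task == "reconstruction" and t.spec is None:
                raise ValueError("reconstruction bundle requires spectrogram targets")
            if self.task == "classification" and t.label is None:
                raise ValueError("classification bundle requires label targets")

    def __len__(self) -> int:
        return len(self.segments)

    def subset(self, indices: Sequence[int]) -> "DatasetBundle":
        return DatasetBundle([self.segments[i] for i in indices],
                             [self.targets[i] for i in indices],
                             task=self.task, meta=dict(self.meta))

    def eeg_array(self) -> np.ndarray:
        """Stacked EEG, shape [N, channels, time]."""
        return np.stack([s.data for s in self.segments])

    def target_array(self) -> np.ndarray:
        if self.task == "reconstruction":
            return np.stack([t.spec for t in self.targets])
        return np.array([t.label for t in self.targets], dtype=np.int64)


def zscore_normalize(segment: EEGSegment) -> EEGSegment:
    """Standardize each channel to zero mean and unit (population) variance.

    Constant channels cannot be standardized; they are returned as all-zeros
    with a warning rather than dividing by zero.
    """
    data = segment.data
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)  # population (1/N) convention
    flat = sd[:, 0] == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant channel(s) set to zero during "
                      "z-score normalization", stacklevel=2)
    sd = np.where(sd == 0, 1.0, sd)
    out = (data - mu) / sd
    out[flat] = 0.0
    return EEGSegment(out, fs=segment.fs, subject_id=segment.subject_id)


def split_for_augmentation(bundle: DatasetBundle, fraction: float = 0.1,
                           seed: int = 0) -> tuple[DatasetBundle, DatasetBundle]:
    """Hold out ``round(fraction * N)`` segments for the augmentation stream.

    Returns ``(plain, enhanced)``; the partition is disjoint, exhaustive and
    reproducible given the seed.  The default fraction of 10% matches the
    framework's training protocol.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    n = len(bundle)
    n_enh = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    enhanced_idx = np.sort(perm[:n_enh])
    plain_idx = np.sort(perm[n_enh:])
    return bundle.subset(plain_idx.tolist()), bundle.subset(enhanced_idx.tolist())


def save_bundle(bundle: DatasetBundle, path: str | Path) -> None:
    """Write a bundle to ``.h5`` (datasets ``eeg``, ``target``) or ``.npz``."""
    path = Path(path)
    eeg = bundle.eeg_array()
    target = bundle.target_array()
    fs = bundle.segments[0].fs if bundle.segments else 64.0
    subjects = [s.subject_id for s in bundle.segments]
    if path.suffix == ".npz":
        np.savez(path, eeg=eeg, target=target, fs=fs, task=bundle.task,
                 subject_id=np.array(subjects, dtype=object))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=eeg)
        f.create_dataset("target", data=target)
        f.attrs["fs"] = fs
        f.attrs["task"] = bundle.task
        f.create_dataset("subject_id", data=np.array(subjects, dtype="S"))


def _build_bundle(eeg: np.ndarray, target: np.ndarray, fs: float, task: str,
                  subjects: list[str]) -> DatasetBundle:
    if eeg.ndim != 3:
        raise ValueError(f"'eeg' dataset must be [N, channels, time], got shape {eeg.shape}")
    if eeg.shape[0] != target.shape[0]:
        raise ValueError(f"'eeg' has {eeg.shape[0]} segments but 'target' has {target.shape[0]}")
    segments = [EEGSegment(e, fs=fs, subject_id=s) for e, s in zip(eeg, subjects)]
    if task == "reconstruction":
        targets = [StimulusTarget(spec=t) for t in target]
    else:
        targets = [StimulusTarget(label=int(t)) for t in target]
    return DatasetBundle(segments, targets, task=task)


def load_bundle(path: str | Path) -> DatasetBundle:
    """Read a bundle written by :func:`save_bundle` (HDF5 or NPZ dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=True) as f:
            for key in ("eeg", "target"):
                if key not in f:
                    raise KeyError(f"bundle file {path} is missing required field '{key}'")
            subjects = [str(s) for s in f["subject_id"]] if "subject_id" in f \
                else [""] * f["eeg"].shape[0]
            return _build_bundle(f["eeg"], f["target"], float(f["fs"]),
                                 str(f["task"]), subjects)
    with h5py.File(path, "r") as f:
        for key in ("eeg", "target"):
            if key not in f:
                raise KeyError(f"bundle file {path} is missing required field '{key}'")
        eeg = f["eeg"][...]
        subjects = [s.decode() for s in f["subject_id"][...]] if "subject_id" in f \
            else [""] * eeg.shape[0]
        return _build_bundle(eeg, f["target"][...], float(f.attrs["fs"]),
                             str(f.attrs["task"]), subjects)
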