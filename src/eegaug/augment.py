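"""The seven EEG augmentation operators.

Each operator is a pure function of ``(segment, parameters, rng)``: it never
mutates its input, preserves the ``[channels, time]`` shape, and is
bit-reproducible given the same :class:`numpy.random.Generator` state.

The seven transforms — additive Gaussian noise, amplitude scaling, horizontal
(time) flip, vertical (channel) flip, temporal dislocation, time warping and
masking — perturb an epoch along the dimensions real recordings vary in
(noise floor, gain, timing) so a decoder trained on them generalizes better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EEGSegment

__all__ = [
    "AugmentationSpec",
    "AUGMENTATION_NAMES",
    "add_noise",
    "amplitude_scale",
    "horizontal_flip",
    "vertical_flip",
    "temporal_dislocation",
    "warp_blocks",
    "time_warp",
    "mask",
    "apply",
]

AUGMENTATION_NAMES = (
    "noise",
    "scale",
    "horizontal_flip",
    "vertical_flip",
    "temporal_dislocation",
    "time_warp",
    "mask",
)


def _out(segment: EEGSegment, data: np.ndarray) -> EEGSegment:
    return EEGSegment(data, fs=segment.fs, subject_id=segment.subject_id)


def add_noise(segment: EEGSegment, sigma: float = 0.1,
              rng: np.random.Generator | None = None) -> EEGSegment:
    """Add iid Gaussian noise with sd ``sigma`` relative to each channel's sd.

    Scaling the noise by the per-channel standard deviation keeps the
    augmentation strength invariant to the recording gain.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return segment.copy()
    rng = np.random.default_rng() if rng is None else rng
    scale_per_ch = segment.data.std(axis=1, keepdims=True)
    noise = rng.standard_normal(segment.data.shape) * (sigma * scale_per_ch)
    return _out(segment, segment.data + noise)


def amplitude_scale(segment: EEGSegment, low: float = 0.5, high: float = 2.0,
                    rng: np.random.Generator | None = None) -> EEGSegment:
    """Multiply the whole epoch by one gain g ~ Uniform[low, high]."""
    rng = np.random.default_rng() if rng is None else rng
    g = rng.uniform(low, high)
    return _out(segment, segment.data * g)


def horizontal_flip(segment: EEGSegment,
                    rng: np.random.Generator | None = None) -> EEGSegment:
    """Reverse the time axis (the epoch played backwards)."""
    return _out(segment, segment.data[:, ::-1].copy())


def vertical_flip(segment: EEGSegment,
                  rng: np.random.Generator | None = None) -> EEGSegment:
    """Reverse the channel ordering."""
    return _out(segment, segment.data[::-1, :].copy())


def _block_bounds(T: int, n_segments: int) -> np.ndarray:
    """Split [0, T) into n_segments blocks; the last block absorbs any remainder."""
    base = T // n_segments
    bounds = np.arange(0, n_segments + 1) * base
    bounds[-1] = T
    return bounds


def temporal_dislocation(segment: EEGSegment, n_segments: int = 10,
                         rng: np.random.Generator | None = None) -> EEGSegment:
    """Cut the epoch into ``n_segments`` equal time blocks and shuffle them.

    The permutation is uniform over all orderings (identity included); the
    multiset of sample values is conserved exactly.
    """
    T = segment.n_samples
    if T < n_segments:
        raise ValueError(f"cannot cut {T} samples into {n_segments} blocks")
    rng = np.random.default_rng() if rng is None else rng
    bounds = _block_bounds(T, n_segments)
    perm = rng.permutation(n_segments)
    blocks = [segment.data[:, bounds[i]:bounds[i + 1]] for i in perm]
    return _out(segment, np.concatenate(blocks, axis=1))


def _linear_resample(block: np.ndarray, new_len: int) -> np.ndarray:
    """Linearly interpolate each channel of [C, t] to length new_len."""
    t = block.shape[1]
    if new_len == t:
        return block.copy()
    old_x = np.arange(t, dtype=float)
    new_x = np.linspace(0.0, t - 1.0, new_len)
    return np.stack([np.interp(new_x, old_x, ch) for ch in block])


def _choose_stretched(n_segments: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask marking the uniformly chosen half of blocks to stretch."""
    return rng.permutation(n_segments) < n_segments // 2


def warp_blocks(segment: EEGSegment, n_segments: int = 10,
                stretch: tuple[float, float] = (1.5, 2.0),
                compress: tuple[float, float] = (0.5, 0.67),
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Variable-length warped signal before resampling back to T.

    The epoch is cut into ``n_segments`` equal blocks; a uniformly chosen half
    is stretched by per-block factors ~ U[1.5, 2], the rest compressed by
    factors ~ U[0.5, 0.67], each via linear interpolation.
    """
    if n_segments % 2 != 0:
        raise ValueError(f"n_segments must be even to stretch exactly half, got {n_segments}")
    T = segment.n_samples
    if T < n_segments:
        raise ValueError(f"cannot cut {T} samples into {n_segments} blocks")
    rng = np.random.default_rng() if rng is None else rng
    bounds = _block_bounds(T, n_segments)
    stretched = _choose_stretched(n_segments, rng)
    pieces = []
    for i in range(n_segments):
        block = segment.data[:, bounds[i]:bounds[i + 1]]
        factor = rng.uniform(*stretch) if stretched[i] else rng.uniform(*compress)
        new_len = max(2, int(round(block.shape[1] * factor)))
        pieces.append(_linear_resample(block, new_len))
    return np.concatenate(pieces, axis=1)


def time_warp(segment: EEGSegment, n_segments: int = 10,
              stretch: tuple[float, float] = (1.5, 2.0),
              compress: tuple[float, float] = (0.5, 0.67),
              rng: np.random.Generator | None = None) -> EEGSegment:
    """Stretch half of the time blocks, compress the other half, resample to T.

    See :func:`warp_blocks` for the warping itself; the warped signal is then
    linearly resampled back to the original length so batches stack.
    """
    warped = warp_blocks(segment, n_segments, stretch, compress, rng)
    return _out(segment, _linear_resample(warped, segment.n_samples))


def mask(segment: EEGSegment, ratio: float = 0.30,
         rng: np.random.Generator | None = None) -> EEGSegment:
    """Zero out ``round(ratio * C * T)`` scalar entries chosen uniformly.

    At the default 30% ratio a 64 x 1920 epoch has exactly 36,864 of its
    122,880 samples replaced by zero-valued mask tokens.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"mask ratio must lie in [0, 1], got {ratio}")
    n_total = segment.data.size
    n_mask = int(round(ratio * n_total))
    if n_mask == 0:
        return segment.copy()
    rng = np.random.default_rng() if rng is None else rng
    flat_idx = rng.choice(n_total, size=n_mask, replace=False)
    out = segment.data.copy()
    out.flat[flat_idx] = 0.0
    return _out(segment, out)


_REGISTRY = {
    "noise": add_noise,
    "scale": amplitude_scale,
    "horizontal_flip": horizontal_flip,
    "vertical_flip": vertical_flip,
    "temporal_dislocation": temporal_dislocation,
    "time_warp": time_warp,
    "mask": mask,
}


@dataclass
class AugmentationSpec:
    """A named augmentation with its parameters and RNG seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.name not in _REGISTRY:
            raise ValueError(
                f"unknown augmentation '{self.name}'; valid names: {', '.join(AUGMENTATION_NAMES)}")


def apply(spec: AugmentationSpec, segment: EEGSegment,
          rng: np.random.Generator | None = None) -> EEGSegment:
    """Dispatch to the named operator.  Never mutates the input segment."""
    fn = _REGISTRY[spec.name]
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return fn(segment, rng=rng, **spec.params)
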