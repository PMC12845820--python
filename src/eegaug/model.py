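"""NeuroBrain: a configurable encoder--decoder for auditory EEG decoding.

The encoder applies squeeze-and-excitation attention along the time axis and
then the channel axis (learning which time points and electrodes matter), a
1-D convolution extracting spatial structure, a GRU extracting temporal
structure, a stack of transposed convolutions, and a multi-receptive-field
(MRF) fusion module of three residual convolution branches with distinct
kernel sizes.  The decoder is exactly the final 1-D convolution: it maps the
encoder's feature map to a mel-spectrogram (reconstruction, three transposed
convolutions by default) or to class logits (classification, one transposed
convolution).

Layer widths are deliberately configuration-driven; the ``tiny`` preset
(8 channels, 128 samples, hidden 16) keeps desk-scale training in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import Conv1d, ConvTranspose1d, GRU, Linear, Module

__all__ = ["NeuroBrainConfig", "SEBlock", "MRFBlock", "NeuroBrain",
           "LinearBaseline", "tiny_config"]


@dataclass
class NeuroBrainConfig:
    channels: int = 64
    time_samples: int = 1920
    hidden_dim: int = 32
    gru_layers: int = 1
    n_transposed: int = 3          # 3 for reconstruction, 1 for classification
    mrf_kernel_sizes: tuple[int, int, int] = (3, 5, 7)
    se_reduction: int = 4
    task: str = "reconstruction"
    mel_bins: int = 10
    n_classes: int = 2
    conv_kernel: int = 3
    conv_stride: int = 1
    trans_kernel: int = 3
    use_se: bool = True            # removable for attention ablations

    def __post_init__(self):
        if self.n_transposed < 1:
            raise ValueError("need at least one transposed convolution")
        if len(self.mrf_kernel_sizes) != 3:
            raise ValueError("MRF takes exactly 3 kernel sizes")
        if any(k % 2 == 0 for k in self.mrf_kernel_sizes):
            raise ValueError("MRF kernel sizes must be odd (symmetric same-padding)")
        for axis_name, size in (("channels", self.channels),
                                ("time_samples", self.time_samples),
                                ("hidden_dim", self.hidden_dim)):
            if self.use_se and size % self.se_reduction != 0:
                raise ValueError(
                    f"se_reduction={self.se_reduction} must divide {axis_name}={size}")
        if self.task not in ("reconstruction", "classification"):
            raise ValueError(f"unknown task '{self.task}'")

    @property
    def frames(self) -> int:
        """Output frame count (time axis after the strided convolution)."""
        return (self.time_samples - 1) // self.conv_stride + 1


def tiny_config(task: str = "reconstruction", **overrides) -> NeuroBrainConfig:
    """Desk-scale preset used throughout the test-suite and examples."""
    cfg = NeuroBrainConfig(channels=8, time_samples=128, hidden_dim=16,
                           n_transposed=3 if task == "reconstruction" else 1,
                           task=task, mel_bins=4, n_classes=2)
    return replace(cfg, **overrides) if overrides else cfg


class SEBlock(Module):
    """Squeeze-and-excitation gate along ``axis`` ("channel" or "time").

    Squeeze: global average pool over the other axis.  Excite: two
    fully-connected layers ending in a sigmoid, giving gates in (0, 1).
    Scale: multiply the feature map by the gates, so outputs never exceed the
    inputs in absolute value.
    """

    def __init__(self, axis_size: int, axis: str, reduction: int,
                 rng: np.random.Generator):
        if axis not in ("channel", "time"):
            raise ValueError(f"axis must be 'channel' or 'time', got '{axis}'")
        if axis_size % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide axis size {axis_size}")
        self.axis = axis
        self.fc1 = Linear(axis_size, axis_size // reduction, rng)
        self.fc2 = Linear(axis_size // reduction, axis_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: [B, C, T]; pool over the axis we are NOT gating
        pooled = x.mean(axis=2) if self.axis == "channel" else x.mean(axis=1)
        gates = self.fc2(self.fc1(pooled).relu()).sigmoid()  # [B, axis_size]
        b, n = gates.shape
        gates = gates.reshape(b, n, 1) if self.axis == "channel" else gates.reshape(b, 1, n)
        return x * gates

    def gate_values(self, x: Tensor) -> np.ndarray:
        pooled = x.mean(axis=2) if self.axis == "channel" else x.mean(axis=1)
        return self.fc2(self.fc1(pooled).relu()).sigmoid().data


class MRFBlock(Module):
    """Multi-receptive-field fusion: mean of three residual conv branches.

    Each branch applies tanh then a same-padded convolution with its own
    kernel size; zero branch weights reduce the block to the identity map.
    """

    def __init__(self, channels: int, kernel_sizes: tuple[int, int, int],
                 rng: np.random.Generator):
        if any(k % 2 == 0 for k in kernel_sizes):
            raise ValueError("kernel sizes must be odd for symmetric padding")
        self.branches = [Conv1d(channels, channels, k, rng, padding=(k - 1) // 2)
                         for k in kernel_sizes]

    def forward(self, x: Tensor) -> Tensor:
        acc = None
        for branch in self.branches:
            out = branch(x.tanh())
            acc = out if acc is None else acc + out
        return x + acc * (1.0 / len(self.branches))


class NeuroBrain(Module):
    def __init__(self, config: NeuroBrainConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        cfg = self.config = config
        if cfg.use_se:
            self.se_time = SEBlock(cfg.time_samples, "time", cfg.se_reduction, rng)
            self.se_channel = SEBlock(cfg.channels, "channel", cfg.se_reduction, rng)
        self.conv = Conv1d(cfg.channels, cfg.hidden_dim, cfg.conv_kernel, rng,
                           stride=cfg.conv_stride, padding=(cfg.conv_kernel - 1) // 2)
        self.grus = [GRU(cfg.hidden_dim, cfg.hidden_dim, rng)
                     for _ in range(cfg.gru_layers)]
        k = cfg.trans_kernel
        self.transposed = [ConvTranspose1d(cfg.hidden_dim, cfg.hidden_dim, k, rng,
                                           padding=(k - 1) // 2)
                           for _ in range(cfg.n_transposed)]
        self.mrf = MRFBlock(cfg.hidden_dim, cfg.mrf_kernel_sizes, rng)
        out_ch = cfg.mel_bins if cfg.task == "reconstruction" else cfg.n_classes
        self.decoder = Conv1d(cfg.hidden_dim, out_ch, 1, rng)

    def encode(self, x) -> Tensor:
        """Encoder feature map [B, hidden, frames] (everything but the last conv)."""
        x = as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.config.channels or x.shape[2] != self.config.time_samples:
            raise ValueError(
                f"input stage expects [B, {self.config.channels}, "
                f"{self.config.time_samples}], got {tuple(x.shape)}")
        if self.config.use_se:
            x = self.se_time(x)
            x = self.se_channel(x)
        h = self.conv(x)                      # [B, hidden, frames]
        for gru in self.grus:
            h = gru(h.swapaxes(1, 2)).swapaxes(1, 2)
        for tconv in self.transposed:
            h = h + tconv(h.tanh())           # residual, length-preserving
        return self.mrf(h)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        """Return (embedding [B, hidden], prediction).

        Prediction is [B, mel_bins, frames] for reconstruction or class
        logits [B, n_classes] for classification (decoder output averaged
        over time).
        """
        feat = self.encode(x)
        embedding = feat.mean(axis=2)
        out = self.decoder(feat)
        if self.config.task == "classification":
            out = out.mean(axis=2)
        return embedding, out


class LinearBaseline(Module):
    """One convolution plus one fully connected layer; the cheap reference model."""

    def __init__(self, config: NeuroBrainConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        cfg = self.config = config
        self.conv = Conv1d(cfg.channels, cfg.hidden_dim, cfg.conv_kernel, rng,
                           stride=cfg.conv_stride, padding=(cfg.conv_kernel - 1) // 2)
        out_dim = (cfg.mel_bins * cfg.frames if cfg.task == "reconstruction"
                   else cfg.n_classes)
        self.fc = Linear(cfg.hidden_dim * cfg.frames, out_dim, rng)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        h = self.conv(x)
        b = h.shape[0]
        flat = h.reshape(b, h.shape[1] * h.shape[2])
        out = self.fc(flat)
        embedding = h.mean(axis=2)
        if self.config.task == "reconstruction":
            out = out.reshape(b, self.config.mel_bins, self.config.frames)
        return embedding, out
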