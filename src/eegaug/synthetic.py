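"""Synthetic paired EEG/stimulus generators with known ground truth.

Real auditory EEG is expensive; these generators emulate just enough of its
structure to exercise every stage of the framework:

* Reconstruction: a smooth per-band stimulus envelope (Gaussian noise
  low-passed by a moving-average kernel, mimicking the bandwidth of a speech
  envelope sampled at 64 Hz) is mapped into EEG channels through a linear
  forward model with an optional neural lag, plus additive Gaussian sensor
  noise.
* Classification: evoked-response epochs where class c carries a Gaussian
  bump of amplitude c * A at a fixed latency on top of noise, with balanced
  classes.

A scripted stub trainer is also provided so the augmentation-selection
engine can be tested exhaustively without any real training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DatasetBundle, EEGSegment, StimulusTarget

__all__ = [
    "ForwardModelParams",
    "EvokedParams",
    "gen_reconstruction_dataset",
    "gen_classification_dataset",
    "StubTrainer",
    "stub_trainer",
]


@dataclass
class ForwardModelParams:
    """Linear stimulus-to-EEG forward model."""

    channels: int = 64
    mel_bins: int = 10
    fs: float = 64.0
    duration: float = 30.0          # seconds per segment
    lag: int = 6                    # samples (~94 ms neural delay)
    noise_sd: float = 0.1
    smooth_len: int = 8             # moving-average kernel, samples
    mixing: np.ndarray | None = None  # [channels, mel_bins]; drawn if None

    def __post_init__(self):
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=np.float64)
            if self.mixing.shape != (self.channels, self.mel_bins):
                raise ValueError(
                    f"mixing must be [channels={self.channels}, mel_bins={self.mel_bins}], "
                    f"got {self.mixing.shape}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class EvokedParams:
    """Class-dependent evoked bump on noise."""

    channels: int = 64
    epoch_len: int = 77             # 1.2 s at 64 Hz, rounded up
    fs: float = 64.0
    amplitude: float = 1.0
    latency: int = 32               # bump center, samples
    width: int = 8                  # bump sd, samples
    n_classes: int = 2
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.latency + self.width > self.epoch_len:
            raise ValueError("bump (latency + width) must fit inside the epoch")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def _smooth_envelope(rng: np.random.Generator, mel_bins: int, n: int,
                     smooth_len: int) -> np.ndarray:
    raw = rng.standard_normal((mel_bins, n + smooth_len - 1))
    kernel = np.ones(smooth_len) / smooth_len
    env = np.stack([np.convolve(row, kernel, mode="valid") for row in raw])
    env -= env.mean(axis=1, keepdims=True)
    env /= env.std(axis=1, keepdims=True)
    return env


def gen_reconstruction_dataset(params: ForwardModelParams, n: int,
                               seed: int = 0) -> DatasetBundle:
    """n paired (EEG, stimulus spectrogram) segments from the forward model.

    EEG at time t mixes the stimulus at time t - lag; the stimulus target is
    the unlagged envelope.  The ground-truth parameters travel in the
    bundle's ``meta``.
    """
    rng = np.random.default_rng(seed)
    T = params.n_samples
    mixing = params.mixing
    if mixing is None:
        mixing = rng.standard_normal((params.channels, params.mel_bins)) \
            / np.sqrt(params.mel_bins)
    segments, targets = [], []
    for _ in range(n):
        stim = _smooth_envelope(rng, params.mel_bins, T, params.smooth_len)
        lagged = np.zeros_like(stim)
        if params.lag:
            lagged[:, params.lag:] = stim[:, :-params.lag]
        else:
            lagged = stim
        eeg = mixing @ lagged + params.noise_sd * rng.standard_normal((params.channels, T))
        segments.append(EEGSegment(eeg, fs=params.fs))
        targets.append(StimulusTarget(spec=stim))
    return DatasetBundle(segments, targets, task="reconstruction",
                         meta={"mixing": mixing, "lag": params.lag,
                               "noise_sd": params.noise_sd})


def gen_classification_dataset(params: EvokedParams, n: int,
                               seed: int = 0) -> DatasetBundle:
    """n evoked-response epochs with balanced class labels.

    Class c adds a Gaussian-shaped bump of amplitude ``c * amplitude`` at the
    stated latency to every channel (with a random per-channel topography
    drawn once), so class 0 is pure noise and separability grows with c.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(params.epoch_len)
    bump = np.exp(-0.5 * ((t - params.latency) / params.width) ** 2)
    topography = np.abs(rng.standard_normal(params.channels))[:, None]
    labels = np.arange(n) % params.n_classes
    rng.shuffle(labels)
    segments, targets = [], []
    for lab in labels:
        noise = params.noise_sd * rng.standard_normal((params.channels, params.epoch_len))
        eeg = noise + lab * params.amplitude * topography * bump[None, :]
        segments.append(EEGSegment(eeg, fs=params.fs))
        targets.append(StimulusTarget(label=int(lab)))
    return DatasetBundle(segments, targets, task="classification",
                         meta={"topography": topography[:, 0], "bump": bump,
                               "amplitude": params.amplitude})


class StubTrainer:
    """Scripted trainer for exercising the selection engine without training.

    ``score_table`` maps each augmentation policy (any iterable of names) to
    its validation score; ``w_script`` maps a policy to the coefficient
    snapshot "observed" when training with it.  Policies absent from
    ``w_script`` report evenly distributed coefficients (0.5 each), which
    terminates the pruning loop.  Everything is deterministic.
    """

    def __init__(self, score_table: dict, w_script: dict | None = None,
                 default_score: float = 0.0):
        self.score_table = {frozenset(k): v for k, v in score_table.items()}
        self.w_script = {frozenset(k): dict(v) for k, v in (w_script or {}).items()}
        self.default_score = default_score
        self.train_calls: list[frozenset] = []

    def train(self, policy, seed: int = 0) -> frozenset:
        handle = frozenset(policy)
        self.train_calls.append(handle)
        return handle

    def evaluate(self, handle: frozenset) -> tuple[float, dict[str, float]]:
        score = self.score_table.get(handle, self.default_score)
        w = self.w_script.get(handle, {name: 0.5 for name in handle})
        return score, w


def stub_trainer(score_table: dict, w_script: dict | None = None,
                 default_score: float = 0.0) -> StubTrainer:
    return StubTrainer(score_table, w_script, default_score)
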