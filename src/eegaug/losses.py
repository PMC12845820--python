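"""Training objectives: contrastive embedding alignment and composite losses.

The Siamese flow produces one embedding per augmentation branch plus the
embedding of the unaugmented signal.  Each pair is aligned with a CLIP-style
contrastive loss: scaled pairwise similarities within the batch, cross-entropy
against the diagonal (item j's positive is item j).  The task heads use a
negative-Pearson + L1 composite for spectrogram reconstruction and plain
cross-entropy for classification, combined as

    L = L_P + alpha * L_cont + beta * L_1      (reconstruction)
    L = L_C + alpha * L_cont                   (classification)

with default mixing weights alpha = 0.01, beta = 0.001.

All functions accept numpy arrays or autodiff tensors and return an autodiff
:class:`~eegaug.autodiff.Tensor` (call ``float()`` on it for the plain value);
gradients flow whenever an input requires them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, log_softmax, softmax, stack
from .nn import Module, Parameter

__all__ = [
    "EmbeddingPair",
    "LossWeights",
    "Temperature",
    "contrastive_logits",
    "contrastive_loss_pair",
    "average_contrastive_loss",
    "cross_attention_align",
    "negative_pearson_loss",
    "l1_loss",
    "combine_regression_loss",
    "regression_total_loss",
    "cross_entropy_loss",
    "classification_total_loss",
]


@dataclass
class LossWeights:
    """Mixing coefficients of the composite loss."""

    alpha: float = 0.01
    beta: float = 0.001

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


class Temperature(Module):
    """Trainable temperature tau = exp(theta), strictly positive by construction."""

    def __init__(self, initial: float = 1.0):
        if initial <= 0:
            raise ValueError("temperature must be positive")
        self.theta = Parameter(np.log(initial))

    @property
    def tau(self) -> Tensor:
        return self.theta.exp()


@dataclass
class EmbeddingPair:
    """Original embedding, one augmentation branch's embedding, and tau."""

    f_a: object  # [batch, d] array or Tensor
    f_i: object  # [batch, d]
    tau: object = 1.0  # positive scalar or Tensor

    def __post_init__(self):
        fa, fi = as_tensor(self.f_a), as_tensor(self.f_i)
        if fa.shape != fi.shape:
            raise ValueError(f"embedding shapes differ: {fa.shape} vs {fi.shape}")


def contrastive_logits(pair: EmbeddingPair) -> Tensor:
    """Scaled pairwise similarity matrix: logits = f_a . f_i^T . tau."""
    tau = as_tensor(pair.tau)
    if float(tau.data) <= 0:
        raise ValueError(f"temperature must be positive, got {float(tau.data)}")
    return (as_tensor(pair.f_a) @ as_tensor(pair.f_i).swapaxes(-1, -2)) * tau


def contrastive_loss_pair(logits, symmetric: bool = False) -> Tensor:
    """Cross-entropy of each row's softmax against the matching diagonal index.

    With ``symmetric=True`` the column-wise direction is averaged in as well
    (the two-directional CLIP variant); default is the one-directional form.
    """
    logits = as_tensor(logits)
    k = logits.shape[0]
    if logits.ndim != 2 or logits.shape[1] != k:
        raise ValueError(f"logits must be square, got shape {logits.shape}")
    diag = (np.arange(k), np.arange(k))
    loss = -log_softmax(logits, axis=1)[diag].mean()
    if symmetric:
        loss = (loss + -log_softmax(logits, axis=0)[diag].mean()) * 0.5
    return loss


def average_contrastive_loss(pairs, symmetric: bool = False) -> Tensor:
    """Mean contrastive loss over the active augmentation branches (0 if none)."""
    pairs = list(pairs)
    if not pairs:
        return Tensor(0.0)
    losses = [contrastive_loss_pair(contrastive_logits(p), symmetric) for p in pairs]
    return stack(losses).mean()


def cross_attention_align(f_a, f_i, return_weights: bool = False):
    """Align the augmented embedding to the original via scaled dot-product attention.

    Queries come from ``f_i``, keys and values from ``f_a``; each output row is
    a convex combination of ``f_a`` rows, so the aligned embedding lives in the
    span of the original batch.
    """
    f_a, f_i = as_tensor(f_a), as_tensor(f_i)
    if f_a.shape[-1] != f_i.shape[-1]:
        raise ValueError(f"feature dimensions differ: {f_a.shape[-1]} vs {f_i.shape[-1]}")
    d = f_a.shape[-1]
    attn = softmax((f_i @ f_a.swapaxes(-1, -2)) * (1.0 / np.sqrt(d)), axis=-1)
    aligned = attn @ f_a
    return (aligned, attn) if return_weights else aligned


def _rowwise_pearson(x: Tensor, y: Tensor):
    """Pearson r of each row (last axis = samples); returns (r rows, valid mask)."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sx = (xc * xc).sum(axis=-1)
    sy = (yc * yc).sum(axis=-1)
    valid = (sx.data > 0) & (sy.data > 0)
    # guard the division for invalid rows; they are masked out by the caller
    denom = ((sx + (~valid) * 1.0) * (sy + (~valid) * 1.0)) ** 0.5
    r = (xc * yc).sum(axis=-1) / denom
    return r, valid


def negative_pearson_loss(X, Y) -> Tensor:
    """Negative mean Pearson correlation, one r per mel bin across frames.

    Accepts matching vectors, ``[mel_bins, frames]`` matrices or batched
    ``[batch, mel_bins, frames]`` stacks; rows with zero variance are skipped
    with a warning.  The value lies in [-1, 1]: -1 for a perfect
    reconstruction, +1 for a perfectly anticorrelated one.
    """
    X, Y = as_tensor(X), as_tensor(Y)
    if X.shape != Y.shape:
        raise ValueError(f"shapes differ: {X.shape} vs {Y.shape}")
    r, valid = _rowwise_pearson(X, Y)
    if not np.all(valid):
        warnings.warn(f"{int((~valid).sum())} zero-variance bin(s) skipped in "
                      "Pearson loss", stacklevel=2)
        if not np.any(valid):
            raise ValueError("all compared vectors have zero variance")
    n_valid = float(valid.sum())
    return -((r * valid).sum() * (1.0 / n_valid))


def l1_loss(X, Y) -> Tensor:
    """Mean absolute error over all entries."""
    X, Y = as_tensor(X), as_tensor(Y)
    return (X - Y).abs().mean()


def combine_regression_loss(l_p, l_cont, l1,
                            weights: LossWeights | None = None) -> Tensor:
    """The composite form L_P + alpha * L_cont + beta * L_1 on given terms."""
    w = weights or LossWeights()
    return as_tensor(l_p) + w.alpha * as_tensor(l_cont) + w.beta * as_tensor(l1)


def regression_total_loss(X, Y, L_cont=0.0,
                          weights: LossWeights | None = None) -> Tensor:
    """Composite reconstruction loss L_P + alpha * L_cont + beta * L_1."""
    return combine_regression_loss(negative_pearson_loss(X, Y), L_cont,
                                   l1_loss(X, Y), weights)


def cross_entropy_loss(y, yhat) -> Tensor:
    """Multiclass cross-entropy of predicted probabilities against labels.

    ``y`` holds integer labels in [0, C); ``yhat`` is [N, C] with rows summing
    to 1.  Zero probability at the true class is clamped at 1e-12 with a
    warning so the loss stays finite.
    """
    eps = 1e-12
    y = np.asarray(y, dtype=np.int64)
    yhat = as_tensor(yhat)
    n, c = yhat.shape
    if y.shape != (n,):
        raise ValueError(f"expected {n} labels, got shape {y.shape}")
    if np.any((y < 0) | (y >= c)):
        raise ValueError(f"labels must lie in [0, {c})")
    if not np.allclose(yhat.data.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of yhat must sum to 1 (probabilities expected)")
    p = yhat[(np.arange(n), y)]
    low = p.data < eps
    if np.any(low):
        warnings.warn(f"{int(low.sum())} zero predicted probability value(s) "
                      "clamped at 1e-12", stacklevel=2)
        p = p * (~low) + low * eps
    return -(p.log().mean())


def classification_total_loss(L_C, L_cont=0.0, alpha: float = 0.01) -> Tensor:
    """Composite classification loss L_C + alpha * L_cont."""
    return as_tensor(L_C) + alpha * as_tensor(L_cont)
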