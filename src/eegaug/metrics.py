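"""Evaluation metrics for reconstruction and classification.

Reconstruction quality is scored with Pearson correlation and two structural
similarity indices on the mel-spectrogram: plain SSIM (local luminance /
contrast / structure comparison under a sliding window) and CW-SSIM, which
compares complex wavelet coefficients and is therefore tolerant of small
geometric distortions such as time shifts.  Because auditory EEG decoding
yields small raw correlations, reported tables conventionally scale all three
by 100; the ``scaled`` flag of :class:`SimilarityReport` records whether that
scaling has been applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, stats

__all__ = [
    "SimilarityReport",
    "pearson",
    "spectrogram_pearson",
    "accuracy",
    "ssim",
    "cw_ssim",
    "relative_improvement",
    "similarity_report",
]


@dataclass
class SimilarityReport:
    """Pearson / SSIM / CW-SSIM triple, optionally on the x100 reporting scale."""

    pearson: float
    ssim: float
    cw_ssim: float
    scaled: bool = False

    def __post_init__(self):
        limit = 100.0 if self.scaled else 1.0
        if abs(self.pearson) > limit + 1e-9:
            raise ValueError(f"|pearson| cannot exceed {limit}")
        if self.ssim > limit + 1e-9 or self.cw_ssim > limit + 1e-9:
            raise ValueError(f"ssim/cw_ssim cannot exceed {limit}")

    def rescaled(self) -> "SimilarityReport":
        """Return the x100 version of an unscaled report (identity if scaled)."""
        if self.scaled:
            return self
        return SimilarityReport(self.pearson * 100, self.ssim * 100,
                                self.cw_ssim * 100, scaled=True)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def spectrogram_pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean Pearson r over mel bins (rows), frames as samples; batched inputs
    ``[batch, mel_bins, frames]`` are averaged over the batch too.  Rows that
    are constant in either argument are skipped."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p2 = pred.reshape(-1, pred.shape[-1])
    t2 = truth.reshape(-1, truth.shape[-1])
    rs = [pearson(a, b) for a, b in zip(p2, t2)
          if np.std(a) > 0 and np.std(b) > 0]
    if not rs:
        raise ValueError("no row with nonzero variance in both inputs")
    return float(np.mean(rs))


def accuracy(y_true, y_pred) -> float:
    """Fraction of correctly predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have matching shapes")
    if y_true.size == 0:
        raise ValueError("cannot compute accuracy of zero samples")
    return float(np.mean(y_true == y_pred))


def _local_mean(a: np.ndarray, win_size: int, sigma: float | None) -> np.ndarray:
    if sigma is None:
        return ndimage.uniform_filter(a, size=win_size)
    truncate = ((win_size - 1) / 2) / sigma
    return ndimage.gaussian_filter(a, sigma=sigma, truncate=truncate)


def ssim(x, y, win_size: int | str = 7, sigma: float | None = 1.5,
         data_range: float | None = None, k1: float = 0.01,
         k2: float = 0.03) -> float:
    """Structural similarity of two equal-shape 2-D matrices.

    By default the statistic is averaged over sliding Gaussian windows
    (win_size 7, sigma 1.5); ``sigma=None`` switches to a uniform window and
    ``win_size="full"`` to the single global-window formula.  Stabilizing
    constants are c1 = (k1 L)^2, c2 = (k2 L)^2 with L the data range
    (inferred from the joint range of both inputs when not given).  Bounded
    above by 1, with equality iff x == y.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        data_range = hi - lo if hi > lo else 1.0
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    if win_size == "full":
        ux, uy = x.mean(), y.mean()
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        vxy = np.mean((x - ux) * (y - uy)) * x.size / (x.size - 1)
        return float(((2 * ux * uy + c1) * (2 * vxy + c2))
                     / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
    f = lambda a: _local_mean(a, win_size, sigma)
    ux, uy = f(x), f(y)
    np_win = win_size ** 2
    cov_norm = np_win / (np_win - 1)  # sample covariance within each window
    vx = cov_norm * (f(x * x) - ux * ux)
    vy = cov_norm * (f(y * y) - uy * uy)
    vxy = cov_norm * (f(x * y) - ux * uy)
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) \
        / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    pad = (win_size - 1) // 2
    core = s[pad:s.shape[0] - pad, pad:s.shape[1] - pad]
    return float(core.mean() if core.size else s.mean())


def cw_ssim(x, y, scales=(2.0, 4.0, 8.0), wavelet: str = "cmor1.5-1.0",
            K: float = 0.01, win_size: int = 7) -> float:
    """Complex-wavelet SSIM of two equal-shape matrices.

    Both matrices are decomposed with a complex Morlet continuous wavelet
    transform along the time (last) axis at the given scales.  Within each
    subband, windowed coefficient sums enter the statistic

        (2 |sum c_x conj(c_y)| + K) / (sum |c_x|^2 + sum |c_y|^2 + K)

    which is averaged over windows and subbands.  A rigid time shift rotates
    all coefficient phases coherently, so the magnitude of the cross term is
    preserved and the index degrades far more gracefully than plain SSIM.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if K == 0 and not (np.any(x) or np.any(y)):
        raise ValueError("CW-SSIM is 0/0-undefined for all-zero inputs with K=0")
    cx, _ = pywt.cwt(x, scales, wavelet, axis=-1)
    cy, _ = pywt.cwt(y, scales, wavelet, axis=-1)

    def winsum(a: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(a):
            return winsum(a.real) + 1j * winsum(a.imag)
        return ndimage.uniform_filter(a, size=win_size, mode="constant") * win_size ** 2

    values = []
    for s in range(len(scales)):
        cross = winsum(cx[s] * np.conj(cy[s]))
        ex = winsum(np.abs(cx[s]) ** 2)
        ey = winsum(np.abs(cy[s]) ** 2)
        values.append((2 * np.abs(cross) + K) / (ex + ey + K))
    return float(np.mean(values))


def relative_improvement(a: float, b: float) -> float:
    """Percent change of a over the reference b: 100 (a - b) / b."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (a - b) / b


def similarity_report(pred: np.ndarray, truth: np.ndarray,
                      scale100: bool = False) -> SimilarityReport:
    """Convenience: Pearson + SSIM + CW-SSIM of a reconstructed spectrogram.

    Batched ``[batch, mel_bins, frames]`` inputs are averaged over the batch.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    ps = np.atleast_3d(pred) if pred.ndim == 3 else pred[None]
    ts = np.atleast_3d(truth) if truth.ndim == 3 else truth[None]
    report = SimilarityReport(
        pearson=spectrogram_pearson(pred, truth),
        ssim=float(np.mean([ssim(p, t) for p, t in zip(ps, ts)])),
        cw_ssim=float(np.mean([cw_ssim(p, t) for p, t in zip(ps, ts)])),
    )
    return report.rescaled() if scale100 else report
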