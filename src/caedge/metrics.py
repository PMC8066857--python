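"""Quantitative measures for edge maps and images.

Edge maps are compared with the Dice similarity coefficient (the
optimization fitness), PSNR and SSIM; whole images are characterized by a
global signal-to-noise ratio and a Sobel mean-gradient difficulty score.
PSNR and SSIM treat the binary maps on the {0, 255} scale with data range
255, which gives the dB magnitudes customary for edge-map comparisons.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.metrics import structural_similarity


def _as_binary_pair(predicted: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    return predicted.astype(bool), truth.astype(bool)


def confusion_counts(predicted: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) pixel counts, positive class = edge."""
    p, t = _as_binary_pair(predicted, truth)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, fn, tn


def dsc(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2*TP / (2*TP + FP + FN).

    Robust to the edge/non-edge class imbalance.  Two empty maps agree
    perfectly and score 1.0; empty vs non-empty scores 0.0.
    """
    tp, fp, fn, _ = confusion_counts(predicted, truth)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2 * tp / denom


def psnr(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on {0, 255}-scaled maps.

    10 * log10(255^2 / MSE); +inf when the maps are identical.
    """
    p, t = _as_binary_pair(predicted, truth)
    mse = float(np.mean((p.astype(float) * 255 - t.astype(float) * 255) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / mse)


def ssim(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean structural similarity on {0, 255}-scaled maps.

    Standard parameters: 11x11 Gaussian window with sigma 1.5,
    K1 = 0.01, K2 = 0.03, data range 255.
    """
    p, t = _as_binary_pair(predicted, truth)
    if min(p.shape) < 11:
        raise ValueError(f"image smaller than the 11x11 SSIM window: {p.shape}")
    return float(
        structural_similarity(
            p.astype(float) * 255,
            t.astype(float) * 255,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=255,
        )
    )


def snr_image(image: np.ndarray) -> float:
    """Global signal-to-noise ratio: mean intensity / intensity std."""
    image = np.asarray(image, dtype=float)
    sd = float(image.std())
    if sd == 0:
        raise ValueError("SNR undefined for a constant image")
    return float(image.mean()) / sd


def mean_gradient_difficulty(image: np.ndarray) -> float:
    """Edge-detection difficulty: mean Sobel gradient magnitude.

    Standard 3x3 Sobel kernels with reflective boundary; higher values
    indicate stronger/denser gradients, i.e., busier images.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got shape {image.shape}")
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    return float(np.mean(np.hypot(gx, gy)))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D sequences with >= 2 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y)[0])
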