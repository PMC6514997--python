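"""Image-quality measures: PSNR, HFEN, SSIM, Pearson correlation, Tenengrad sharpness.

All metrics are computed on image magnitudes.  HFEN (high-frequency error norm)
measures edge and fine-feature fidelity: the l2 norm of the
Laplacian-of-Gaussian-filtered difference between reconstruction and reference,
normalized by the LoG norm of the reference so values are scale-free.  The LoG
kernel is the 15x15, sigma=1.5 filter conventional in dictionary-learning MRI
benchmarks.  Filter boundaries use symmetric padding.

The sharpness measure is Tenengrad — the mean squared Sobel gradient magnitude;
it is a focus/edge-energy score of a single image, not a fidelity metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "MetricsReport",
    "psnr",
    "hfen",
    "ssim",
    "correlation",
    "sharpness",
    "log_kernel",
    "evaluate",
]


def _mag(x: np.ndarray) -> np.ndarray:
    return np.abs(np.asarray(x))


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class MetricsReport:
    psnr_db: float
    hfen: float
    ssim: float
    correlation: float
    sharpness: float


def psnr(recon: np.ndarray, reference: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB: 20 log10(peak / RMSE) on magnitudes.

    ``peak`` defaults to the reference maximum.  Identical images give +inf.
    """
    r, ref = _mag(recon), _mag(reference)
    _check_shapes(r, ref)
    if peak is None:
        peak = float(ref.max())
    if peak <= 0:
        raise ValueError("peak must be positive")
    rmse = float(np.sqrt(np.mean((r - ref) ** 2)))
    if rmse == 0.0:
        return float("inf")
    return 20.0 * np.log10(peak / rmse)


def log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Zero-sum Laplacian-of-Gaussian kernel (classical 'log' filter construction)."""
    half = (size - 1) / 2.0
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    arg = -(x * x + y * y) / (2.0 * sigma**2)
    h = np.exp(arg)
    h[h < np.finfo(float).eps * h.max()] = 0.0
    h /= h.sum()
    h1 = h * (x * x + y * y - 2.0 * sigma**2) / sigma**4
    return h1 - h1.sum() / h1.size  # enforce zero response to constants


def hfen(recon: np.ndarray, reference: np.ndarray) -> float:
    """High-frequency error norm, normalized by the reference's LoG norm."""
    r, ref = _mag(recon), _mag(reference)
    _check_shapes(r, ref)
    k = log_kernel()
    num = ndimage.convolve(r - ref, k, mode="reflect")
    den = ndimage.convolve(ref, k, mode="reflect")
    den_norm = float(np.linalg.norm(den))
    if den_norm == 0.0:
        raise ValueError("reference has zero high-frequency content")
    return float(np.linalg.norm(num)) / den_norm


def ssim(recon: np.ndarray, reference: np.ndarray) -> float:
    """Mean structural similarity (11x11 Gaussian window, sigma 1.5, K1/K2 = 0.01/0.03)."""
    r, ref = _mag(recon).astype(float), _mag(reference).astype(float)
    _check_shapes(r, ref)
    drange = float(ref.max() - ref.min())
    if drange == 0.0:
        raise ValueError("reference has zero dynamic range")
    return float(
        structural_similarity(
            ref, r, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            K1=0.01, K2=0.03, data_range=drange,
        )
    )


def correlation(recon: np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation of the magnitude images over all pixels."""
    r, ref = _mag(recon).ravel(), _mag(reference).ravel()
    _check_shapes(r, ref)
    if r.std() == 0.0 or ref.std() == 0.0:
        raise ValueError("correlation undefined for a zero-variance image")
    return float(np.corrcoef(r, ref)[0, 1])


def sharpness(image: np.ndarray) -> float:
    """Tenengrad sharpness: mean squared Sobel gradient magnitude."""
    img = _mag(image).astype(float)
    kx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
    gx = ndimage.convolve(img, kx, mode="reflect")
    gy = ndimage.convolve(img, kx.T, mode="reflect")
    return float(np.mean(gx * gx + gy * gy))


def evaluate(recon: np.ndarray, reference: np.ndarray) -> MetricsReport:
    """All fidelity metrics of a reconstruction against its reference."""
    return MetricsReport(
        psnr_db=psnr(recon, reference),
        hfen=hfen(recon, reference),
        ssim=ssim(recon, reference),
        correlation=correlation(recon, reference),
        sharpness=sharpness(recon),
    )
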