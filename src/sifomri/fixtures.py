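"""Synthetic test inputs: Shepp-Logan phantom, brain-like images, planted sparse models.

The Shepp-Logan phantom is rasterized from the canonical 10-ellipse parameter
table at any grid size; the high-contrast ("modified") intensity variant is the
default.  ``brain_like`` produces seeded piecewise-smooth images — an elliptical
"skull" containing random-intensity blobs plus optional low-pass texture — as a
stand-in for real T2-weighted brain scans.  ``planted_sparse_instance`` builds
exact sparse-coding ground truth for oracle tests.

All generators are deterministic per seed and emit intensities in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gridops import Image

__all__ = ["EllipseSpec", "shepp_logan", "brain_like", "planted_sparse_instance"]


@dataclass(frozen=True)
class EllipseSpec:
    """One phantom ellipse: center in [-1,1]^2, semi-axes, rotation (deg), intensity."""

    intensity: float
    a: float
    b: float
    x0: float
    y0: float
    phi_deg: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")


# canonical Shepp-Logan ellipses (a, b, x0, y0, phi); intensities per variant
_SL_GEOMETRY = [
    (0.69, 0.92, 0.0, 0.0, 0.0),
    (0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (0.1100, 0.3100, 0.22, 0.0, -18.0),
    (0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.0230, 0.0460, 0.06, -0.605, 0.0),
]
_SL_INTENSITY = {
    "modified": [1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
    "original": [2.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01],
}


def shepp_logan_ellipses(variant: str = "modified") -> list[EllipseSpec]:
    intens = _SL_INTENSITY[variant]
    return [
        EllipseSpec(intensity=v, a=a, b=b, x0=x0, y0=y0, phi_deg=phi)
        for v, (a, b, x0, y0, phi) in zip(intens, _SL_GEOMETRY)
    ]


def _rasterize(ellipses: list[EllipseSpec], size: int) -> np.ndarray:
    coords = np.linspace(-1.0, 1.0, size)
    x = coords[None, :]
    y = -coords[:, None]  # row 0 is the top of the head
    img = np.zeros((size, size))
    for e in ellipses:
        phi = np.deg2rad(e.phi_deg)
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - e.x0) * c + (y - e.y0) * s
        yr = -(x - e.x0) * s + (y - e.y0) * c
        inside = (xr / e.a) ** 2 + (yr / e.b) ** 2 <= 1.0
        img[inside] += e.intensity
    return img


def shepp_logan(size: int = 512, variant: str = "modified") -> Image:
    """Shepp-Logan phantom on a size x size grid, intensities scaled to [0, 255]."""
    if size < 16:
        raise ValueError("size must be >= 16")
    vmax = 2.0 if variant == "original" else 1.0  # original table peaks at 2.0
    img = np.clip(_rasterize(shepp_logan_ellipses(variant), size), 0.0, vmax)
    return Image(pixels=img * (255.0 / vmax))


def brain_like(
    size: int = 512, seed: int = 0, n_blobs: int = 6, texture_amp: float = 5.0
) -> Image:
    """Seeded piecewise-smooth brain-like image.

    An elliptical outer "skull" of constant base intensity, ``n_blobs`` random
    interior ellipses of random distinct intensities, and low-pass-filtered
    Gaussian texture of amplitude ``texture_amp`` inside the skull.
    """
    rng = np.random.default_rng(seed)
    coords = np.linspace(-1.0, 1.0, size)
    x = coords[None, :]
    y = -coords[:, None]
    img = np.zeros((size, size))
    skull = (x / 0.82) ** 2 + (y / 0.95) ** 2 <= 1.0
    img[skull] = 120.0
    for _ in range(n_blobs):
        a, b = rng.uniform(0.06, 0.30, size=2)
        x0 = rng.uniform(-0.45, 0.45)
        y0 = rng.uniform(-0.55, 0.55)
        phi = rng.uniform(0.0, np.pi)
        level = rng.uniform(30.0, 230.0)
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        inside = ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0) & skull
        img[inside] = level
    if texture_amp > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
        img[skull] += texture_amp * noise[skull] / max(noise.std(), 1e-12)
    return Image(pixels=np.clip(img, 0.0, 255.0))


def planted_sparse_instance(
    n: int, K: int, P: int, tau: int, noise: float = 0.0, seed: int = 0
):
    """Ground-truth sparse model: random unit-norm dictionary, exactly tau-sparse codes.

    Code magnitudes are +/- Uniform(0.5, 1.5); data = D theta + Gaussian(0, noise).
    Returns (Dictionary, SparseCodeMatrix, data matrix).
    """
    from .sparse_coding import Dictionary, SparseCodeMatrix

    if tau > min(n, K):
        raise ValueError(f"tau={tau} exceeds min(n, K)={min(n, K)}")
    rng = np.random.default_rng(seed)
    atoms = rng.standard_normal((n, K))
    atoms /= np.linalg.norm(atoms, axis=0)
    codes = np.zeros((K, P))
    for j in range(P):
        supp = rng.choice(K, size=tau, replace=False)
        codes[supp, j] = rng.choice([-1.0, 1.0], size=tau) * rng.uniform(0.5, 1.5, tau)
    data = atoms @ codes
    if noise > 0:
        data = data + rng.normal(0.0, noise, size=data.shape)
    return Dictionary(atoms=atoms), SparseCodeMatrix(codes=codes, tau0=tau), data
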