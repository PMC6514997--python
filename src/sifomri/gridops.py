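"""k-space sampling masks, the undersampled Fourier measurement operator and its adjoint.

MRI acquisition is modelled as ``z = F_u x``: the centered, *unitary* 2D DFT of the
image evaluated on a subset of the k-space grid.  The unitary convention (1/sqrt(q)
scaling both ways, DC at the grid center) keeps Parseval exact, so a noise standard
deviation expressed in k-space units is directly comparable across grid sizes.

Three sampling schemes are provided: 2D variable-density random, Cartesian
(full phase-encode lines), and pseudo-radial (rasterized spokes on the Cartesian
grid).  Each generator reports the *achieved* undersampling fold — total grid
cells divided by sampled cells — and guarantees it lies within 10% of the request.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceMeasurement",
    "Image",
    "fft2c",
    "ifft2c",
    "make_vd_random_mask",
    "make_cartesian_mask",
    "make_radial_mask",
    "undersample",
    "zero_filled_recon",
]

FOLD_TOL = 0.10  # relative tolerance on the achieved fold


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2D DFT (DC at ``(rows//2, cols//2)``)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


@dataclass
class Image:
    """A 2D pixel grid, real or complex."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image must be a non-empty 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.pixels)


@dataclass
class SamplingMask:
    """Boolean k-space sampling pattern on the centered grid.

    ``fold`` is the achieved undersampling factor (grid cells / sampled cells).
    """

    grid: np.ndarray
    scheme: str
    fold: float = field(default=0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        m = int(self.grid.sum())
        if m == 0:
            raise ValueError("mask must sample at least one cell")
        achieved = self.grid.size / m
        if self.fold == 0.0:
            self.fold = achieved
        elif not np.isclose(self.fold, achieved, rtol=1e-9):
            raise ValueError(
                f"declared fold {self.fold} inconsistent with grid ({achieved:.4f})"
            )

    @property
    def n_sampled(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class KSpaceMeasurement:
    """Zero-filled complex k-space measurement (the N0 of the data-consistency step).

    ``data`` is exactly zero wherever the mask is false; ``noise_sigma`` is the
    per-component standard deviation of the Gaussian noise added to sampled cells.
    """

    data: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.shape != self.mask.shape:
            raise ValueError("data / mask shape mismatch")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if np.any(self.data[~self.mask.grid] != 0):
            raise ValueError("measurement must be zero at unsampled cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def _radius_grid(shape: tuple[int, int]) -> np.ndarray:
    """Distance of every cell from the DC cell, normalized by min(shape)/2."""
    rows, cols = shape
    cy, cx = rows // 2, cols // 2
    yy, xx = np.ogrid[:rows, :cols]
    dist = np.hypot(yy - cy, xx - cx)
    return dist / (min(rows, cols) / 2.0)


def _check_fold_request(shape: tuple[int, int], fold: float) -> int:
    if fold < 1:
        raise ValueError("fold must be >= 1")
    q = shape[0] * shape[1]
    budget = int(q // fold)
    if budget < 1:
        raise ValueError(f"fold {fold} larger than grid size {q}")
    return budget


def make_vd_random_mask(
    shape: tuple[int, int],
    fold: float,
    seed: int = 0,
    density_power: float = 3.0,
    center_fraction: float = 1.0 / 16.0,
) -> SamplingMask:
    """Variable-density random mask: sampling probability decays with k-space radius.

    Cells inside the central disc of radius ``center_fraction * min(shape) / 2`` are
    always sampled; the rest of the exact budget ``floor(q / fold)`` is drawn without
    replacement with probability proportional to ``(1 - r_norm)^density_power``.
    """
    budget = _check_fold_request(shape, fold)
    rows, cols = shape
    r_norm = _radius_grid(shape)
    grid = np.zeros(shape, dtype=bool)

    center = r_norm <= center_fraction
    n_center = int(center.sum())
    if n_center > budget:
        raise ValueError(
            f"fully sampled center ({n_center} cells) exceeds the budget {budget}; "
            "reduce center_fraction or fold"
        )
    grid[center] = True

    remaining = budget - n_center
    if remaining > 0:
        weights = np.clip(1.0 - r_norm, 0.0, None) ** density_power
        weights[center] = 0.0
        flat = weights.ravel() + 1e-12  # floor so the budget is always reachable
        candidates = np.flatnonzero(~center.ravel())
        p = flat[candidates]
        p /= p.sum()
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=remaining, replace=False, p=p)
        grid.ravel()[chosen] = True

    return SamplingMask(grid=grid, scheme="vd_random", seed=seed)


def make_cartesian_mask(
    shape: tuple[int, int],
    fold: float,
    seed: int = 0,
    center_lines: int | None = None,
    density_power: float = 3.0,
) -> SamplingMask:
    """Cartesian mask: full phase-encode rows, variable-density row selection.

    ``floor(rows / fold)`` rows are sampled in total; ``center_lines`` contiguous
    central rows are always included, the rest drawn with probability decaying with
    distance from the center row.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rows, cols = shape
    n_rows = int(rows // fold)
    if n_rows < 1:
        raise ValueError(f"fold {fold} leaves no phase-encode lines on {rows} rows")
    if center_lines is None:
        center_lines = max(1, n_rows // 4)
    if center_lines > n_rows:
        raise ValueError(
            f"center_lines={center_lines} exceeds the row budget rows/fold={n_rows}"
        )

    start = (rows - center_lines + 1) // 2
    selected = set(range(start, start + center_lines))

    remaining = n_rows - len(selected)
    if remaining > 0:
        idx = np.arange(rows)
        dist = np.abs(idx - rows // 2) / (rows / 2.0)
        weights = np.clip(1.0 - dist, 0.0, None) ** density_power + 1e-12
        weights[list(selected)] = 0.0
        p = weights / weights.sum()
        rng = np.random.default_rng(seed)
        extra = rng.choice(idx, size=remaining, replace=False, p=p)
        selected.update(int(i) for i in extra)

    grid = np.zeros(shape, dtype=bool)
    grid[sorted(selected), :] = True
    return SamplingMask(grid=grid, scheme="cartesian", seed=seed)


def _rasterize_spoke(shape: tuple[int, int], angle: float) -> np.ndarray:
    """Nearest-cell rasterization of a straight line through the grid center."""
    rows, cols = shape
    cy, cx = rows // 2, cols // 2
    grid = np.zeros(shape, dtype=bool)
    c, s = np.cos(angle), np.sin(angle)
    if abs(c) >= abs(s):  # sweep along x
        x = np.arange(cols)
        y = np.rint(cy + (x - cx) * (s / c)).astype(int)
        ok = (y >= 0) & (y < rows)
        grid[y[ok], x[ok]] = True
    else:  # sweep along y
        y = np.arange(rows)
        x = np.rint(cx + (y - cy) * (c / s)).astype(int)
        ok = (x >= 0) & (x < cols)
        grid[y[ok], x[ok]] = True
    return grid


def make_radial_mask(shape: tuple[int, int], fold: float) -> SamplingMask:
    """Pseudo-radial mask: equally spaced spokes through the k-space center.

    The number of spokes is the smallest count whose rasterized union achieves
    the requested fold within 10%.  Deterministic (no randomness).
    """
    q = shape[0] * shape[1]
    _check_fold_request(shape, fold)
    lo, hi = fold * (1 - FOLD_TOL), fold * (1 + FOLD_TOL)
    achieved: list[float] = []
    max_lines = 4 * max(shape)
    for n_lines in range(1, max_lines + 1):
        angles = np.pi * np.arange(n_lines) / n_lines
        grid = np.zeros(shape, dtype=bool)
        for a in angles:
            grid |= _rasterize_spoke(shape, a)
        f = q / grid.sum()
        achieved.append(f)
        if lo <= f <= hi:
            return SamplingMask(grid=grid, scheme="radial")
        if f < lo:  # folds only decrease as spokes are added
            break
    raise ValueError(
        f"radial fold {fold} unreachable on {shape}: achievable folds near the "
        f"request are {achieved[-1]:.3f} (with {len(achieved)} spokes)"
        + (f" and {achieved[-2]:.3f} (with {len(achieved) - 1})" if len(achieved) > 1 else "")
    )


def undersample(
    image: Image | np.ndarray,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpaceMeasurement:
    """Measure an image: unitary DFT, Gaussian noise at sampled cells, zero-fill.

    Noise is i.i.d. zero-mean Gaussian with standard deviation ``noise_sigma``
    added independently to the real and imaginary parts of *sampled* cells only.
    """
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    if pixels.shape != mask.shape:
        raise ValueError(f"image shape {pixels.shape} != mask shape {mask.shape}")
    data = fft2c(pixels)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        m = mask.n_sampled
        noise = rng.normal(0.0, noise_sigma, m) + 1j * rng.normal(0.0, noise_sigma, m)
        data[mask.grid] += noise
    data[~mask.grid] = 0.0
    return KSpaceMeasurement(data=data, mask=mask, noise_sigma=noise_sigma)


def zero_filled_recon(meas: KSpaceMeasurement) -> Image:
    """Inverse unitary DFT of the zero-filled measurement (x0, the aliased baseline)."""
    return Image(pixels=ifft2c(meas.data))
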