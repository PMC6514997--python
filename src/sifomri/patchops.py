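"""Overlapping patch extraction and patch-average reassembly.

An image is decomposed into all overlapping sqrt(n) x sqrt(n) blocks with origin
stride ``r`` (r=1 gives maximal overlap).  Each patch is vectorized column-major;
patches are ordered row-major by origin.  Reassembly averages the per-patch
approximations pixel-wise, dividing each pixel by the number of patches covering
it — exact averaging at borders as well as in the interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PatchConfig",
    "PatchSet",
    "extract_patches",
    "coverage_counts",
    "reassemble",
    "unnormalized_reassemble",
    "sample_training_patches",
]


@dataclass(frozen=True)
class PatchConfig:
    """Patch geometry: ``n`` pixels per patch (perfect square), origin stride ``r``."""

    n: int = 36
    stride: int = 1

    def __post_init__(self) -> None:
        ps = int(round(np.sqrt(self.n)))
        if ps * ps != self.n:
            raise ValueError(f"patch pixel count n={self.n} must be a perfect square")
        if not (1 <= self.stride <= ps):
            raise ValueError(f"stride must satisfy 1 <= r <= sqrt(n)={ps}")

    @property
    def patch_side(self) -> int:
        return int(round(np.sqrt(self.n)))


@dataclass
class PatchSet:
    """A stack of vectorized patches: ``matrix`` is n x P, column j one patch."""

    matrix: np.ndarray
    origins: np.ndarray  # (P, 2) top-left (row, col) coordinates
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.origins = np.asarray(self.origins)
        if self.matrix.ndim != 2 or self.origins.shape != (self.matrix.shape[1], 2):
            raise ValueError("inconsistent patch matrix / origins")

    @property
    def n_patches(self) -> int:
        return self.matrix.shape[1]


def _axis_origins(dim: int, ps: int, stride: int) -> np.ndarray:
    """Origins along one axis: regular grid plus a final border-touching origin."""
    if dim < ps:
        raise ValueError(f"image dimension {dim} smaller than patch side {ps}")
    last = dim - ps
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return np.asarray(origins)


def extract_patches(image: np.ndarray, config: PatchConfig) -> PatchSet:
    """All overlapping patches of ``image`` as columns of an n x P matrix.

    Vectorization is column-major within the patch; origins run row-major over
    the image.  Deterministic.
    """
    image = np.asarray(image)
    ps = config.patch_side
    oy = _axis_origins(image.shape[0], ps, config.stride)
    ox = _axis_origins(image.shape[1], ps, config.stride)
    windows = sliding_window_view(image, (ps, ps))[np.ix_(oy, ox)]
    # (R, C, ps, ps) -> column-major patch vectors: index pr fastest within pc
    mat = windows.transpose(0, 1, 3, 2).reshape(len(oy) * len(ox), ps * ps).T
    origins = np.stack(
        [np.repeat(oy, len(ox)), np.tile(ox, len(oy))], axis=1
    )
    return PatchSet(matrix=np.ascontiguousarray(mat), origins=origins,
                    source_shape=image.shape)


def coverage_counts(config: PatchConfig, shape: tuple[int, int]) -> np.ndarray:
    """Number of patches covering each pixel (n in the interior when r=1)."""
    ps = config.patch_side
    oy = _axis_origins(shape[0], ps, config.stride)
    ox = _axis_origins(shape[1], ps, config.stride)
    row_cov = np.zeros(shape[0], dtype=np.int64)
    col_cov = np.zeros(shape[1], dtype=np.int64)
    for o in oy:
        row_cov[o : o + ps] += 1
    for o in ox:
        col_cov[o : o + ps] += 1
    return np.outer(row_cov, col_cov)  # separable: patch grid is a product set


def _accumulate(patches: PatchSet, config: PatchConfig) -> np.ndarray:
    ps = config.patch_side
    rows, cols = patches.source_shape
    oy = np.unique(patches.origins[:, 0])
    ox = np.unique(patches.origins[:, 1])
    R, C = len(oy), len(ox)
    if R * C != patches.n_patches:
        raise ValueError("patch set origins inconsistent with a grid layout")
    out = np.zeros((rows, cols), dtype=np.result_type(patches.matrix, float))
    stack = patches.matrix.T.reshape(R, C, ps * ps)
    for pc in range(ps):
        for pr in range(ps):
            vals = stack[:, :, pc * ps + pr]
            out[np.ix_(oy + pr, ox + pc)] += vals
    return out


def unnormalized_reassemble(patches: PatchSet, config: PatchConfig) -> np.ndarray:
    """Sum of patch contributions without averaging — the adjoint of extraction."""
    return _accumulate(patches, config)


def reassemble(approx_patches: PatchSet, config: PatchConfig) -> np.ndarray:
    """Patch-average image: per-pixel mean of all patch approximations covering it.

    ``reassemble(extract_patches(x, c), c)`` reproduces ``x`` exactly.
    """
    acc = _accumulate(approx_patches, config)
    ps = config.patch_side
    oy = np.unique(approx_patches.origins[:, 0])
    ox = np.unique(approx_patches.origins[:, 1])
    row_cov = np.zeros(approx_patches.source_shape[0], dtype=np.int64)
    col_cov = np.zeros(approx_patches.source_shape[1], dtype=np.int64)
    for o in oy:
        row_cov[o : o + ps] += 1
    for o in ox:
        col_cov[o : o + ps] += 1
    cov = np.outer(row_cov, col_cov)
    if np.any(cov == 0):
        raise ValueError("patch set does not cover the image")
    return acc / cov


def sample_training_patches(patchset: PatchSet, count: int, seed: int = 0) -> PatchSet:
    """Uniform random subset of patches (without replacement) for dictionary training."""
    P = patchset.n_patches
    if count > P:
        raise ValueError(f"requested {count} training patches but only {P} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(P, size=count, replace=False)
    return PatchSet(
        matrix=patchset.matrix[:, idx],
        origins=patchset.origins[idx],
        source_shape=patchset.source_shape,
    )
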