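"""Image, mask, dictionary and measurement serialization.

Raster output is 8-bit grayscale PNG/PGM for viewing; exact numerics always go
through lossless raw array files (.npy).  Measurements are stored as paired
real/imaginary raw arrays plus a small JSON text header (shape, sigma, scheme,
fold, seed); masks as 1-bit rasters plus a raw boolean array.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .gridops import Image, KSpaceMeasurement, SamplingMask
from .sparse_coding import Dictionary

__all__ = [
    "load_image",
    "save_image",
    "save_mask",
    "load_mask",
    "save_measurement",
    "load_measurement",
    "save_dictionary",
    "load_dictionary",
]


def load_image(path: str | Path) -> Image:
    """Read an image file: raster formats via imageio, .npy as raw array."""
    path = Path(path)
    if path.suffix == ".npy":
        return Image(pixels=np.load(path))
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=2)
    return Image(pixels=arr)


def save_image(image: Image | np.ndarray, path: str | Path) -> None:
    """Write a magnitude image; .npy is lossless, raster formats are 8-bit."""
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, pixels)
        return
    mag = np.abs(pixels)
    iio.imwrite(path, np.clip(mag, 0, 255).astype(np.uint8))


def save_mask(mask: SamplingMask, raster_path: str | Path, array_path: str | Path) -> None:
    raster_path, array_path = Path(raster_path), Path(array_path)
    raster_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(raster_path, (mask.grid.astype(np.uint8) * 255))
    np.save(array_path, mask.grid)


def load_mask(array_path: str | Path, scheme: str = "vd_random",
              seed: int | None = None) -> SamplingMask:
    return SamplingMask(grid=np.load(array_path), scheme=scheme, seed=seed)


def save_measurement(meas: KSpaceMeasurement, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".real.npy"), meas.data.real)
    np.save(prefix.with_suffix(".imag.npy"), meas.data.imag)
    np.save(prefix.with_suffix(".mask.npy"), meas.mask.grid)
    header = {
        "shape": list(meas.shape),
        "noise_sigma": meas.noise_sigma,
        "scheme": meas.mask.scheme,
        "fold": meas.mask.fold,
        "seed": meas.mask.seed,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_measurement(prefix: str | Path) -> KSpaceMeasurement:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".real.npy")) + 1j * np.load(
        prefix.with_suffix(".imag.npy")
    )
    mask = SamplingMask(
        grid=np.load(prefix.with_suffix(".mask.npy")),
        scheme=header["scheme"],
        seed=header["seed"],
    )
    return KSpaceMeasurement(data=data, mask=mask, noise_sigma=header["noise_sigma"])


def save_dictionary(D: Dictionary, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), D.atoms)
    prefix.with_suffix(".json").write_text(
        json.dumps({"n": D.n, "K": D.K}, indent=2)
    )


def load_dictionary(prefix: str | Path) -> Dictionary:
    return Dictionary(atoms=np.load(Path(prefix).with_suffix(".npy")))
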