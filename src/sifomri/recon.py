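"""The SiFo reconstruction loop and the DLMRI baseline.

Starting from the zero-filled image, each outer iteration (1) learns a patch
dictionary on a random training subset of the current estimate's overlapping
patches (SimCO + FOCUSS for SiFo, K-SVD + OMP for DLMRI), (2) sparse-codes
*all* patches against it, (3) reassembles the per-patch approximations into the
"patched average" image, and (4) restores measured k-space data: at unsampled
cells the average's spectrum N is kept, at sampled cells it is either replaced
by the measurement N0 (noiseless limit, eta -> inf) or blended as
(N + eta N0) / (1 + eta) with eta = lambda * sigma in the noisy case.

The estimate is kept complex throughout; patches are coded on the real part by
default (real-valued sparsifying transform), with magnitude/complex coding
available via ``complex_patches``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics as _metrics
from .dict_learning import DictLearnConfig, learn, representation_objective
from .gridops import Image, KSpaceMeasurement, fft2c, ifft2c, zero_filled_recon
from .patchops import PatchConfig, extract_patches, reassemble, sample_training_patches
from .sparse_coding import Dictionary, FocussParams, code_all

__all__ = [
    "ReconConfig",
    "ReconResult",
    "data_consistency_update",
    "sifo_reconstruct",
    "dlmri_reconstruct",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconConfig:
    """All reconstruction hyperparameters.

    Defaults follow the standard experimental protocol: 6x6 patches (n=36) at
    stride 1, K=36 atoms, sparsity tau0=6, SimCO regularizer mu=0.05, FOCUSS
    exponent p=0.5, lambda=140, 15 outer iterations, 200*K training patches.
    """

    patch: PatchConfig = field(default_factory=PatchConfig)
    dict: DictLearnConfig = field(default_factory=DictLearnConfig)
    focuss: FocussParams = field(default_factory=FocussParams)
    tau0: int = 6
    coder: str = "focuss"
    dict_method: str = "simco"
    outer_iters: int = 15
    train_patch_count: int | None = None  # default 200 * K
    dict_rounds: int = 2  # coding/update alternations per outer iteration
    lambda_weight: float = 140.0
    eta_mode: str = "auto"  # weighted when sigma > 0, noiseless_exact otherwise
    complex_patches: bool = False
    center_patches: bool = True  # code zero-mean patches, carry the DC separately
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_iters < 1:
            raise ValueError("outer_iters must be >= 1")
        if self.lambda_weight <= 0:
            raise ValueError("lambda_weight must be positive")
        if self.eta_mode not in ("auto", "noiseless_exact", "weighted"):
            raise ValueError("eta_mode must be 'auto', 'noiseless_exact' or 'weighted'")

    @property
    def resolved_train_count(self) -> int:
        return self.train_patch_count if self.train_patch_count else 200 * self.dict.K


@dataclass
class ReconResult:
    """Final estimate, per-iteration (PSNR, HFEN, objective) records, final dictionary."""

    image: Image
    per_iteration: list[tuple[float, float, float]]
    dictionary: Dictionary


def data_consistency_update(
    patch_avg_image: np.ndarray | Image,
    meas: KSpaceMeasurement,
    eta: float = 0.0,
    eta_mode: str = "noiseless_exact",
) -> Image:
    """k-space restoration: keep N off the sampled set, blend with N0 on it.

    In ``noiseless_exact`` mode sampled cells are replaced by the measured
    values exactly (the eta -> inf limit); in ``weighted`` mode they become
    (N + eta*N0) / (1 + eta), a convex combination of estimate and measurement.
    """
    pixels = patch_avg_image.pixels if isinstance(patch_avg_image, Image) else patch_avg_image
    if pixels.shape != meas.shape:
        raise ValueError("patch-average image / measurement shape mismatch")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    N = fft2c(pixels)
    S = meas.mask.grid
    if eta_mode == "noiseless_exact":
        N[S] = meas.data[S]
    elif eta_mode == "weighted":
        N[S] = (N[S] + eta * meas.data[S]) / (1.0 + eta)
    else:
        raise ValueError(f"unknown eta_mode {eta_mode!r}")
    return Image(pixels=ifft2c(N))


def _patch_view(x: np.ndarray, complex_patches: bool) -> np.ndarray:
    return np.abs(x) if complex_patches else np.real(x)


def _reconstruct(
    meas: KSpaceMeasurement,
    config: ReconConfig,
    reference: Image | np.ndarray | None = None,
    initial_dictionary: Dictionary | None = None,
) -> ReconResult:
    ref = None
    if reference is not None:
        ref = reference.pixels if isinstance(reference, Image) else np.asarray(reference)

    x = zero_filled_recon(meas).pixels
    eta = config.lambda_weight * meas.noise_sigma
    eta_mode = config.eta_mode
    if eta_mode == "auto":
        eta_mode = "weighted" if meas.noise_sigma > 0 else "noiseless_exact"
    if eta_mode == "weighted" and meas.noise_sigma == 0:
        # eta = lambda*sigma would be 0 and discard all measurements
        log.warning("weighted eta_mode with sigma=0; falling back to noiseless_exact")
        eta_mode = "noiseless_exact"

    D: Dictionary | None = initial_dictionary
    records: list[tuple[float, float, float]] = []
    for it in range(config.outer_iters):
        view = _patch_view(x, config.complex_patches)
        patches = extract_patches(view, config.patch)
        # per-patch DC is carried outside the sparse model: the dictionary then
        # spends its atoms (and tau0) on structure rather than mean level
        col_means = patches.matrix.mean(axis=0) if config.center_patches else 0.0
        patches.matrix = patches.matrix - col_means
        if config.center_patches:
            # flat patches reduce to roundoff dust after centering; their code
            # is indistinguishable from zero at image scale, so skip them
            norms = np.linalg.norm(patches.matrix, axis=0)
            patches.matrix[:, norms < 1e-9 * max(norms.max(), 1e-300)] = 0.0
        train_count = min(config.resolved_train_count, patches.n_patches)
        train = sample_training_patches(patches, train_count, seed=config.seed + it)
        D, _, _ = learn(
            train.matrix,
            coder=config.coder,
            dict_cfg=config.dict,
            tau0=config.tau0,
            outer_iters=config.dict_rounds,
            dict_method=config.dict_method,
            focuss_params=config.focuss,
            initial=D,  # warm start after the first iteration
        )
        theta = code_all(
            D, patches.matrix, coder=config.coder, params=config.focuss, tau0=config.tau0
        )
        objective = representation_objective(D.atoms, patches.matrix, theta.codes)
        patches.matrix = D.atoms @ theta.codes + col_means  # origins/shape reused
        avg = reassemble(patches, config.patch)
        x = data_consistency_update(avg, meas, eta=eta, eta_mode=eta_mode).pixels
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite image estimate at iteration {it}")
        if ref is not None:
            p = _metrics.psnr(x, ref)
            h = _metrics.hfen(x, ref)
        else:
            p = h = float("nan")
        records.append((p, h, objective))
        log.info("iter %d: psnr=%.3f dB, hfen=%.4f, objective=%.4g", it, p, h, objective)
    assert D is not None
    return ReconResult(image=Image(pixels=x), per_iteration=records, dictionary=D)


def sifo_reconstruct(
    meas: KSpaceMeasurement,
    config: ReconConfig | None = None,
    reference: Image | np.ndarray | None = None,
    initial_dictionary: Dictionary | None = None,
) -> ReconResult:
    """SiFo reconstruction: regularized SimCO dictionary update + FOCUSS coding.

    ``initial_dictionary`` warm-starts the first iteration (e.g. a dictionary
    saved from a previous run); by default the first dictionary is initialized
    from patches of the zero-filled estimate.
    """
    config = config or ReconConfig()
    config = replace(config, coder="focuss", dict_method="simco")
    return _reconstruct(meas, config, reference, initial_dictionary)


def dlmri_reconstruct(
    meas: KSpaceMeasurement,
    config: ReconConfig | None = None,
    reference: Image | np.ndarray | None = None,
    initial_dictionary: Dictionary | None = None,
) -> ReconResult:
    """DLMRI baseline: K-SVD dictionary update + OMP coding, same outer loop."""
    config = config or ReconConfig()
    config = replace(config, coder="omp", dict_method="ksvd")
    return _reconstruct(meas, config, reference, initial_dictionary)
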