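"""Dictionary initialization and update: regularized SimCO and the K-SVD baseline.

SimCO (simultaneous codeword optimization) treats the dictionary as a point on
the product of unit spheres and moves *all* atoms at once along the projected
gradient of

    f(D) = sum_j ||x_j - D theta_j||^2 + mu ||theta_j||^2,

where for each candidate D the coefficients theta_j are the optimal ridge
coefficients on the column's *fixed* sparsity support (the support pattern never
changes during the update).  Steps are chosen by backtracking Armijo line
search, and atoms are retracted to the sphere by renormalization, so the
objective never increases.

K-SVD updates atoms one at a time: each atom is replaced by the leading left
singular vector of the residual restricted to the patches that use it, and the
corresponding coefficient row by sigma_1 times the leading right singular
vector.  Unused atoms are replaced by the worst-represented training patch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sparse_coding import Dictionary, FocussParams, SparseCodeMatrix, code_all

__all__ = [
    "DictLearnConfig",
    "init_dictionary",
    "simco_update",
    "ksvd_update",
    "learn",
    "representation_objective",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DictLearnConfig:
    """Dictionary-learning controls.

    K                : number of atoms (36 matches the default 6x6 patch size).
    mu               : SimCO coefficient regularizer (>0 avoids ill-conditioned
                       atom/coefficient scaling; 0.05 is the experimental value).
    simco_inner_iters: projected-gradient steps per update call.
    step_init        : initial line-search step; step_shrink: backtracking factor.
    """

    K: int = 36
    mu: float = 0.05
    simco_inner_iters: int = 5
    step_init: float = 1.0
    step_shrink: float = 0.5
    max_backtracks: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")


def representation_objective(
    D: np.ndarray, X: np.ndarray, Theta: np.ndarray, mu: float = 0.0
) -> float:
    """sum_j ||x_j - D theta_j||^2 + mu ||theta_j||^2."""
    R = X - D @ Theta
    val = float(np.sum(R * R))
    if mu:
        val += mu * float(np.sum(Theta * Theta))
    return val


def init_dictionary(training_patches: np.ndarray, K: int, seed: int = 0) -> Dictionary:
    """Initialize from K distinct random training patches, normalized to unit norm.

    Patches are used as-is (means preserved); zero-norm candidates are skipped.
    """
    X = np.asarray(training_patches, dtype=float)
    norms = np.linalg.norm(X, axis=0)
    usable = np.flatnonzero(norms > 0)
    if usable.size < K:
        raise ValueError(f"need {K} nonzero training patches, found {usable.size}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(usable, size=K, replace=False)
    atoms = X[:, chosen] / norms[chosen]
    return Dictionary(atoms=atoms)


def _supports_by_size(pattern: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Group columns of a boolean K x P pattern by support size.

    Returns {size: (column_indices, supports array of shape (n_cols, size))}.
    """
    K, P = pattern.shape
    sizes = pattern.sum(axis=0)
    groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for s in np.unique(sizes):
        if s == 0:
            continue
        cols = np.flatnonzero(sizes == s)
        # nonzero row indices per column, in row order
        supp = np.nonzero(pattern[:, cols].T)[1].reshape(len(cols), int(s))
        groups[int(s)] = (cols, supp)
    return groups


def _ridge_refit(
    A: np.ndarray,
    X: np.ndarray,
    groups: dict[int, tuple[np.ndarray, np.ndarray]],
    mu: float,
) -> np.ndarray:
    """Optimal ridge coefficients on fixed supports: (D_S^T D_S + mu I)^-1 D_S^T x."""
    K = A.shape[1]
    Theta = np.zeros((K, X.shape[1]))
    for s, (cols, supp) in groups.items():
        Ds = A.T[supp]  # (n_cols, s, n)
        G = Ds @ Ds.transpose(0, 2, 1)
        G[:, np.arange(s), np.arange(s)] += mu + 1e-12
        rhs = np.einsum("psn,np->ps", Ds, X[:, cols])
        sol = np.linalg.solve(G, rhs[..., None])[..., 0]
        T = np.zeros((len(cols), K))
        np.put_along_axis(T, supp, sol, axis=1)
        Theta[:, cols] = T.T
    return Theta


def _normalize_atoms(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    return A / norms


def simco_update(
    D: Dictionary,
    X_train: np.ndarray,
    Theta: SparseCodeMatrix,
    config: DictLearnConfig,
) -> tuple[Dictionary, SparseCodeMatrix]:
    """Regularized SimCO: simultaneous projected-gradient update of all atoms.

    The sparsity pattern of ``Theta`` is held fixed; its nonzero values are
    re-optimized (ridge least squares per column) for every candidate
    dictionary.  Atoms used by no column have zero gradient and stay unchanged.
    Guaranteed objective non-increase.
    """
    A = D.atoms.copy()
    X = np.asarray(X_train, dtype=float)
    pattern = Theta.codes != 0
    groups = _supports_by_size(pattern)
    unused = np.flatnonzero(~pattern.any(axis=1))
    if unused.size:
        log.debug("simco_update: %d atoms used by no patch, left unchanged", unused.size)

    Th = _ridge_refit(A, X, groups, config.mu)
    f = representation_objective(A, X, Th, config.mu)
    for _ in range(config.simco_inner_iters):
        R = X - A @ Th
        grad = -2.0 * (R @ Th.T)  # Euclidean gradient wrt D (envelope: Th optimal)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient in SimCO update")
        # project to the tangent space of each unit sphere
        grad_t = grad - A * np.sum(A * grad, axis=0, keepdims=True)
        gnorm2 = float(np.sum(grad_t * grad_t))
        if gnorm2 <= 1e-30 * max(f, 1.0):
            break
        step = config.step_init
        accepted = False
        for _bt in range(config.max_backtracks):
            A_try = _normalize_atoms(A - step * grad_t)
            Th_try = _ridge_refit(A_try, X, groups, config.mu)
            f_try = representation_objective(A_try, X, Th_try, config.mu)
            if f_try <= f - 1e-4 * step * gnorm2:
                A, Th, f = A_try, Th_try, f_try
                accepted = True
                break
            step *= config.step_shrink
        if not accepted:
            break
    return Dictionary(atoms=A), SparseCodeMatrix(codes=Th, tau0=Theta.tau0)


def ksvd_update(
    D: Dictionary, X_train: np.ndarray, Theta: SparseCodeMatrix
) -> tuple[Dictionary, SparseCodeMatrix]:
    """K-SVD: sequential rank-1 SVD update of each atom and its coefficient row."""
    A = D.atoms.copy()
    X = np.asarray(X_train, dtype=float)
    codes = Theta.codes.copy()
    K = A.shape[1]
    for k in range(K):
        users = np.flatnonzero(codes[k])
        if users.size == 0:
            # replace with the worst-represented training patch
            err = np.linalg.norm(X - A @ codes, axis=0)
            worst = int(np.argmax(err))
            v = X[:, worst]
            nv = np.linalg.norm(v)
            if nv > 0:
                A[:, k] = v / nv
            log.debug("ksvd_update: atom %d unused, replaced by worst-fit patch", k)
            continue
        E = X[:, users] - A @ codes[:, users] + np.outer(A[:, k], codes[k, users])
        U, S, Vt = np.linalg.svd(E, full_matrices=False)
        A[:, k] = U[:, 0]
        codes[k, users] = S[0] * Vt[0]
    return Dictionary(atoms=A), SparseCodeMatrix(codes=codes, tau0=Theta.tau0)


def learn(
    training_patches: np.ndarray,
    coder: str,
    dict_cfg: DictLearnConfig,
    tau0: int,
    outer_iters: int,
    dict_method: str = "simco",
    focuss_params: FocussParams | None = None,
    initial: Dictionary | None = None,
) -> tuple[Dictionary, SparseCodeMatrix, list[float]]:
    """Alternate sparse coding and dictionary update for ``outer_iters`` rounds.

    Returns the learned dictionary, the codes of the training patches against
    it, and the per-round objective values (after each dictionary update).
    """
    X = np.asarray(training_patches, dtype=float)
    D = initial if initial is not None else init_dictionary(X, dict_cfg.K, dict_cfg.seed)
    Theta = code_all(D, X, coder=coder, params=focuss_params, tau0=tau0)
    mu = dict_cfg.mu if dict_method == "simco" else 0.0
    objectives = [representation_objective(D.atoms, X, Theta.codes, mu)]
    for _ in range(outer_iters):
        if dict_method == "simco":
            D, Theta = simco_update(D, X, Theta, dict_cfg)
        elif dict_method == "ksvd":
            D, Theta = ksvd_update(D, X, Theta)
        else:
            raise ValueError(f"unknown dict_method {dict_method!r}")
        objectives.append(representation_objective(D.atoms, X, Theta.codes, mu))
        if _ < outer_iters - 1:
            Theta = code_all(D, X, coder=coder, params=focuss_params, tau0=tau0)
    return D, Theta, objectives
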