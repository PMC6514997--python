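"""Sparse approximation of patches against a dictionary: FOCUSS and OMP.

FOCUSS (FOCal Underdetermined System Solver) is an iteratively reweighted
minimum-norm coder.  With the diagonal weighting ``M = diag(|theta|^p)`` each
iteration solves a Tikhonov-stabilized weighted least-squares problem

    b = argmin ||x - D M b||^2 + ridge ||b||^2,      theta <- M b,

which progressively concentrates energy on a few coefficients (a *soft*
sparsity constraint); coefficients falling below a relative magnitude floor are
pruned to zero and stay zero.  After the final iteration the code is hard
thresholded to the ``tau0`` largest-magnitude coefficients and those are re-fit
by least squares on their support, so every returned column honours the hard
bound ``||theta||_0 <= tau0``.

OMP (orthogonal matching pursuit) is the greedy baseline coder: it repeatedly
selects the atom most correlated with the residual and re-solves least squares
on the growing support.

Both coders have a vectorized many-column path (`code_all`) that matches the
per-column reference functions to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dictionary",
    "SparseCodeMatrix",
    "FocussParams",
    "focuss_code",
    "omp_code",
    "code_all",
]


@dataclass
class Dictionary:
    """n x K matrix of unit-norm atoms."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("dictionary must be a 2D array")
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(norms == 0):
            raise ValueError("dictionary contains a zero atom")
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("dictionary atoms must have unit l2 norm (within 1e-9)")

    @property
    def n(self) -> int:
        return self.atoms.shape[0]

    @property
    def K(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SparseCodeMatrix:
    """K x P coefficient matrix; every column has at most ``tau0`` nonzeros."""

    codes: np.ndarray
    tau0: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2D array")
        nnz = np.count_nonzero(self.codes, axis=0)
        if nnz.size and nnz.max() > self.tau0:
            raise ValueError(
                f"sparsity contract violated: a column has {nnz.max()} > tau0={self.tau0}"
            )

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class FocussParams:
    """FOCUSS controls.

    p          : diversity exponent of the weighting M = diag(|theta|^p), 0 < p <= 1.
    inner_iters: number of reweighting iterations.
    eps_prune  : relative magnitude floor — coefficients below
                 eps_prune * max|theta| (per column, per iteration) are pruned.
    ridge      : relative Tikhonov regularizer; the solve uses ridge * ||x||^2
                 (with a small conditioning floor for numerically-dead columns).
    """

    p: float = 0.5
    inner_iters: int = 8
    eps_prune: float = 1e-4
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("diversity exponent p must satisfy 0 < p <= 1")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")


def _refit_on_support(D: np.ndarray, x: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of x on D[:, support]; zeros elsewhere."""
    theta = np.zeros(D.shape[1])
    if support.size:
        sol, *_ = np.linalg.lstsq(D[:, support], x, rcond=None)
        theta[support] = sol
    return theta


def _project_tau0(D: np.ndarray, x: np.ndarray, theta: np.ndarray, tau0: int) -> np.ndarray:
    """Hard-threshold to the tau0 largest |theta| and re-fit on that support."""
    nz = np.flatnonzero(theta)
    if nz.size > tau0:
        keep = nz[np.argsort(np.abs(theta[nz]))[-tau0:]]
    else:
        keep = nz
    return _refit_on_support(D, x, keep)


def focuss_code(
    D: Dictionary, x_col: np.ndarray, params: FocussParams, tau0: int
) -> np.ndarray:
    """FOCUSS sparse code of a single column (reference implementation).

    Starts from the matched-filter estimate theta0 = D^T x, runs
    ``params.inner_iters`` reweighting iterations with pruning, then projects to
    the tau0-sparse least-squares fit on the surviving largest coefficients.
    """
    x = np.asarray(x_col, dtype=float).ravel()
    _check_finite(x)
    A = D.atoms
    if x.size != D.n:
        raise ValueError("column length does not match dictionary")
    xnorm2 = float(x @ x)
    if xnorm2 == 0.0:
        return np.zeros(D.K)
    lam = params.ridge * xnorm2
    theta = A.T @ x
    for _ in range(params.inner_iters):
        mx = np.max(np.abs(theta))
        if mx == 0.0:
            break
        w = np.abs(theta) ** params.p
        w[np.abs(theta) < params.eps_prune * mx] = 0.0
        w2 = w * w
        # conditioning floor: |theta|^2p and ridge*||x||^2 scale differently
        # (p != 1), so numerically-negligible columns would otherwise make the
        # system singular; bright columns never hit the floor
        lam_it = max(lam, 1e-10 * float(w2.max()))
        # theta = w^2 * D^T (D diag(w^2) D^T + lam I)^-1 x
        B = (A * w2) @ A.T
        B[np.diag_indices_from(B)] += lam_it
        y = np.linalg.solve(B, x)
        theta = w2 * (A.T @ y)
    return _project_tau0(A, x, theta, tau0)


def omp_code(
    D: Dictionary, x_col: np.ndarray, tau0: int, tol: float = 1e-10
) -> np.ndarray:
    """Orthogonal matching pursuit code of a single column.

    Greedy atom selection by maximal absolute residual correlation, full
    least-squares re-solve on the growing support; stops at tau0 atoms or when
    the residual norm falls below ``tol * ||x||``.
    """
    x = np.asarray(x_col, dtype=float).ravel()
    _check_finite(x)
    A = D.atoms
    if x.size != D.n:
        raise ValueError("column length does not match dictionary")
    xnorm = np.linalg.norm(x)
    theta = np.zeros(D.K)
    if xnorm == 0.0:
        return theta
    support: list[int] = []
    residual = x.copy()
    for _ in range(min(tau0, D.K)):
        corr = A.T @ residual
        corr[support] = 0.0
        k = int(np.argmax(np.abs(corr)))
        if abs(corr[k]) <= tol * xnorm:
            break
        support.append(k)
        sub = A[:, support]
        sol, *_ = np.linalg.lstsq(sub, x, rcond=None)
        residual = x - sub @ sol
        if np.linalg.norm(residual) <= tol * xnorm:
            break
    if support:
        theta = _refit_on_support(A, x, np.asarray(support))
    return theta


# ---------------------------------------------------------------------------
# vectorized many-column paths


def _batched_support_refit(
    A: np.ndarray, X: np.ndarray, supports: np.ndarray
) -> np.ndarray:
    """LS refit of each column of X on its (uniform-size) support. Returns K x P."""
    P = X.shape[1]
    K = A.shape[1]
    s = supports.shape[1]
    theta = np.zeros((K, P))
    if s == 0:
        return theta
    Ds = A.T[supports]  # (P, s, n)
    G = Ds @ Ds.transpose(0, 2, 1)  # (P, s, s)
    G[:, np.arange(s), np.arange(s)] += 1e-12  # jitter against exact rank deficiency
    rhs = np.einsum("psn,np->ps", Ds, X)
    sol = np.linalg.solve(G, rhs[..., None])[..., 0]  # (P, s)
    np.put_along_axis(theta.T, supports, sol, axis=1)
    return theta


def _focuss_inner_dense(
    A: np.ndarray, Xc: np.ndarray, W2: np.ndarray, lam: np.ndarray
) -> np.ndarray:
    """theta = W2 * D^T (D diag(W2) D^T + lam I)^-1 x for every column."""
    n = A.shape[0]
    Pc = Xc.shape[1]
    B = (W2[:, None, :] * A[None, :, :]).reshape(Pc * n, -1) @ A.T
    B = B.reshape(Pc, n, n)
    B[:, np.arange(n), np.arange(n)] += lam[:, None]
    Y = np.linalg.solve(B, Xc.T[:, :, None])[..., 0]  # (Pc, n)
    return W2.T * (A.T @ Y.T)


def _focuss_inner_lowrank(
    A: np.ndarray, Xc: np.ndarray, W2: np.ndarray, lam: np.ndarray, smax: int
) -> np.ndarray:
    """Same solve through the dual (Woodbury) form when weights are s-sparse.

    With U = D_S W_S (padding to smax columns with zero weight is harmless),
    (lam I + U U^T)^-1 x = (x - U (lam I_s + U^T U)^-1 U^T x) / lam.
    """
    K = A.shape[1]
    Pc = Xc.shape[1]
    order = np.argpartition(-W2, min(smax, K - 1), axis=1)[:, :smax]  # (Pc, smax)
    Ws = np.sqrt(np.take_along_axis(W2, order, axis=1))  # (Pc, smax)
    U = A.T[order] * Ws[:, :, None]  # (Pc, smax, n) rows are weighted atoms
    G = U @ U.transpose(0, 2, 1)  # (Pc, smax, smax)
    G[:, np.arange(smax), np.arange(smax)] += lam[:, None]
    Ux = np.einsum("psn,np->ps", U, Xc)
    sol = np.linalg.solve(G, Ux[..., None])[..., 0]  # (Pc, smax)
    Y = (Xc - np.einsum("psn,ps->np", U, sol)) / lam[None, :]
    Theta = W2.T * (A.T @ Y)
    # numerically exact zeros off the weight support
    mask = np.zeros((Pc, K), dtype=bool)
    np.put_along_axis(mask, order, True, axis=1)
    Theta[~mask.T] = 0.0
    return Theta


def _focuss_code_batch(
    D: Dictionary, X: np.ndarray, params: FocussParams, tau0: int, chunk: int = 4096
) -> np.ndarray:
    A = D.atoms
    n, K = A.shape
    P = X.shape[1]
    lowrank_cutoff = max(tau0 + 2, n // 3)
    out = np.zeros((K, P))
    for start in range(0, P, chunk):
        Xc = X[:, start : start + chunk]
        xnorm2 = np.einsum("np,np->p", Xc, Xc)
        live = xnorm2 > 0
        if not np.any(live):
            continue
        lam = params.ridge * xnorm2
        Theta = A.T @ Xc  # (K, Pc)
        active = live.copy()
        for _ in range(params.inner_iters):
            mx = np.max(np.abs(Theta[:, active]), axis=0, initial=0.0)
            act_idx = np.flatnonzero(active)[mx > 0]
            if act_idx.size == 0:
                break
            Th_a = Theta[:, act_idx]
            w = np.abs(Th_a) ** params.p
            w[np.abs(Th_a) < params.eps_prune * np.abs(Th_a).max(axis=0)[None, :]] = 0.0
            W2 = (w * w).T  # (Pa, K)
            # same conditioning floor as the per-column reference
            lam_eff = np.maximum(lam[act_idx], 1e-10 * W2.max(axis=1))
            nnz = np.count_nonzero(W2, axis=1)
            dense_cols = nnz > lowrank_cutoff
            Theta_new = np.empty_like(Th_a)
            if np.any(dense_cols):
                Theta_new[:, dense_cols] = _focuss_inner_dense(
                    A, Xc[:, act_idx[dense_cols]], W2[dense_cols], lam_eff[dense_cols]
                )
            if np.any(~dense_cols):
                Theta_new[:, ~dense_cols] = _focuss_inner_lowrank(
                    A, Xc[:, act_idx[~dense_cols]], W2[~dense_cols],
                    lam_eff[~dense_cols], lowrank_cutoff,
                )
            # freeze columns whose iterate has stopped moving
            delta = np.max(np.abs(Theta_new - Th_a), axis=0)
            scale = np.maximum(np.max(np.abs(Th_a), axis=0), 1e-300)
            Theta[:, act_idx] = Theta_new
            still = delta > 1e-9 * scale
            active = np.zeros_like(active)
            active[act_idx[still]] = True
            if not np.any(active):
                break
        # final hard projection to tau0 + LS refit
        view = out[:, start : start + chunk]
        nnz = np.count_nonzero(Theta, axis=0)
        full = live & (nnz >= tau0)
        if np.any(full):
            supp = np.argpartition(np.abs(Theta[:, full]), K - tau0, axis=0)[-tau0:].T
            view[:, full] = _batched_support_refit(A, Xc[:, full], supp)
        rest = live & ~full
        for j in np.flatnonzero(rest):
            view[:, j] = _project_tau0(A, Xc[:, j], Theta[:, j], tau0)
    return out


def _omp_code_batch(
    D: Dictionary, X: np.ndarray, tau0: int, tol: float = 1e-10
) -> np.ndarray:
    A = D.atoms
    n, K = A.shape
    P = X.shape[1]
    xnorm = np.linalg.norm(X, axis=0)
    active = xnorm > 0
    supports = np.zeros((P, 0), dtype=np.int64)
    residual = X.copy()
    sol = np.zeros((P, 0))
    for t in range(min(tau0, K)):
        if not np.any(active):
            break
        corr = A.T @ residual  # (K, P)
        if t:
            np.put_along_axis(corr.T, supports, 0.0, axis=1)
        picks = np.argmax(np.abs(corr), axis=0)
        gain = np.abs(corr[picks, np.arange(P)])
        active = active & (gain > tol * xnorm)
        if not np.any(active):
            break
        # picks never collide with an existing support entry (corr zeroed there),
        # so appending the pick for inactive columns too is harmless: its
        # coefficient stays frozen at zero below.
        supports = np.concatenate([supports, picks[:, None]], axis=1)
        # solve LS on supports for active columns (size t+1)
        Ds = A.T[supports]  # (P, t+1, n)
        G = Ds @ Ds.transpose(0, 2, 1)
        G[:, np.arange(t + 1), np.arange(t + 1)] += 1e-12
        rhs = np.einsum("psn,np->ps", Ds, X)
        full_sol = np.linalg.solve(G, rhs[..., None])[..., 0]
        sol = np.where(active[:, None], full_sol,
                       np.concatenate([sol, np.zeros((P, 1))], axis=1))
        recon = np.einsum("ps,psn->np", sol, A.T[supports])
        residual = np.where(active[None, :], X - recon, residual)
        active = active & (np.linalg.norm(residual, axis=0) > tol * xnorm)
    theta = np.zeros((K, P))
    if supports.shape[1]:
        # reversed order: if an inactive column ever appended a duplicate index
        # (its frozen zero), the earlier real coefficient must win the write
        np.put_along_axis(theta.T, supports[:, ::-1], sol[:, ::-1], axis=1)
    return theta


def code_all(
    D: Dictionary,
    patch_matrix: np.ndarray,
    coder: str = "focuss",
    params: FocussParams | None = None,
    tau0: int = 6,
) -> SparseCodeMatrix:
    """Sparse-code every column of ``patch_matrix`` with the chosen coder.

    Columns are coded independently; the result is deterministic given inputs.
    """
    X = np.asarray(patch_matrix, dtype=float)
    _check_finite(X)
    if X.shape[0] != D.n:
        raise ValueError("patch matrix row count does not match dictionary")
    if coder == "focuss":
        codes = _focuss_code_batch(D, X, params or FocussParams(), tau0)
    elif coder == "omp":
        codes = _omp_code_batch(D, X, tau0)
    else:
        raise ValueError(f"unknown coder {coder!r} (expected 'focuss' or 'omp')")
    return SparseCodeMatrix(codes=codes, tau0=tau0)
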