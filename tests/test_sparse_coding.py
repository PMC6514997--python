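"""FOCUSS and OMP sparse coders: exactness, recovery, descent, and contracts."""

import itertools

import numpy as np
import pytest

import sifomri as sm
from sifomri.fixtures import planted_sparse_instance
from sifomri.sparse_coding import (Dictionary, FocussParams, code_all, focuss_code,
                                   omp_code)


@pytest.fixture(scope="module")
def small_dict():
    rng = np.random.default_rng(0)
    atoms = rng.standard_normal((20, 50))
    return Dictionary(atoms=atoms / np.linalg.norm(atoms, axis=0))


class TestFocuss:
    def test_zero_input_zero_code(self, small_dict):
        theta = focuss_code(small_dict, np.zeros(20), FocussParams(), 3)
        assert np.all(theta == 0)

    def test_single_atom_recovered_exactly(self, small_dict):
        x = small_dict.atoms[:, 17]
        theta = focuss_code(small_dict, x, FocussParams(), 1)
        assert np.flatnonzero(theta).tolist() == [17]
        assert np.linalg.norm(x - small_dict.atoms @ theta) <= 1e-6

    def test_planted_support_recovery_rate(self):
        """Exact 3-sparse support recovery on the 20x50 planted ensemble."""
        hits = 0
        for trial in range(100):
            D, codes, X = planted_sparse_instance(20, 50, 1, 3, 0.0, seed=trial)
            theta = focuss_code(D, X[:, 0], FocussParams(), 3)
            if set(np.flatnonzero(theta)) == set(np.flatnonzero(codes.codes[:, 0])):
                hits += 1
        assert hits >= 95

    def test_weighted_objective_descent(self):
        """The regularized FOCUSS cost ||x-Dt||^2 + ridge*sum|t|^(2(1-p)) never rises."""
        params = FocussParams()
        q = 2 * (1 - params.p)
        for trial in range(100):
            D, _, X = planted_sparse_instance(12, 24, 1, 3, 0.1, seed=500 + trial)
            x = X[:, 0]
            A = D.atoms
            lam = params.ridge * float(x @ x)

            def cost(theta):
                r = x - A @ theta
                return float(r @ r) + lam * float(np.sum(np.abs(theta) ** q))

            theta = A.T @ x
            costs = [cost(theta)]
            for _ in range(params.inner_iters):
                mx = np.max(np.abs(theta))
                if mx == 0:
                    break
                w = np.abs(theta) ** params.p
                w[np.abs(theta) < params.eps_prune * mx] = 0.0
                B = (A * w * w) @ A.T
                B[np.diag_indices_from(B)] += lam
                theta = (w * w) * (A.T @ np.linalg.solve(B, x))
                costs.append(cost(theta))
            diffs = np.diff(costs)
            assert np.all(diffs <= 1e-6 * costs[0])

    def test_noise_amplification_bounded(self):
        """||D(theta_hat - theta*)|| stays within a modest factor of the noise."""
        ratios = []
        for trial in range(50):
            D, codes, clean = planted_sparse_instance(20, 50, 1, 3, 0.0, seed=trial)
            rng = np.random.default_rng(9000 + trial)
            eps = rng.standard_normal(20) * 0.01
            theta = focuss_code(D, clean[:, 0] + eps, FocussParams(), 3)
            err = np.linalg.norm(D.atoms @ theta - clean[:, 0])
            ratios.append(err / np.linalg.norm(eps))
        assert np.mean(ratios) <= 5.0

    def test_nonfinite_input_rejected(self, small_dict):
        with pytest.raises(ValueError):
            focuss_code(small_dict, np.full(20, np.nan), FocussParams(), 3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocussParams(p=0.0)
        with pytest.raises(ValueError):
            FocussParams(inner_iters=0)


class TestOmp:
    def test_single_atom_exact(self, small_dict):
        x = small_dict.atoms[:, 5]
        theta = omp_code(small_dict, x, 3)
        assert np.flatnonzero(theta).tolist() == [5]
        assert np.linalg.norm(x - small_dict.atoms @ theta) <= 1e-10

    def test_orthogonal_input_zero_code(self):
        # K < n: an input orthogonal to every atom gains nothing
        atoms = np.zeros((4, 2))
        atoms[0, 0] = atoms[1, 1] = 1.0
        D = Dictionary(atoms=atoms)
        x = np.array([0.0, 0.0, 1.0, 2.0])
        theta = omp_code(D, x, 2)
        assert np.all(theta == 0)

    def test_matches_greedy_oracle_and_bounded_by_best_support(self, rng):
        """OMP equals a brute-force greedy path; its residual is >= the exhaustive optimum."""
        for trial in range(20):
            r = np.random.default_rng(trial)
            atoms = r.standard_normal((5, 8))
            D = Dictionary(atoms=atoms / np.linalg.norm(atoms, axis=0))
            x = r.standard_normal(5)
            theta = omp_code(D, x, 2)
            # greedy oracle
            support: list[int] = []
            resid = x.copy()
            for _ in range(2):
                corr = np.abs(D.atoms.T @ resid)
                corr[support] = 0
                support.append(int(np.argmax(corr)))
                sol, *_ = np.linalg.lstsq(D.atoms[:, support], x, rcond=None)
                resid = x - D.atoms[:, support] @ sol
            omp_err = np.linalg.norm(x - D.atoms @ theta)
            assert omp_err == pytest.approx(np.linalg.norm(resid), abs=1e-10)
            best = min(
                np.linalg.norm(x - D.atoms[:, list(s)]
                               @ np.linalg.lstsq(D.atoms[:, list(s)], x, rcond=None)[0])
                for s in itertools.combinations(range(8), 2)
            )
            assert omp_err >= best - 1e-10


class TestCodeAll:
    def test_zero_matrix(self, small_dict):
        out = code_all(small_dict, np.zeros((20, 7)), "focuss", FocussParams(), 3)
        assert np.all(out.codes == 0)

    @pytest.mark.parametrize("coder", ["focuss", "omp"])
    def test_matches_per_column_reference(self, coder):
        D, _, X = planted_sparse_instance(36, 36, 120, 6, 0.05, seed=11)
        batch = code_all(D, X, coder, FocussParams(), 6).codes
        single = focuss_code if coder == "focuss" else lambda d, x, p, t: omp_code(d, x, t)
        ref = np.stack(
            [single(D, X[:, j], FocussParams(), 6) for j in range(X.shape[1])], axis=1
        )
        assert np.allclose(batch, ref, atol=1e-8)

    def test_column_permutation_equivariance(self):
        D, _, X = planted_sparse_instance(16, 24, 30, 3, 0.1, seed=3)
        perm = np.random.default_rng(0).permutation(30)
        a = code_all(D, X, "omp", tau0=3).codes[:, perm]
        b = code_all(D, X[:, perm], "omp", tau0=3).codes
        assert np.allclose(a, b)

    @pytest.mark.parametrize("coder", ["focuss", "omp"])
    def test_sparsity_contract(self, coder):
        D, _, X = planted_sparse_instance(20, 40, 60, 4, 0.3, seed=21)
        out = code_all(D, X, coder, FocussParams(), 4)
        assert np.count_nonzero(out.codes, axis=0).max() <= 4

    def test_unknown_coder_rejected(self, small_dict):
        with pytest.raises(ValueError):
            code_all(small_dict, np.zeros((20, 1)), "lasso", tau0=2)


class TestContainers:
    def test_dictionary_rejects_zero_or_unnormalized_atoms(self):
        with pytest.raises(ValueError):
            Dictionary(atoms=np.zeros((4, 3)))
        with pytest.raises(ValueError):
            Dictionary(atoms=np.eye(4) * 2.0)

    def test_sparse_code_matrix_enforces_tau0(self):
        with pytest.raises(ValueError):
            sm.SparseCodeMatrix(codes=np.ones((5, 2)), tau0=3)
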