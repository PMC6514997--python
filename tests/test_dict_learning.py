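"""Dictionary initialization, SimCO and K-SVD updates, and the alternation driver."""

import numpy as np
import pytest

import sifomri as sm
from sifomri.dict_learning import (DictLearnConfig, init_dictionary, ksvd_update,
                                   learn, representation_objective, simco_update)
from sifomri.fixtures import planted_sparse_instance
from sifomri.sparse_coding import Dictionary, SparseCodeMatrix


class TestInit:
    def test_unit_norms_and_determinism(self, rng):
        X = rng.standard_normal((16, 100))
        D1 = init_dictionary(X, 20, seed=5)
        D2 = init_dictionary(X, 20, seed=5)
        assert np.abs(np.linalg.norm(D1.atoms, axis=0) - 1).max() <= 1e-12
        assert np.array_equal(D1.atoms, D2.atoms)

    def test_constant_patches_give_constant_atoms(self):
        X = np.full((9, 50), 4.0)
        D = init_dictionary(X, 10, seed=0)
        expected = np.full(9, 1.0 / 3.0)
        assert np.allclose(D.atoms, expected[:, None])

    def test_zero_patches_skipped_and_shortage_rejected(self, rng):
        X = np.zeros((8, 30))
        X[:, :5] = rng.standard_normal((8, 5))
        D = init_dictionary(X, 5, seed=1)
        assert D.K == 5
        with pytest.raises(ValueError):
            init_dictionary(X, 6, seed=1)


def _random_instance(seed, n=8, K=12, P=40, tau=3, noise=0.3):
    return planted_sparse_instance(n, K, P, tau, noise, seed=seed)


class TestSimco:
    def test_objective_non_increase_100_instances(self):
        cfg = DictLearnConfig(K=12, mu=0.05)
        for seed in range(100):
            D, Th, X = _random_instance(seed)
            f0 = representation_objective(D.atoms, X, Th.codes, cfg.mu)
            D2, Th2 = simco_update(D, X, Th, cfg)
            f1 = representation_objective(D2.atoms, X, Th2.codes, cfg.mu)
            assert f1 <= f0 + 1e-9 * max(f0, 1.0)

    def test_unit_norm_and_pattern_conservation(self):
        cfg = DictLearnConfig(K=12, mu=0.05)
        D, Th, X = _random_instance(7)
        D2, Th2 = simco_update(D, X, Th, cfg)
        assert np.abs(np.linalg.norm(D2.atoms, axis=0) - 1).max() <= 1e-9
        assert np.array_equal(Th2.codes != 0, Th.codes != 0)

    def test_orthonormal_full_support_refit_is_projection(self):
        # mu=0, square orthonormal D, full support: refit must equal D^T X
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        D = Dictionary(atoms=Q)
        X = rng.standard_normal((6, 10))
        Th = SparseCodeMatrix(codes=np.ones((6, 10)), tau0=6)
        cfg = DictLearnConfig(K=6, mu=0.0, simco_inner_iters=0)
        _, Th2 = simco_update(D, X, Th, cfg)
        assert np.allclose(Th2.codes, Q.T @ X, atol=1e-8)

    def test_stationary_point_unchanged(self):
        # D exactly representing the data with optimal codes: zero tangent gradient
        D, Th, X = planted_sparse_instance(8, 12, 40, 3, 0.0, seed=1)
        cfg = DictLearnConfig(K=12, mu=0.0)
        D2, _ = simco_update(D, X, Th, cfg)
        assert np.allclose(D2.atoms, D.atoms, atol=1e-8)

    def test_unused_atom_left_unchanged(self):
        D, Th, X = _random_instance(3)
        codes = Th.codes.copy()
        codes[5, :] = 0.0  # atom 5 now used by nobody
        Th = SparseCodeMatrix(codes=codes, tau0=Th.tau0)
        D2, _ = simco_update(D, X, Th, DictLearnConfig(K=12, mu=0.05))
        assert np.allclose(D2.atoms[:, 5], D.atoms[:, 5])


class TestKsvd:
    def test_objective_non_increase_100_instances(self):
        for seed in range(100):
            D, Th, X = _random_instance(seed + 200)
            f0 = representation_objective(D.atoms, X, Th.codes)
            D2, Th2 = ksvd_update(D, X, Th)
            f1 = representation_objective(D2.atoms, X, Th2.codes)
            assert f1 <= f0 + 1e-9 * max(f0, 1.0)
            assert np.abs(np.linalg.norm(D2.atoms, axis=0) - 1).max() <= 1e-9

    def test_single_atom_full_support_is_rank_one_svd(self, rng):
        X = rng.standard_normal((6, 15))
        v = rng.standard_normal(6)
        D = Dictionary(atoms=(v / np.linalg.norm(v))[:, None])
        Th = SparseCodeMatrix(codes=np.ones((1, 15)), tau0=1)
        D2, Th2 = ksvd_update(D, X, Th)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        assert np.allclose(np.abs(D2.atoms[:, 0]), np.abs(U[:, 0]), atol=1e-10)
        assert np.allclose(D2.atoms @ Th2.codes, S[0] * np.outer(U[:, 0], Vt[0]),
                           atol=1e-10)

    def test_unused_atom_replaced_by_worst_fit_patch(self):
        D, Th, X = _random_instance(9)
        codes = Th.codes.copy()
        codes[4, :] = 0.0
        Th = SparseCodeMatrix(codes=codes, tau0=Th.tau0)
        D2, _ = ksvd_update(D, X, Th)
        assert not np.allclose(D2.atoms[:, 4], D.atoms[:, 4])
        assert np.isclose(np.linalg.norm(D2.atoms[:, 4]), 1.0)


class TestLearn:
    def test_zero_rounds_returns_initial(self):
        D0, _, X = planted_sparse_instance(8, 10, 60, 2, 0.1, seed=4)
        D, Th, objs = learn(X, "omp", DictLearnConfig(K=10, seed=4), 2, 0,
                            dict_method="ksvd", initial=D0)
        assert np.array_equal(D.atoms, D0.atoms)
        assert len(objs) == 1

    @pytest.mark.parametrize("method,coder", [("simco", "focuss"), ("ksvd", "omp")])
    def test_update_objective_sequence_non_increasing(self, method, coder):
        _, _, X = planted_sparse_instance(16, 20, 300, 3, 0.05, seed=8)
        cfg = DictLearnConfig(K=20, mu=0.05 if method == "simco" else 0.0, seed=0)
        _, _, objs = learn(X, coder, cfg, 3, 5, dict_method=method)
        assert objs[-1] <= objs[0] * (1 + 1e-6)

    def test_planted_dictionary_recovery(self):
        """Exactly tau-sparse data: alternation reduces representation error >=10x."""
        _, _, X = planted_sparse_instance(16, 20, 400, 3, 0.0, seed=2)
        cfg = DictLearnConfig(K=20, mu=0.01, seed=0)
        _, _, objs = learn(X, "focuss", cfg, 3, 15, dict_method="simco")
        assert objs[-1] <= 0.10 * objs[0]

    def test_simco_ksvd_parity_on_denoising_benchmark(self):
        """Final representation errors of the two updates within 10% (sanity)."""
        Dp, Th, X = planted_sparse_instance(36, 36, 500, 4, 0.05, seed=6)
        res = {}
        for method, coder in (("simco", "focuss"), ("ksvd", "omp")):
            mu = 0.05 if method == "simco" else 0.0
            D, Thf, _ = learn(X, coder, DictLearnConfig(K=36, mu=mu, seed=1), 4, 8,
                              dict_method=method)
            res[method] = representation_objective(D.atoms, X, Thf.codes)
        assert res["simco"] <= 1.10 * res["ksvd"] or res["ksvd"] <= 1.10 * res["simco"]
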