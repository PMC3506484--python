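"""Gram construction, centering and regularized kernel CCA."""

import numpy as np
import pytest

from kccu import (
    KernelSpec,
    cca_first,
    center_gram,
    compute_gram,
    kcca_max_correlation,
)
from kccu._engine import StratumEngine

from conftest import make_matrix


class TestComputeGram:
    def test_rbf_diagonal_is_one(self, random_pair):
        G, _ = random_pair
        K = compute_gram(G, KernelSpec(family="rbf", sigma=0.5))
        np.testing.assert_allclose(np.diag(K.values), 1.0)

    def test_rbf_hand_computed_value(self):
        G = make_matrix([[0, 1, 2], [1, 1, 0]])
        K = compute_gram(G, KernelSpec(family="rbf", sigma=0.5))
        # ||u - v||^2 = 1 + 0 + 4 = 5 -> exp(-0.5 * 5)
        assert K.values[0, 1] == pytest.approx(0.0820849986238988, abs=1e-15)

    def test_ibs_extremes(self):
        G = make_matrix([[0, 0], [2, 2], [0, 0]])
        K = compute_gram(G, KernelSpec(family="ibs"))
        assert K.values[0, 2] == pytest.approx(1.0)  # identical vectors
        assert K.values[0, 1] == pytest.approx(0.0)  # (0,0) vs (2,2)

    def test_weighted_ibs_uses_inverse_sqrt_maf(self):
        G = make_matrix([[0, 0], [2, 0], [0, 1], [1, 1]])
        mafs = np.array([s.minor_allele_freq for s in G.snps])
        w = 1.0 / np.sqrt(mafs)
        K = compute_gram(G, KernelSpec(family="weighted_ibs"))
        expected = (w[0] * (2 - 2) / 1 + w[1] * 2) / (2 * w.sum())
        assert K.values[0, 1] == pytest.approx(expected)

    @pytest.mark.parametrize("family", ["linear", "polynomial", "sigmoid"])
    def test_dot_product_families_match_direct_formula(self, family, random_pair):
        G, _ = random_pair
        spec = KernelSpec(family=family, degree=3, offset=0.5, scale=0.2)
        K = compute_gram(G, spec).values
        dots = G.values @ G.values.T
        expected = {
            "linear": dots,
            "polynomial": (dots + 0.5) ** 3,
            "sigmoid": np.tanh(0.2 * dots + 0.5),
        }[family]
        np.testing.assert_allclose(K, expected)

    def test_unsupported_family_is_fatal(self):
        with pytest.raises(ValueError, match="family"):
            KernelSpec(family="spectral")


class TestCenterGram:
    def test_constant_kernel_annihilated(self):
        K = compute_gram(make_matrix([[1, 1], [1, 1], [1, 1]]), KernelSpec())
        np.testing.assert_allclose(center_gram(K).values, 0.0, atol=1e-12)

    def test_row_sums_zero_and_idempotent(self, random_pair):
        G, _ = random_pair
        Kc = center_gram(compute_gram(G, KernelSpec()))
        np.testing.assert_allclose(Kc.values.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(
            center_gram(Kc).values, Kc.values, atol=1e-10
        )

    def test_matches_feature_space_centering(self, rng):
        # linear Gram of pre-centred features is already doubly centred
        X = rng.normal(size=(30, 3))
        Xc = X - X.mean(0)
        G = Xc @ Xc.T
        from kccu.kernels import GramMatrix

        Kc = center_gram(GramMatrix(G, KernelSpec(family="linear")))
        np.testing.assert_allclose(Kc.values, G, atol=1e-10)


class TestKcca:
    def test_identical_gram_gives_unit_correlation(self, random_pair):
        G, _ = random_pair
        Kc = center_gram(compute_gram(G, KernelSpec()))
        kr, _, _ = kcca_max_correlation(Kc, Kc, eta=1e-10)
        assert kr == pytest.approx(1.0, abs=1e-6)

    def test_linear_small_eta_recovers_classical_cca(self, rng):
        spec = KernelSpec(family="linear")
        for _ in range(20):
            X = rng.integers(0, 3, (60, 4)).astype(float)
            Y = rng.integers(0, 3, (60, 3)).astype(float)
            r = cca_first(X, Y).r
            Kx = center_gram(compute_gram(make_matrix_like(X), spec))
            Ky = center_gram(compute_gram(make_matrix_like(Y), spec))
            kr, _, _ = kcca_max_correlation(Kx, Ky, eta=1e-8)
            assert kr == pytest.approx(r, abs=1e-4)

    def test_unregularized_full_rank_is_degenerate(self, rng):
        # m = 5 individuals, RBF features span 5 independent directions
        X = rng.integers(0, 3, (5, 6)).astype(float)
        Y = rng.integers(0, 3, (5, 7)).astype(float)
        Kx = center_gram(compute_gram(make_matrix_like(X), KernelSpec()))
        Ky = center_gram(compute_gram(make_matrix_like(Y), KernelSpec()))
        with pytest.warns(UserWarning, match="degenerate"):
            kr, _, _ = kcca_max_correlation(Kx, Ky, eta=0.0)
        assert kr == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_regularization_and_symmetric(self, random_pair):
        G_A, G_B = random_pair
        Kx = center_gram(compute_gram(G_A, KernelSpec()))
        Ky = center_gram(compute_gram(G_B, KernelSpec()))
        krs = [kcca_max_correlation(Kx, Ky, eta=e)[0] for e in (0.1, 1, 10, 100)]
        assert all(a >= b - 1e-12 for a, b in zip(krs, krs[1:]))
        kr_xy, _, _ = kcca_max_correlation(Kx, Ky, eta=5.0)
        kr_yx, _, _ = kcca_max_correlation(Ky, Kx, eta=5.0)
        assert kr_xy == pytest.approx(kr_yx, abs=1e-8)
        assert 0.0 <= kr_xy <= 1.0

    def test_permutation_equivariance(self, random_pair, rng):
        G_A, G_B = random_pair
        perm = rng.permutation(G_A.n_samples)
        spec = KernelSpec()
        Kx = center_gram(compute_gram(G_A, spec))
        Ky = center_gram(compute_gram(G_B, spec))
        kr0, _, _ = kcca_max_correlation(Kx, Ky, eta=3.0)
        Kxp = center_gram(compute_gram(G_A.take_samples(perm), spec))
        Kyp = center_gram(compute_gram(G_B.take_samples(perm), spec))
        kr1, _, _ = kcca_max_correlation(Kxp, Kyp, eta=3.0)
        assert kr1 == pytest.approx(kr0, abs=1e-10)

    def test_size_mismatch_is_fatal(self, random_pair):
        G_A, G_B = random_pair
        Kx = center_gram(compute_gram(G_A, KernelSpec()))
        Ky = center_gram(compute_gram(G_B.take_samples(range(100)), KernelSpec()))
        with pytest.raises(ValueError, match="size"):
            kcca_max_correlation(Kx, Ky, eta=1.0)


class TestPatternCompressedPath:
    """The low-rank unique-pattern solver must agree with the dense one."""

    @pytest.mark.parametrize("m", [50, 120, 200])
    def test_agrees_with_dense_eigenproblem(self, m, rng):
        X = rng.integers(0, 3, (m, 4)).astype(float)
        Y = rng.integers(0, 3, (m, 5)).astype(float)
        spec = KernelSpec()
        Kx = center_gram(compute_gram(make_matrix_like(X), spec))
        Ky = center_gram(compute_gram(make_matrix_like(Y), spec))
        for eta in (0.5, 5.0, 0.1 * m):
            dense, _, _ = kcca_max_correlation(Kx, Ky, eta=eta)
            fast = StratumEngine(
                X, Y, "kcca", KernelSpec(eta=eta)
            ).corr()
            assert fast == pytest.approx(dense, abs=1e-6)

    def test_cca_engine_matches_direct_solver(self, rng):
        X = rng.integers(0, 3, (150, 5)).astype(float)
        Y = rng.integers(0, 3, (150, 6)).astype(float)
        assert StratumEngine(X, Y, "cca").corr() == pytest.approx(
            cca_first(X, Y).r, abs=1e-10
        )


def make_matrix_like(values):
    return make_matrix(values)
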