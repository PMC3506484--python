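"""The CCU/KCCU statistic: Fisher transform, bootstrap, U, permutation, min-p."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kccu import (
    CaseControlSplit,
    KernelSpec,
    bootstrap_var_z,
    co_association_test,
    fisher_z,
    pairwise_logistic_minp,
    permutation_pvalue,
)
from kccu._engine import StratumEngine

from conftest import make_matrix


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-15)
        # closed form 1/2 ln((1+r)/(1-r)) to machine precision
        for r in (0.1, 0.3, 0.8, 0.99):
            assert fisher_z(r) == pytest.approx(
                0.5 * np.log((1 + r) / (1 - r)), abs=1e-15
            )

    def test_strictly_increasing(self):
        rs = np.linspace(0, 0.999, 50)
        zs = [fisher_z(r) for r in rs]
        assert np.all(np.diff(zs) > 0)

    def test_clip_near_one_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            z = fisher_z(1.0)
        assert np.isfinite(z)

    def test_out_of_range_is_fatal(self):
        with pytest.raises(ValueError):
            fisher_z(-0.2)
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @given(
        st.floats(min_value=0.0, max_value=0.999),
        st.floats(min_value=0.0, max_value=0.999),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_order_preserving_and_invertible(self, r1, r2):
        z1, z2 = fisher_z(r1), fisher_z(r2)
        assert (z1 <= z2) == (r1 <= r2)
        assert np.tanh(z1) == pytest.approx(r1, abs=1e-12)


def _correlated_pair(rng, n, corr, p=2, q=2):
    """Two dosage matrices whose first columns share correlation ~corr."""
    u = rng.integers(0, 3, n)
    keep = rng.random(n) < corr
    a = np.column_stack([u] + [rng.integers(0, 3, n) for _ in range(p - 1)])
    b0 = np.where(keep, u, rng.integers(0, 3, n))
    b = np.column_stack([b0] + [rng.integers(0, 3, n) for _ in range(q - 1)])
    return make_matrix(a, "A", "a"), make_matrix(b, "B", "b")


def _null_split(rng, n_cases=150, n_controls=150):
    GA_d, GB_d = _correlated_pair(rng, n_cases, 0.0)
    GA_c, GB_c = _correlated_pair(rng, n_controls, 0.0)
    return CaseControlSplit(GA_d, GB_d, GA_c, GB_c)


class TestBootstrapVarZ:
    def test_fixed_seed_is_bit_reproducible(self, rng):
        GA, GB = _correlated_pair(rng, 120, 0.3)
        v1, z1 = bootstrap_var_z(GA, GB, "cca", None, B=50, seed=7)
        v2, z2 = bootstrap_var_z(GA, GB, "cca", None, B=50, seed=7)
        assert (v1, z1) == (v2, z2)
        v3, _ = bootstrap_var_z(GA, GB, "cca", None, B=50, seed=8)
        assert v3 != v1

    def test_identical_single_columns_have_zero_variance(self, rng):
        x = rng.integers(0, 3, 50)
        GA = make_matrix(x[:, None], "A", "a")
        GB = make_matrix(x[:, None], "B", "b")
        with pytest.warns(UserWarning, match="clipping"):
            var_z, z_hat = bootstrap_var_z(GA, GB, "cca", None, B=20, seed=0)
        assert var_z == 0.0
        assert z_hat == pytest.approx(np.arctanh(1 - 1e-12))

    def test_matches_monte_carlo_variance_within_factor_two(self):
        """Bootstrap variance vs the variance of z across independent datasets."""

        def dataset(seed):
            r = np.random.default_rng(seed)
            return _correlated_pair(r, 300, 0.0, p=3, q=3)

        zs = []
        for s in range(200):
            GA, GB = dataset(1000 + s)
            eng = StratumEngine(GA.values, GB.values, "cca")
            zs.append(fisher_z(eng.corr()))
        mc_var = np.var(zs, ddof=1)
        GA, GB = dataset(999)
        boot_var, _ = bootstrap_var_z(GA, GB, "cca", None, B=200, seed=3)
        assert mc_var / 2 < boot_var < mc_var * 2

    def test_too_few_replicates_is_fatal(self, rng):
        GA, GB = _correlated_pair(rng, 50, 0.0)
        with pytest.raises(ValueError, match="B = 2"):
            bootstrap_var_z(GA, GB, "cca", None, B=1, seed=0)


class TestCoAssociationTest:
    def test_stratum_swap_negates_u_exactly(self, rng):
        GA_d, GB_d = _correlated_pair(rng, 150, 0.5)
        GA_c, GB_c = _correlated_pair(rng, 150, 0.0)
        split = CaseControlSplit(GA_d, GB_d, GA_c, GB_c)
        for method in ("ccu", "kccu"):
            res = co_association_test(split, method, B=40, seed=5)
            res_sw = co_association_test(split.swapped(), method, B=40, seed=5)
            assert res_sw.U == -res.U  # bit-exact
            assert res_sw.p_value == res.p_value
            assert res_sw.var_z_cases == res.var_z_controls

    def test_same_seed_is_bit_reproducible(self, rng):
        split = _null_split(rng)
        r1 = co_association_test(split, "kccu", B=30, seed=11)
        r2 = co_association_test(split, "kccu", B=30, seed=11)
        assert r1.U == r2.U and r1.p_value == r2.p_value

    def test_result_invariants(self, rng):
        split = _null_split(rng)
        res = co_association_test(split, "kccu", KernelSpec(sigma=0.5), B=30, seed=1)
        assert res.U == pytest.approx(
            (res.z_cases - res.z_controls)
            / np.sqrt(res.var_z_cases + res.var_z_controls)
        )
        assert 0 < res.p_value <= 1
        assert 0 <= res.kr_cases < 1 and 0 <= res.kr_controls < 1
        assert res.method == "kccu" and res.n_bootstrap == 30

    def test_zero_total_variance_is_fatal(self):
        # two-row strata: every non-degenerate resample has the same counts,
        # so both bootstrap variances are exactly zero
        col = np.array([[0.0], [2.0]])
        GA = make_matrix(col, "A", "a")
        GB = make_matrix(col, "B", "b")
        split = CaseControlSplit(GA, GB, GA, GB)
        with pytest.raises(ValueError, match="variance"):
            co_association_test(split, "ccu", B=10, seed=0)

    def test_detects_case_only_cross_gene_correlation(self):
        """Induced correlation 0.6 in cases, 0 in controls, n = 500/500."""
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            GA_d, GB_d = _correlated_pair(r, 500, 0.6)
            GA_c, GB_c = _correlated_pair(r, 500, 0.0)
            split = CaseControlSplit(GA_d, GB_d, GA_c, GB_c)
            res = co_association_test(split, "ccu", B=50, seed=s)
            hits += res.p_value < 0.05
        assert hits >= 90


class TestPermutationPvalue:
    def test_strong_signal_attains_minimum_p(self, rng):
        GA_d, GB_d = _correlated_pair(rng, 300, 0.9)
        GA_c, GB_c = _correlated_pair(rng, 300, 0.0)
        split = CaseControlSplit(GA_d, GB_d, GA_c, GB_c)
        p = permutation_pvalue(split, "ccu", B=30, n_perm=19, seed=2)
        assert p == pytest.approx(1 / 20)

    def test_bounds_and_null_uniformity(self):
        ps = []
        for s in range(40):
            split = _null_split(np.random.default_rng(3000 + s))
            p = permutation_pvalue(split, "ccu", B=25, n_perm=24, seed=s)
            assert 1 / 25 <= p <= 1.0
            ps.append(p)
        # permutation p approximately uniform under the null
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairwiseLogisticMinP:
    def test_single_pair_reduction_matches_direct_fit(self, rng):
        import statsmodels.api as sm

        n = 400
        a = rng.integers(0, 3, n).astype(float)
        b = rng.integers(0, 3, n).astype(float)
        y = (rng.random(n) < 0.4).astype(int)
        res = pairwise_logistic_minp(
            make_matrix(a[:, None], "A", "a"), make_matrix(b[:, None], "B", "b"), y
        )
        direct = sm.Logit(
            y, np.column_stack([np.ones(n), a, b, a * b])
        ).fit(disp=0)
        assert res.min_p == pytest.approx(float(direct.pvalues[3]))
        assert res.best_pair == ("a1", "b1")

    def test_null_interaction_p_is_uniform_like(self):
        ps = []
        for s in range(60):
            r = np.random.default_rng(500 + s)
            a = r.integers(0, 3, 500).astype(float)
            b = r.integers(0, 3, 500).astype(float)
            y = (r.random(500) < 0.5).astype(int)
            res = pairwise_logistic_minp(
                make_matrix(a[:, None], "A", "a"),
                make_matrix(b[:, None], "B", "b"),
                y,
            )
            ps.append(res.min_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_separated_pair_scores_p_one(self):
        a = np.array([0.0, 0, 0, 2, 2, 2])
        y = np.array([0, 0, 0, 1, 1, 1])
        res = pairwise_logistic_minp(
            make_matrix(a[:, None], "A", "a"),
            make_matrix(a[:, None], "B", "b"),
            y,
        )
        assert res.min_p == 1.0
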