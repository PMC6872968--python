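import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statistics import NormalDist

from dfnc.errors import InvalidConfigError, InvalidInputError
from dfnc.inference import (
    dprime,
    ks_normality,
    partial_corr_behavior,
    permutation_mean_diff,
    state_edge_paired_t,
    state_mean_fnc,
)


def naive_bh_stepup(pvals, alpha=0.05):
    """Independent step-up oracle: largest i with p_(i) <= i/m * alpha."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    cutoff = 0
    for i in range(m, 0, -1):
        if sorted_p[i - 1] <= i / m * alpha:
            cutoff = i
            break
    reject = np.zeros(m, dtype=bool)
    reject[order[:cutoff]] = True
    return reject


class TestPermutationMeanDiff:
    def test_identical_groups_large_p(self, rng):
        a = rng.standard_normal(10)
        res = permutation_mean_diff(a, a.copy(), n_permutations=500, seed=0)
        assert res.p_value >= 0.5
        assert res.statistic == pytest.approx(0.0)

    def test_determinism(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        p1 = permutation_mean_diff(a, b, n_permutations=500, seed=4).p_value
        p2 = permutation_mean_diff(a, b, n_permutations=500, seed=4).p_value
        assert p1 == p2

    def test_p_floor(self, rng):
        a = rng.standard_normal(10) + 100
        b = rng.standard_normal(10)
        res = permutation_mean_diff(a, b, n_permutations=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501)

    def test_obvious_shift_detected_one_sided(self, rng):
        a = rng.standard_normal(15) + 3
        b = rng.standard_normal(15)
        res = permutation_mean_diff(a, b, n_permutations=1000, seed=2, sidedness="greater")
        assert res.p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            permutation_mean_diff(np.array([1.0]), np.array([1.0, 2.0]), seed=0)

    def test_super_uniform_null(self):
        # empirical CDF of null p-values stays below uniform + 0.02
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            a, b = rng.standard_normal(12), rng.standard_normal(12)
            ps.append(permutation_mean_diff(a, b, n_permutations=200, seed=rng).p_value)
        ps = np.sort(ps)
        ecdf = np.arange(1, 1001) / 1000
        assert np.max(ecdf - ps) <= 0.02  # super-uniform: CDF(p) <= p + 0.02


class TestStateEdgePairedT:
    def test_identical_tasks_no_rejections(self, rng):
        means = {f"s{i}": rng.standard_normal(91) for i in range(10)}
        table = state_edge_paired_t(means, {k: v.copy() for k, v in means.items()})
        assert table is not None
        assert not table["reject"].any()
        np.testing.assert_allclose(table["t"], 0.0)

    def test_planted_shift_detected(self, rng):
        a = {f"s{i}": rng.standard_normal(91) for i in range(15)}
        b = {k: v + 0.05 * rng.standard_normal(91) for k, v in a.items()}
        for k in b:
            b[k][7] = a[k][7] + 5.0  # large constant shift on edge 7
        table = state_edge_paired_t(a, b)
        assert bool(table.loc[table["edge"] == 7, "reject"].iloc[0])
        assert table.loc[table["edge"] != 7, "reject"].sum() <= 2

    def test_incomplete_pairs_excluded(self, rng):
        a = {f"s{i}": rng.standard_normal(10) for i in range(6)}
        b = {f"s{i}": rng.standard_normal(10) for i in range(1, 6)}
        table = state_edge_paired_t(a, b)
        assert int(table["n_pairs"].iloc[0]) == 5

    def test_few_pairs_skipped(self, rng):
        a = {"s1": rng.standard_normal(5), "s2": rng.standard_normal(5)}
        assert state_edge_paired_t(a, a) is None

    def test_bh_matches_naive_stepup(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = np.concatenate(
                [rng.uniform(0, 0.03, 5), rng.uniform(0, 1, 86)]
            )
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, naive_bh_stepup(p, 0.05))

    def test_fdr_controlled_on_planted_nulls(self, rng):
        # mean false-discovery proportion under partial signal stays near 0.05
        fdps = []
        for _ in range(150):
            n, m, signal = 20, 60, 8
            base = rng.standard_normal((n, m))
            shift = np.zeros(m)
            shift[:signal] = 1.5
            a = {f"s{i}": base[i] for i in range(n)}
            b = {f"s{i}": base[i] + shift + 0.5 * rng.standard_normal(m) for i in range(n)}
            table = state_edge_paired_t(a, b)
            rejected = table[table["reject"]]["edge"].to_numpy()
            if len(rejected):
                fdps.append(np.mean(rejected >= signal))
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 0.07


class TestStateMeanFNC:
    def test_mean_over_state_windows(self, rng):
        windows = rng.standard_normal((10, 4))
        labels = np.array([0, 1, 0, 1, 1, 0, 2, 2, 1, 0])
        m = state_mean_fnc(windows, labels, 1)
        np.testing.assert_allclose(m, windows[labels == 1].mean(axis=0))

    def test_unvisited_state_none(self, rng):
        assert state_mean_fnc(rng.standard_normal((5, 3)), np.zeros(5, int), 2) is None


class TestDprime:
    def test_equal_rates_zero(self):
        assert dprime(50, 100, 50, 100) == pytest.approx(0.0)

    def test_normal_quantile_oracle(self):
        # stdlib NormalDist as the independent quantile oracle
        nd = NormalDist()
        oracle = nd.inv_cdf(69.5 / 101) - nd.inv_cdf(31.5 / 101)
        assert dprime(69, 100, 31, 100) == pytest.approx(oracle, abs=0.01)

    def test_perfect_performance_finite(self):
        d = dprime(100, 100, 0, 100)
        assert np.isfinite(d)
        nd = NormalDist()
        assert d == pytest.approx(nd.inv_cdf(100.5 / 101) - nd.inv_cdf(0.5 / 101))

    @settings(max_examples=40, deadline=None)
    @given(
        h=st.integers(0, 50), f=st.integers(0, 80),
        ns=st.just(50), nn=st.just(80),
    )
    def test_antisymmetry(self, h, f, ns, nn):
        assert dprime(h, ns, f, nn) == pytest.approx(-dprime(f, nn, h, ns))

    def test_zero_denominator(self):
        with pytest.raises(InvalidInputError):
            dprime(0, 0, 0, 10)

    def test_counts_out_of_range(self):
        with pytest.raises(InvalidInputError):
            dprime(11, 10, 0, 10)


class TestPartialCorr:
    def test_orthogonal_covariate_reduces_to_pearson(self, rng):
        n = 64
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)
        # orthogonalize z against x and y exactly
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), x, y]))
        z = z - Q @ (Q.T @ z)
        res = partial_corr_behavior(x, y, z)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_identical_variables(self, rng):
        x = rng.standard_normal(30)
        res = partial_corr_behavior(x, x.copy(), rng.standard_normal(30))
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= np.finfo(float).tiny * 10

    def test_covariate_affine_invariance(self, rng):
        x, y, z = (rng.standard_normal(25) for _ in range(3))
        r1 = partial_corr_behavior(x, y, z).r
        r2 = partial_corr_behavior(x, y, 100.0 - 7.0 * z).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_t_and_df(self, rng):
        x, y, z = (rng.standard_normal(20) for _ in range(3))
        res = partial_corr_behavior(x, y, z)
        assert res.df == 17
        expected_t = res.r * np.sqrt(17) / np.sqrt(1 - res.r**2)
        assert res.statistic == pytest.approx(expected_t)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            partial_corr_behavior(np.ones(10), rng.standard_normal(10), rng.standard_normal(10))

    def test_too_small_n(self, rng):
        with pytest.raises(InvalidInputError):
            partial_corr_behavior(np.arange(3.0), np.arange(3.0), np.arange(3.0))


class TestKSNormality:
    def test_runs_on_gaussian(self, rng):
        res = ks_normality(rng.standard_normal(100))
        assert 0 < res.p_value <= 1
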