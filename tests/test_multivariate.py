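"""Winsorization, multivariate-normality screening, robust Mahalanobis
distance and the label-permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from morphorep.io_tables import FeaturePanel, SubjectTable
from morphorep.multivariate import (
    henze_zirkler,
    mardia_tests,
    permutation_test,
    robust_mahalanobis,
    winsorize,
)


def make_table(X_hc, X_ibs, feature_names=None):
    """Wrap two numeric group matrices into a SubjectTable."""
    X = np.vstack([X_hc, X_ibs])
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(X))])
    df.insert(1, "group", ["HC"] * len(X_hc) + ["IBS"] * len(X_ibs))
    df.insert(2, "sex", "F")
    df.insert(3, "age", 30.0)
    return SubjectTable(df, FeaturePanel(tuple(names), (), include_etiv=False))


class TestWinsorize:
    def test_constant_and_full_range_are_identities(self):
        x = np.full(7, 3.3)
        np.testing.assert_array_equal(winsorize(x), x)
        y = np.arange(10.0)
        np.testing.assert_array_equal(winsorize(y, 0, 100), y)

    def test_clips_to_interpolated_percentiles(self):
        x = np.arange(1.0, 11.0)
        out = winsorize(x, 10, 90)
        # linear-interpolation percentiles of 1..10: q10 = 1.9, q90 = 9.1
        assert out[0] == pytest.approx(1.9)
        assert out[-1] == pytest.approx(9.1)
        np.testing.assert_array_equal(out[2:8], x[2:8])

    @given(hnp.arrays(np.float64, st.integers(2, 30),
                      elements=st.floats(-100, 100, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_projection_properties(self, x):
        """Clipping is contractive and leaves interior order statistics alone.

        (Strict idempotence does not hold for interpolated percentiles: the
        clipped sample's own percentiles move slightly inward, so a second
        pass can nudge the extremes.  The contraction below is the invariant
        that does hold.)"""
        lo, hi = np.percentile(x, [10, 90])
        once = winsorize(x, 10, 90)
        assert once.min() >= lo - 1e-12 and once.max() <= hi + 1e-12
        interior = (x >= lo) & (x <= hi)
        np.testing.assert_array_equal(once[interior], x[interior])
        twice = winsorize(once, 10, 90)
        assert np.abs(twice - once).max() <= np.abs(once - x).max() + 1e-12

    def test_idempotent_when_limits_sit_on_repeated_values(self):
        # with >=10% mass exactly at each extreme the percentile equals the
        # data value and re-winsorizing changes nothing
        x = np.array([2.0] * 3 + list(range(3, 18)) + [20.0] * 3)
        once = winsorize(x, 10, 90)
        np.testing.assert_array_equal(winsorize(once, 10, 90), once)

    def test_guards(self):
        with pytest.raises(ValueError):
            winsorize(np.array([]), 10, 90)
        with pytest.raises(ValueError):
            winsorize(np.ones(5), 90, 10)


def mardia_double_sum_oracle(X):
    """Definitional O(n^2) double sums for multivariate skewness/kurtosis."""
    X = np.asarray(X, float)
    n = len(X)
    Y = X - X.mean(axis=0)
    S = Y.T @ Y / n
    Sinv = np.linalg.inv(S)
    b1 = sum((Y[i] @ Sinv @ Y[j]) ** 3 for i in range(n) for j in range(n)) / n**2
    b2 = sum((Y[i] @ Sinv @ Y[i]) ** 2 for i in range(n)) / n
    return b1, b2


class TestMardia:
    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 2))
        b1, b2 = mardia_double_sum_oracle(X)
        res = mardia_tests(X)
        n, p = X.shape
        assert res.skew_stat == pytest.approx(n * b1 / 6, rel=1e-10)
        assert res.kurt_stat == pytest.approx(
            (b2 - p * (p + 2)) / np.sqrt(8 * p * (p + 2) / n), rel=1e-10
        )

    def test_null_kurtosis_expectation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 3))
        b1, b2 = mardia_double_sum_oracle(X)
        assert b2 == pytest.approx(3 * 5, rel=0.05)  # p(p+2) = 15
        res = mardia_tests(X)
        assert res.kurt_p > 0.01

    def test_univariate_symmetric_sample_has_near_zero_skewness(self):
        x = np.concatenate([np.arange(-50, 0), np.arange(1, 51)]).reshape(-1, 1).astype(float)
        res = mardia_tests(x)
        assert res.skew_stat == pytest.approx(0.0, abs=1e-10)

    def test_singular_covariance_flagged(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=(20, 1))
        X = np.hstack([col, 2 * col, col + 1])
        res = mardia_tests(X)
        assert res.unstable and res.skew_stat is None


def hz_double_sum_oracle(X):
    """Definitional Henze-Zirkler statistic (smoothing parameter from n, p)."""
    X = np.asarray(X, float)
    n, p = X.shape
    Y = X - X.mean(axis=0)
    S = Y.T @ Y / n
    Sinv = np.linalg.inv(S)
    G = Y @ Sinv @ Y.T
    d = np.diag(G)
    Dij = d[:, None] + d[None, :] - 2 * G  # pairwise squared Mahalanobis
    b = ((n * (2 * p + 1)) / 4) ** (1 / (p + 4)) / np.sqrt(2)
    t1 = np.exp(-(b**2) / 2 * Dij).sum() / n**2
    t2 = 2 * (1 + b**2) ** (-p / 2) * np.exp(-(b**2) / (2 * (1 + b**2)) * d).sum() / n
    t3 = (1 + 2 * b**2) ** (-p / 2)
    return n * (t1 - t2 + t3)


class TestHenzeZirkler:
    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_definitional_oracle(self, p):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, p))
        res = henze_zirkler(X)
        assert not res.unstable
        assert res.hz_stat == pytest.approx(hz_double_sum_oracle(X), rel=1e-6)

    def test_null_rejection_rate(self):
        """Size of the alpha=0.05 test stays near nominal under normality."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            res = henze_zirkler(rng.normal(size=(500, 3)))
            assert not res.unstable
            rejections += res.hz_p < 0.05
        assert 0.03 * n_sim <= rejections <= 0.08 * n_sim

    def test_duplicated_column_flags_instability(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=(30, 1))
        res = henze_zirkler(np.hstack([col, col]))
        assert res.unstable


def classical_mahalanobis_oracle(X_hc, X_ibs):
    """Textbook two-sample Mahalanobis distance by direct linear solve."""
    n1, n2 = len(X_hc), len(X_ibs)
    diff = X_hc.mean(axis=0) - X_ibs.mean(axis=0)
    A = X_hc - X_hc.mean(axis=0)
    B = X_ibs - X_ibs.mean(axis=0)
    S = (A.T @ A + B.T @ B) / (n1 + n2 - 2)
    return float(np.sqrt(diff @ np.linalg.solve(S, diff)))


class TestRobustMahalanobis:
    def test_identical_groups_give_zero_distance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        res = robust_mahalanobis(make_table(X, X), [f"f{i}" for i in range(4)])
        assert res.distance == pytest.approx(0.0, abs=1e-10)
        assert res.p > 0.99

    def test_reduces_to_classical_at_full_range_mean_centers(self):
        rng = np.random.default_rng(3)
        X_hc = rng.normal(0, 1, size=(25, 3))
        X_ibs = rng.normal(0.5, 1, size=(30, 3))
        table = make_table(X_hc, X_ibs)
        res = robust_mahalanobis(
            table, ["f0", "f1", "f2"], winsor_limits=(0, 100), center="mean"
        )
        assert res.distance == pytest.approx(
            classical_mahalanobis_oracle(X_hc, X_ibs), rel=1e-9
        )

    def test_single_feature_matches_scalar_route(self):
        """The univariate case equals a pure-scalar replication of the recipe:
        clip at pooled 10/90 percentiles, difference of medians over the SD of
        median-centered clipped data.  (Clipping 20% of the mass shrinks the
        denominator, so the robust distance sits deliberately above the
        classical |mean difference|/SD on clean normal data.)"""
        rng = np.random.default_rng(9)
        x = rng.normal(0.0, 1.0, size=2000)
        y = rng.normal(1.0, 1.0, size=2000)
        res = robust_mahalanobis(make_table(x[:, None], y[:, None]), ["f0"])
        lo, hi = np.percentile(np.concatenate([x, y]), [10, 90])
        xc, yc = np.clip(x, lo, hi), np.clip(y, lo, hi)
        centered = np.concatenate([xc - np.median(xc), yc - np.median(yc)])
        sd = np.sqrt((centered**2).sum() / (len(centered) - 2))
        scalar = abs(np.median(xc) - np.median(yc)) / sd
        assert res.distance == pytest.approx(scalar, rel=1e-9)
        classical = abs(x.mean() - y.mean()) / np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        assert res.distance > classical  # denominator shrinkage, see docstring

    def test_affine_invariance_coordinatewise(self):
        rng = np.random.default_rng(5)
        X_hc = rng.normal(size=(20, 3))
        X_ibs = rng.normal(0.3, 1, size=(25, 3))
        feats = ["f0", "f1", "f2"]
        base = robust_mahalanobis(make_table(X_hc, X_ibs), feats)
        a = np.array([2.0, 0.5, 10.0])
        b = np.array([-1.0, 4.0, 0.0])
        moved = robust_mahalanobis(make_table(X_hc * a + b, X_ibs * a + b), feats)
        assert moved.distance == pytest.approx(base.distance, rel=1e-9)

    def test_invariant_to_row_and_feature_order(self):
        rng = np.random.default_rng(6)
        X_hc = rng.normal(size=(15, 3))
        X_ibs = rng.normal(0.4, 1, size=(18, 3))
        feats = ["f0", "f1", "f2"]
        base = robust_mahalanobis(make_table(X_hc, X_ibs), feats)
        shuffled = robust_mahalanobis(
            make_table(X_hc[rng.permutation(15)], X_ibs[rng.permutation(18)]),
            list(reversed(feats)),
        )
        assert shuffled.distance == pytest.approx(base.distance, rel=1e-9)

    def test_underdetermined_panel_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 5))
        with pytest.raises(ValueError, match="feature"):
            robust_mahalanobis(make_table(X, X), [f"f{i}" for i in range(5)])


def exact_permutation_p(X, labels):
    """Exhaustive enumeration over all group assignments of the given sizes."""
    n = len(labels)
    n_hc = int((labels == 0).sum())

    def stat(lab):
        diff = X[lab == 0].mean(axis=0) - X[lab == 1].mean(axis=0)
        return float(diff @ diff)

    observed = stat(labels)
    stats_all = []
    for hc_idx in itertools.combinations(range(n), n_hc):
        lab = np.ones(n, dtype=int)
        lab[list(hc_idx)] = 0
        stats_all.append(stat(lab))
    stats_all = np.array(stats_all)
    return float((stats_all >= observed).mean())


class TestPermutationTest:
    def test_degenerate_data_gives_p_one(self):
        X = np.ones((6, 2))
        res = permutation_test(make_table(X[:3], X[3:]), ["f0", "f1"], n_perm=50, seed=0)
        assert res.observed_stat == 0.0
        assert res.p_empirical == 1.0

    def test_widely_separated_groups_reject(self):
        """With 5+5 subjects 10 pooled SDs apart only the 2 label patterns
        reproducing the original partition reach the observed statistic, so
        the exact p is 2/C(10,5) < 0.01; the Monte-Carlo estimate must sit
        within binomial noise of it."""
        rng = np.random.default_rng(2)
        X_hc = rng.normal(0, 1, size=(5, 3))
        X_ibs = rng.normal(10, 1, size=(5, 3))
        X = np.vstack([X_hc, X_ibs])
        exact = exact_permutation_p(X, np.repeat([0, 1], 5))
        assert exact == pytest.approx(2 / 252)
        res = permutation_test(make_table(X_hc, X_ibs), ["f0", "f1", "f2"],
                               n_perm=1000, seed=1)
        se = np.sqrt(exact * (1 - exact) / 1000)
        assert abs(res.p_empirical - exact) <= 3 * se

    def test_monte_carlo_close_to_exact_enumeration(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        exact = exact_permutation_p(X, labels)
        res = permutation_test(make_table(X[:3], X[3:]), ["f0", "f1"],
                               n_perm=2000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(res.p_empirical - exact) <= 3 * se + 1e-12

    def test_deterministic_given_seed(self, normalized):
        feats = list(normalized.panel.region_columns)[:5]
        a = permutation_test(normalized, feats, n_perm=100, seed=42)
        b = permutation_test(normalized, feats, n_perm=100, seed=42)
        assert a.p_empirical == b.p_empirical
        np.testing.assert_array_equal(a.null_stats, b.null_stats)

    def test_add_one_smoothing_never_zero(self):
        rng = np.random.default_rng(2)
        X_hc = rng.normal(0, 1, size=(5, 2))
        X_ibs = rng.normal(50, 1, size=(5, 2))
        res = permutation_test(make_table(X_hc, X_ibs), ["f0", "f1"],
                               n_perm=100, seed=0, add_one=True)
        hits = int((res.null_stats >= res.observed_stat).sum())
        assert res.p_empirical == pytest.approx((1 + hits) / 101)
        assert res.p_empirical > 0

    def test_n_perm_guard(self, normalized):
        with pytest.raises(ValueError):
            permutation_test(normalized, ["Left Thalamus"], n_perm=0, seed=0)
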