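"""Univariate statistics: closed-form oracles and documented conventions."""

import numpy as np
import pytest
from scipy import stats as sps

from oenomet.io import MetaboliteTable, OenometError
from oenomet.stats import (
    anova_oneway,
    duncan_least_significant_ranges,
    duncan_letters,
    hierarchical_cluster,
    log10_transform,
    sample_correlation,
    ttest_two_group,
    zscore_rows,
)


class TestAnova:
    def test_identical_groups_convention(self):
        f, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert (f, p) == pytest.approx((0.0, 1.0))

    def test_constant_everything(self):
        assert anova_oneway([[5, 5], [5, 5]]) == (0.0, 1.0)

    def test_separation_dominates(self):
        _, p = anova_oneway([[0, 1e-8, -1e-8], [10, 10 + 1e-8, 10 - 1e-8]])
        assert p < 1e-6

    def test_matches_hand_computed_sum_of_squares(self):
        # groups {1,2,3},{2,3,4},{6,7,8}: SSB=42 (df 2), SSW=6 (df 6) → F=21
        f, p = anova_oneway([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert f == pytest.approx(21.0, rel=1e-10)
        assert p == pytest.approx(float(sps.f.sf(21.0, 2, 6)), rel=1e-10)


class TestTTest:
    def test_equal_data_p_one(self):
        assert ttest_two_group([1, 2, 3], [1, 2, 3]) == pytest.approx(
            1.0, abs=1e-12
        ) or ttest_two_group([1, 2, 3], [1, 2, 3]) == 1.0

    def test_degenerate_conventions(self):
        assert ttest_two_group([2, 2], [2, 2]) == 1.0
        assert ttest_two_group([0, 0], [5, 5]) == 0.0

    def test_huge_separation(self):
        x = [0, 1e-6, -1e-6]
        y = [5, 5 + 1e-6, 5 - 1e-6]
        assert ttest_two_group(x, y) < 1e-6

    def test_matches_textbook_formula(self):
        x = np.array([4.1, 5.0, 6.2])
        y = np.array([7.3, 8.1, 6.9])
        sp2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / 4
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        expect = 2 * sps.t.sf(abs(t), df=4)
        assert ttest_two_group(x, y) == pytest.approx(expect, rel=1e-12)


def _brute_force_duncan_share(groups, alpha=0.05):
    """Independent multiple-range decision: span i..j homogeneous iff its
    range <= LSR(span) or it sits inside a wider homogeneous span."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    order = np.argsort(means)
    sm = means[order]
    sse = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df = sum(len(g) for g in groups) - k
    mse = sse / df
    n_h = k / sum(1 / len(g) for g in groups)
    lsr = duncan_least_significant_ranges(k, mse, df, n_h, alpha)
    homo = {(i, i): True for i in range(k)}
    for span in range(k, 1, -1):
        for i in range(k - span + 1):
            j = i + span - 1
            inside = any(
                homo.get((a, b), False)
                for a in range(i + 1)
                for b in range(j, k)
                if (a, b) != (i, j) and (b - a) > (j - i)
            )
            homo[(i, j)] = inside or (sm[j] - sm[i]) <= lsr[span] + 1e-12
    share = np.zeros((k, k), bool)
    for i in range(k):
        for j in range(i, k):
            if homo.get((i, j), False):
                share[order[i] : order[j] + 1][:, order[i] : order[j] + 1] = True
    # a pair shares a letter iff some homogeneous span covers both
    pair_share = np.zeros((k, k), bool)
    for i in range(k):
        for j in range(k):
            pi, pj = np.where(order == i)[0][0], np.where(order == j)[0][0]
            lo, hi = min(pi, pj), max(pi, pj)
            pair_share[i, j] = any(
                homo.get((a, b), False)
                for a in range(lo + 1)
                for b in range(hi, k)
            )
    return pair_share


class TestDuncan:
    def test_single_group(self):
        out = duncan_letters([[1.0, 2.0, 3.0]])
        assert out[0].letters == "a"

    def test_fully_separated_groups_get_distinct_letters(self):
        # six groups ~20 pooled SDs apart: all-distinct lettering a..f,
        # the pattern of a well-separated colorimetry column
        rng = np.random.default_rng(0)
        groups = [20 * k + 0.1 * rng.standard_normal(3) for k in range(6)]
        out = duncan_letters(groups)
        assert sorted(s.letters for s in out) == list("abcdef")

    def test_identical_groups_share_a(self):
        out = duncan_letters([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert all(s.letters == "a" for s in out)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_letters_match_brute_force_range_decisions(self, seed):
        rng = np.random.default_rng(seed)
        k = 4
        groups = [rng.normal(loc=rng.uniform(0, 3), scale=1.0, size=4) for _ in range(k)]
        out = duncan_letters(groups)
        share = _brute_force_duncan_share(groups)
        for i in range(k):
            for j in range(k):
                got = bool(set(out[i].letters) & set(out[j].letters))
                assert got == bool(share[i, j]), (i, j, [s.letters for s in out])


class TestTransforms:
    def test_log10_of_powers_of_ten(self):
        t = MetaboliteTable(["m"], ["phenols"], np.array([[1.0, 10.0, 100.0]]))
        np.testing.assert_allclose(log10_transform(t), [[0, 1, 2]])

    def test_zscore_moments_and_constant_row(self):
        X = np.vstack([np.arange(6, dtype=float), np.full(6, 3.0)])
        Z = zscore_rows(X)
        assert abs(Z[0].mean()) < 1e-12
        assert Z[0].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert (Z[1] == 0).all()


class TestSampleCorrelation:
    def test_duplicate_and_anticorrelated_columns(self):
        x = np.array([[1.0, 1.0, 3.0], [2.0, 2.0, 2.0], [3.0, 3.0, 1.0]])
        r = sample_correlation(x)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_replicates_correlate_within_variety(self, small_bundle):
        table, samples, *_ = small_bundle
        logX = log10_transform(table)
        r = sample_correlation(logX)
        within, between = [], []
        for i, si in enumerate(samples):
            for j, sj in enumerate(samples):
                if j <= i or si.is_qc or sj.is_qc:
                    continue
                (within if si.variety == sj.variety else between).append(r[i, j])
        assert np.mean(within) > np.mean(between)
        assert np.mean(within) > 0.8  # platform-reproducibility threshold

    def test_needs_three_metabolites(self):
        with pytest.raises(OenometError):
            sample_correlation(np.ones((2, 4)))


class TestHierarchicalCluster:
    def test_average_linkage_heights_match_hand_merge(self):
        # colinear points 0,1,3: merge (0,1) at 1, then to 3 at mean(3,2)=2.5
        X = np.array([[0.0], [1.0], [3.0]])
        Z = hierarchical_cluster(X)
        np.testing.assert_allclose(sorted(Z[:, 2]), [1.0, 2.5])

    def test_top_split_separates_blobs(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        Z = hierarchical_cluster(X)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(two[:5])) == 1 and len(set(two[5:])) == 1
        assert set(two[:5]) != set(two[5:])

    def test_identical_points_merge_at_zero(self):
        Z = hierarchical_cluster(np.zeros((3, 2)))
        assert (Z[:, 2] == 0).all()

    def test_accepts_precomputed_distance_matrix(self):
        D = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        Z = hierarchical_cluster(D)
        assert Z[0, 2] == 1.0
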