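"""Group-comparison statistics: filtering, tests, imputation, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import euclidean

from metaproiq.stats_compare import (
    bh_qvalues,
    hcluster,
    knn_impute_pca,
    mannwhitney,
    presence_filter,
    ttest_bh,
    welch_ttest,
)


class TestPresenceFilter:
    @pytest.mark.parametrize("n_valid,kept", [(29, True), (28, False), (32, True)])
    def test_threshold_at_29_of_32(self, n_valid, kept):
        row = [1.0] * n_valid + [np.nan] * (32 - n_valid)
        m = pd.DataFrame([row], index=["r"], columns=[f"S{i}" for i in range(32)])
        out = presence_filter(m)
        assert ("r" in out.index) is kept

    def test_zero_fraction_is_identity(self):
        m = pd.DataFrame(np.full((5, 4), np.nan))
        assert presence_filter(m, min_frac=0.0).shape == m.shape


class TestBenjaminiHochberg:
    def test_hand_computation(self):
        """p = (.01,.02,.03,.04), m=4 -> q all 0.04."""
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_reference_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(3, 60)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_qvalues(p), ref, atol=1e-12)

    def test_monotone_on_sorted_pvalues(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q = bh_qvalues(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p)


class TestWelch:
    def test_matches_closed_form(self, rng):
        """Hand-computed Welch statistic + t survival function, 1e-9."""
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 12)))
            t, p = welch_ttest(a, b)
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            p_ref = 2 * sps.t.sf(abs(t_ref), df)
            assert t == pytest.approx(t_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_zero_variance_equal_means(self):
        assert welch_ttest(np.ones(4), np.ones(5))[1] == 1.0


class TestTtestBh:
    def matrix(self, rng, n_rows=40, shift_rows=(), shift=1.0):
        cols = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        base = rng.uniform(5, 7, size=(n_rows, 1)) + rng.normal(0, 0.05, size=(n_rows, 8))
        for r in shift_rows:
            base[r, :4] += shift
        m = pd.DataFrame(10.0**base, index=[f"g{r}" for r in range(n_rows)], columns=cols)
        groups = pd.Series({c: c[0] for c in cols})
        return m, groups

    def test_planted_shift_detected_with_sign(self, rng):
        m, groups = self.matrix(rng, shift_rows=(0, 1), shift=1.0)
        out = ttest_bh(m, groups, group_order=("A", "B"))
        assert bool(out.loc["g0", "significant"]) and out.loc["g0", "log10_fc"] > 0
        assert bool(out.loc["g1", "significant"])

    def test_null_rows_rarely_flagged(self, rng):
        flagged = 0
        for _ in range(10):
            m, groups = self.matrix(rng)
            out = ttest_bh(m, groups)
            flagged += int(out["significant"].sum())
        assert flagged <= 5  # BH nominal rate over 400 null rows

    def test_antisymmetric_under_group_swap(self, rng):
        m, groups = self.matrix(rng, shift_rows=(3,), shift=0.8)
        fwd = ttest_bh(m, groups, group_order=("A", "B"))
        rev = ttest_bh(m, groups, group_order=("B", "A"))
        np.testing.assert_allclose(fwd["log10_fc"], -rev["log10_fc"], atol=1e-12)

    def test_fold_change_tiers(self, rng):
        m, groups = self.matrix(rng, shift_rows=(0,), shift=2.5)
        out = ttest_bh(m, groups, group_order=("A", "B"))
        assert bool(out.loc["g0", "fold_change_2x"]) and bool(out.loc["g0", "fold_change_100x"])
        assert not bool(out.loc["g5", "fold_change_100x"])


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_groups_p_one(self):
        assert mannwhitney([1, 2, 3], [1, 2, 3])[1] == 1.0

    def test_exact_close_to_approximation_at_n8(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.8, 1, 8)
            _, p_exact = mannwhitney(a, b)
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert abs(p_exact - res.pvalue) <= 0.02

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([1, 2], [3, 4, 5])


class TestImputePca:
    def test_no_missing_is_identity(self, rng):
        m = pd.DataFrame(rng.uniform(0, 1, size=(10, 6)))
        scores, loadings = knn_impute_pca(m)
        assert scores.shape == (6, 2)

    def test_rank2_distances_reproduced(self, rng):
        """PCA scores of an exactly rank-2 matrix preserve sample distances."""
        u = rng.normal(size=(20, 2))
        v = rng.normal(size=(2, 6))
        m = pd.DataFrame(u @ v, columns=[f"S{i}" for i in range(6)])
        scores, _ = knn_impute_pca(m, n_components=2)
        centred = (m - m.mean(axis=1).to_numpy()[:, None]).T.to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            d_full = euclidean(centred[i], centred[j])
            d_pc = euclidean(scores.iloc[i], scores.iloc[j])
            assert d_pc == pytest.approx(d_full, rel=1e-9, abs=1e-9)

    def test_two_planted_clusters_separate_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        offsets = np.array([0.0] * 4 + [3.0] * 4)
        m = pd.DataFrame(
            rng.normal(0, 0.2, size=(30, 8)) + offsets[None, :],
            columns=[f"S{i}" for i in range(8)],
        )
        mask = rng.random(m.shape) < 0.1
        m = m.mask(mask)
        scores, _ = knn_impute_pca(m, k=1)
        labels = [0] * 4 + [1] * 4
        assert silhouette_score(scores[["PC1"]], labels) > 0.5


def brute_upgma(points):
    """Textbook UPGMA on Euclidean distances; returns merge heights."""
    clusters = {i: [i] for i in range(len(points))}
    dist = {
        (i, j): euclidean(points[i], points[j])
        for i, j in itertools.combinations(range(len(points)), 2)
    }

    def d(a, b):
        total = 0.0
        for x in clusters[a]:
            for y in clusters[b]:
                total += dist[(min(x, y), max(x, y))]
        return total / (len(clusters[a]) * len(clusters[b]))

    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        pairs = list(itertools.combinations(sorted(clusters), 2))
        a, b = min(pairs, key=lambda ab: d(*ab))
        heights.append(d(a, b))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestHcluster:
    def test_nearest_pair_merges_first(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=list("ABC"), columns=["x", "y"]
        )
        out = hcluster(m)
        link = out["row_linkage"]
        assert link[0, 2] == pytest.approx(1.0)
        assert set(link[0, :2].astype(int)) == {0, 1}

    def test_heights_non_decreasing(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 4)))
        link = hcluster(m)["row_linkage"]
        assert np.all(np.diff(link[:, 2]) >= -1e-12)

    def test_matches_brute_force_upgma(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(8, 3))
            m = pd.DataFrame(pts)
            link = hcluster(m)["row_linkage"]
            np.testing.assert_allclose(
                np.sort(link[:, 2]), np.sort(brute_upgma(pts)), atol=1e-9
            )

    def test_newick_contains_all_labels(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        nwk = hcluster(m)["row_newick"]
        assert nwk.endswith(";")
        for lab in "abcde":
            assert lab in nwk

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            hcluster(pd.DataFrame([[1.0, 2.0]]))
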