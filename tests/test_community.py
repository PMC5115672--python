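"""Distance-based tests against closed-form, exhaustive and library oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from soilfungnet import (
    DistanceMatrix,
    depth_trend_test,
    mantel_correlogram,
    permanova,
    permdisp,
    raup_crick,
    richness_per_sample,
)

from conftest import make_matrix, make_meta


class TestRichness:
    def test_counts_nonzero_otus(self):
        m = make_matrix([[0, 3, 0, 1], [0, 0, 0, 0]])
        r = richness_per_sample(m)
        assert r.tolist() == [2, 0]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 4, size=(15, 25))
        m = make_matrix(counts)
        r = richness_per_sample(m)
        for i in range(15):
            assert r.iloc[i] == sum(1 for c in counts[i] if c > 0)


class TestDepthTrend:
    def test_hand_computed_ols_decomposition(self):
        # x = 1..5, y = (5,4,4,2,1): Sxx=10, Sxy=-10 => slope -1,
        # SSreg = 10, SStot = 10.8, SSres = 0.8 => F = 10 / (0.8/3) = 37.5
        richness = pd.Series([5, 4, 4, 2, 1], index=[f"s{i}" for i in range(5)], dtype=float)
        depth = pd.Series([1, 2, 3, 4, 5], index=richness.index, dtype=float)
        res = depth_trend_test(richness, depth)
        assert res.statistic == pytest.approx(37.5, rel=1e-10)
        assert res.extra["df"] == (1, 3)

    def test_ten_depths_report_one_eight_df(self):
        rng = np.random.default_rng(0)
        depths = np.repeat(np.arange(10, dtype=float), 4)
        richness = pd.Series(100 - 3 * depths + rng.normal(0, 2, 40),
                             index=[f"s{i}" for i in range(40)])
        res = depth_trend_test(richness, pd.Series(depths, index=richness.index))
        assert res.extra["df"] == (1, 8)
        assert res.p_value < 0.05

    def test_perfect_linear_trend(self):
        richness = pd.Series(np.arange(10, 0, -1, dtype=float),
                             index=[f"s{i}" for i in range(10)])
        depth = pd.Series(np.arange(10, dtype=float), index=richness.index)
        res = depth_trend_test(richness, depth)
        assert res.statistic > 1e6 or math.isinf(res.statistic)
        assert res.p_value < 1e-6

    def test_constant_richness(self):
        richness = pd.Series([7.0] * 6, index=[f"s{i}" for i in range(6)])
        depth = pd.Series(np.arange(6, dtype=float), index=richness.index)
        res = depth_trend_test(richness, depth)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_too_few_depths_rejected(self):
        richness = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="depth classes"):
            depth_trend_test(richness, pd.Series([0.0, 1.0], index=richness.index))


def _exact_raup_crick(presence: np.ndarray, i: int, j: int) -> float:
    """Exhaustive-enumeration oracle for the occupancy-weighted null.

    Enumerates every ordered without-replacement draw for both samples
    and accumulates exact subset probabilities, then compares the null
    shared-OTU count with the observed one.
    """
    w = presence.sum(axis=0).astype(float)
    pool = np.where(w > 0)[0]

    def subset_probs(r: int) -> dict[frozenset, float]:
        probs: dict[frozenset, float] = {}
        for seq in itertools.permutations(pool, r):
            p = 1.0
            rem = w[pool].sum()
            for otu in seq:
                p *= w[otu] / rem
                rem -= w[otu]
            key = frozenset(seq)
            probs[key] = probs.get(key, 0.0) + p
        return probs

    ri, rj = int(presence[i].sum()), int(presence[j].sum())
    obs = int((presence[i] & presence[j]).sum())
    pi, pj = subset_probs(ri), subset_probs(rj)
    p_gt = p_eq = 0.0
    for a, pa in pi.items():
        for b, pb in pj.items():
            shared = len(a & b)
            if shared > obs:
                p_gt += pa * pb
            elif shared == obs:
                p_eq += pa * pb
    return p_gt + 0.5 * p_eq


class TestRaupCrick:
    def test_identical_rich_samples_near_zero(self):
        counts = np.zeros((4, 40), dtype=int)
        counts[0, :20] = 1
        counts[1, :20] = 1
        counts[2, 15:35] = 1
        counts[3, 5:25] = 1
        d = raup_crick(make_matrix(counts), n_null=999, seed=1)
        assert d.to_frame().iloc[0, 1] < 0.05

    def test_disjoint_samples_near_one(self):
        counts = np.zeros((4, 30), dtype=int)
        counts[0, :15] = 1
        counts[1, 15:] = 1
        counts[2, ::2] = 1
        counts[3, 1::2] = 1
        d = raup_crick(make_matrix(counts), n_null=999, seed=1)
        assert d.to_frame().iloc[0, 1] > 0.95

    def test_exhaustive_enumeration_oracle(self):
        # 4 samples over a 6-OTU pool, small enough for exact enumeration
        presence = np.array(
            [
                [1, 1, 0, 1, 0, 0],
                [1, 0, 1, 0, 1, 0],
                [0, 1, 1, 0, 0, 1],
                [1, 1, 1, 1, 1, 1],
            ],
            dtype=bool,
        )
        m = make_matrix(presence.astype(int))
        d = raup_crick(m, n_null=6000, seed=3).to_frame().to_numpy()
        for i, j in itertools.combinations(range(4), 2):
            exact = _exact_raup_crick(presence, i, j)
            se = math.sqrt(max(exact * (1 - exact), 0.01) / 6000)
            assert abs(d[i, j] - exact) < 4 * se + 1e-9, (i, j, d[i, j], exact)

    def test_zero_richness_sample_gets_half(self):
        counts = np.array([[1, 1, 0], [0, 0, 0], [0, 1, 1]])
        d = raup_crick(make_matrix(counts), n_null=99, seed=0).to_frame()
        assert d.iloc[0, 1] == 0.5 and d.iloc[1, 2] == 0.5

    def test_otu_column_order_invariance(self):
        rng = np.random.default_rng(9)
        counts = (rng.random((6, 20)) < 0.4).astype(int)
        m1 = make_matrix(counts)
        perm = rng.permutation(20)
        m2 = make_matrix(counts[:, perm])
        d1 = raup_crick(m1, n_null=499, seed=5).data
        d2 = raup_crick(m2, n_null=499, seed=5).data
        # same null law either way; estimates agree within Monte-Carlo error
        assert np.abs(d1 - d2).max() < 0.08

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            raup_crick(make_matrix(np.zeros((0, 3), dtype=int)), n_null=9, seed=0)


def _brute_force_pseudo_f(d: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from raw sums of squared distances (categorical)."""
    n = len(groups)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(np.unique(groups))
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _toy(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.5, 1, (3, 2))])
        d = squareform(pdist(pts))
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        return DistanceMatrix(d, [f"s{i}" for i in range(6)], "euclidean"), groups

    def test_six_sample_brute_force_and_exhaustive_p(self):
        dm, groups = self._toy()
        res = permanova(dm, groups, n_perm=20000, seed=4, coding="categorical")
        f_oracle = _brute_force_pseudo_f(dm.data, groups)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        # exhaustive relabelling p over all 6! orderings
        f_all = [
            _brute_force_pseudo_f(dm.data, np.asarray(g))
            for g in itertools.permutations(groups)
        ]
        p_exact = sum(f >= res.statistic - 1e-12 for f in f_all) / len(f_all)
        assert abs(res.p_value - p_exact) < 3 * math.sqrt(p_exact * (1 - p_exact) / 20000) + 1e-4

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        pts = rng.random((12, 4))
        pts[6:] += 0.8
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(12)]
        groups = ["A"] * 6 + ["B"] * 6
        ours = permanova(DistanceMatrix(d, ids, "e"), np.array(groups),
                         n_perm=99, seed=0, coding="categorical")
        theirs = skbio_stats.permanova(skbio_stats.DistanceMatrix(d, ids), groups,
                                       permutations=99)
        assert ours.statistic == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_numeric_predictor_has_model_df_one(self):
        dm, _ = self._toy()
        res = permanova(dm, np.arange(6, dtype=float), n_perm=99, seed=1)
        assert res.extra["df"][0] == 1

    def test_duplicated_group_gives_trivial_f(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 5))
        d = squareform(pdist(np.vstack([x, x])))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(8)], "e")
        res = permanova(dm, np.array(["A"] * 4 + ["B"] * 4), n_perm=199, seed=1,
                        coding="categorical")
        assert res.statistic < 1e-6
        assert res.p_value > 0.9

    def test_sample_reordering_invariance(self):
        dm, groups = self._toy()
        perm = np.array([3, 1, 5, 0, 4, 2])
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                             [dm.ids[i] for i in perm], "e")
        r1 = permanova(dm, groups, n_perm=9, seed=0, coding="categorical")
        r2 = permanova(dm2, groups[perm], n_perm=9, seed=0, coding="categorical")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-10)

    def test_constant_predictor_rejected(self):
        dm, _ = self._toy()
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, np.ones(6), n_perm=9, seed=0)

    def test_add_one_rule_p_never_zero(self):
        dm, groups = self._toy()
        res = permanova(dm, groups, n_perm=50, seed=2, coding="categorical")
        assert res.p_value >= 1 / 51


class TestPermdisp:
    def test_identical_geometry_gives_zero_f(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 3))
        pts = np.vstack([a, a + 50.0])
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(16)], "e")
        res = permdisp(dm, np.array(["A"] * 8 + ["B"] * 8), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        pts = np.vstack([a, 3.0 * a + 50.0])
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(20)], "e")
        res = permdisp(dm, np.array(["A"] * 10 + ["B"] * 10), n_perm=499, seed=0)
        assert res.statistic > 10
        assert res.p_value < 0.05
        disp = res.extra["group_dispersions"]
        assert disp["B"] == pytest.approx(3 * disp["A"], rel=0.05)

    def test_df_is_group_count_minus_one(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 4))
        d = squareform(pdist(pts))
        labels = np.repeat([f"g{k}" for k in range(10)], 3)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(30)], "e")
        res = permdisp(dm, labels, n_perm=19, seed=0)
        assert res.extra["df"] == (9, 20)

    def test_singleton_group_excluded(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        labels = np.array(["A"] * 4 + ["B"] * 4 + ["C"])
        dm = DistanceMatrix(d, [f"s{i}" for i in range(9)], "e")
        res = permdisp(dm, labels, n_perm=19, seed=0)
        assert res.extra["df"] == (1, 6)


class TestMantelCorrelogram:
    def test_gradient_first_class_negative_significant(self):
        # community dissimilarity proportional to spatial separation
        n = 24
        pos = np.arange(n, dtype=float)
        d = np.abs(pos[:, None] - pos[None, :]) / n
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(n)], "gradient")
        results = mantel_correlogram(dm, pos, n_perm=499, seed=1)
        first = results[0]
        assert first.statistic < 0
        assert first.p_value < 0.05

    def test_null_familywise_error_controlled(self):
        # progressive correction controls the familywise rate only
        # approximately (true rate ~0.10 at nominal 0.05 here); the test
        # guards against gross miscalibration of the per-class p-values
        rng = np.random.default_rng(7)
        false_hits = 0
        runs = 100
        for run in range(runs):
            pts = rng.normal(size=(12, 5))
            d = squareform(pdist(pts))
            pos = rng.permutation(12).astype(float)
            dm = DistanceMatrix(d, [f"s{i}" for i in range(12)], "e")
            results = mantel_correlogram(dm, pos, n_perm=99, seed=run)
            if any(r.extra["p_corrected"] < 0.05 for r in results):
                false_hits += 1
        assert false_hits / runs <= 0.17

    def test_sparse_class_omitted(self):
        pos = np.array([0.0, 0.1, 0.2, 10.0])
        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.random((4, 3))))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(4)], "e")
        results = mantel_correlogram(dm, pos, n_classes=10, n_perm=49, seed=0)
        assert all(r.extra["n_pairs"] >= 2 for r in results)

    def test_tiny_input_rejected(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ["a", "b"], "e")
        with pytest.raises(ValueError):
            mantel_correlogram(dm, np.array([0.0, 1.0]), n_perm=9, seed=0)


class TestDistanceMatrixContract:
    def test_asymmetry_rejected(self):
        bad = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(bad, ["a", "b"], "x")

    def test_nonzero_diagonal_rejected(self):
        bad = np.array([[0.1, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(bad, ["a", "b"], "x")
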