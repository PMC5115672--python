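"""Filtering/normalisation chain: boundaries, oracles and monotonicity."""

import numpy as np
import pytest
from scipy import stats

from soilfungnet import (
    SyntheticConfig,
    filter_low_count_otus,
    generate_dataset,
    merge_replicates,
    prevalence_filter,
    rarefy,
    remove_control_otus,
)

from conftest import make_matrix, make_meta


class TestMergeReplicates:
    def test_replicate_counts_sum(self):
        samples = [make_meta("p1_r1", "d1", 2.0, 0.0, 1), make_meta("p1_r2", "d1", 2.0, 0.0, 2)]
        m = make_matrix([[3, 0], [4, 2]], sample_ids=["p1_r1", "p1_r2"], samples=samples)
        merged, _ = merge_replicates(m)
        assert merged.n_samples == 1
        assert merged.counts.iloc[0].tolist() == [7, 2]

    def test_single_replicate_passes_with_note(self):
        samples = [
            make_meta("p1_r1", "d1", 2.0, 0.0, 1),
            make_meta("p1_r2", "d1", 2.0, 0.0, 2),
            make_meta("p2_r1", "d1", 2.0, 0.2, 1),  # lone replicate
        ]
        m = make_matrix([[3, 0], [4, 2], [5, 5]],
                        sample_ids=["p1_r1", "p1_r2", "p2_r1"], samples=samples)
        merged, report = merge_replicates(m)
        assert merged.n_samples == 2
        assert merged.counts.loc["p2"].tolist() == [5, 5]
        assert any("expected" in n for n in report.notes)

    def test_controls_not_merged(self):
        samples = [
            make_meta("p1_r1", "d1", 2.0, 0.0, 1),
            make_meta("p1_r2", "d1", 2.0, 0.0, 2),
            make_meta("neg1", "none", 0.0, -1.0, 1, control=True),
        ]
        m = make_matrix([[1, 1], [1, 1], [9, 0]],
                        sample_ids=["p1_r1", "p1_r2", "neg1"], samples=samples)
        merged, _ = merge_replicates(m)
        assert "neg1" in merged.sample_ids
        assert merged.counts.loc["neg1"].tolist() == [9, 0]

    def test_study_shaped_halving(self):
        cfg = SyntheticConfig(n_depths=4, n_positions_per_depth=25, n_replicates=2,
                              n_otus=40, seed=21)
        m, _, _ = generate_dataset(cfg)
        merged, _ = merge_replicates(m)
        assert m.n_samples == 200 and merged.n_samples == 100
        # merged totals equal summed replicate totals
        assert merged.counts.to_numpy().sum() == m.counts.to_numpy().sum()


class TestLowCountFilter:
    @pytest.mark.parametrize("total,kept", [(9, False), (10, True), (11, True)])
    def test_less_than_ten_boundary(self, total, kept):
        m = make_matrix(np.array([[total, 20], [0, 20]]))
        out, report = filter_low_count_otus(m, min_total=10)
        assert ("OTU_01" in out.otu_ids) is kept
        assert ("OTU_01" in report.dropped_otus) is (not kept)

    def test_all_zero_matrix_loses_all_otus(self):
        out, _ = filter_low_count_otus(make_matrix(np.zeros((3, 4), dtype=int)))
        assert out.n_otus == 0 and out.n_samples == 3


class TestControlRemoval:
    def test_contaminated_otus_removed_everywhere(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 50, size=(8, 30))
        samples = [make_meta(f"s{i+1}", "d1", 0.0, float(i)) for i in range(6)]
        samples += [make_meta(f"neg{i+1}", "none", 0.0, -1.0, control=True) for i in range(2)]
        # controls are clean except for 10 known OTUs
        counts[6:, :] = 0
        contaminated = rng.choice(30, size=10, replace=False)
        counts[6, contaminated[:5]] = 3
        counts[7, contaminated[5:]] = 1
        m = make_matrix(counts, sample_ids=[s.sample_id for s in samples], samples=samples)
        out, report = remove_control_otus(m)
        expected_dropped = {f"OTU_{k+1:02d}" for k in contaminated}
        assert set(report.dropped_otus) == expected_dropped
        assert out.n_otus == 20 and out.n_samples == 6
        assert not any(s.is_negative_control for s in out.samples)

    def test_no_controls_is_noop(self):
        m = make_matrix([[1, 2]], samples=[make_meta("s1")])
        out, report = remove_control_otus(m)
        assert out.counts.equals(m.counts)
        assert any("no-op" in n for n in report.notes)


class TestRarefy:
    def test_exact_total_returned_unchanged(self):
        m = make_matrix([[600, 400]])
        out, _ = rarefy(m, depth=1000, seed=0)
        assert out.counts.iloc[0].tolist() == [600, 400]

    def test_row_sums_exact_and_cellwise_bounded(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 60, size=(6, 50))
        counts[0] *= 3  # ensure some rows exceed the depth
        m = make_matrix(counts)
        out, report = rarefy(m, depth=1000, seed=1)
        kept = out.sample_ids
        assert (out.counts.sum(axis=1) == 1000).all()
        assert (out.counts.to_numpy() <=
                m.counts.loc[kept, out.otu_ids].to_numpy()).all()
        dropped = set(m.sample_ids) - set(kept)
        assert dropped == {s for s in m.sample_ids if m.counts.loc[s].sum() < 1000}

    def test_shallow_samples_dropped(self):
        m = make_matrix([[400, 300], [900, 200]])
        out, report = rarefy(m, depth=1000, seed=0)
        assert out.n_samples == 1 and report.dropped_samples == ["s1"]

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            rarefy(make_matrix([[5]]), depth=0, seed=0)

    def test_hypergeometric_mean_oracle(self):
        # one OTU with k of N reads: rarefied mean ~ depth * k / N
        row = np.array([[300, 500, 1200, 1000]])
        m = make_matrix(row)
        depth, N, k = 1000, row.sum(), 1200
        draws = []
        for seed in range(400):
            out, _ = rarefy(m, depth=depth, seed=seed)
            draws.append(out.counts.loc["s1", "OTU_03"])
        mean_expected = depth * k / N
        se = stats.hypergeom(N, k, depth).std() / np.sqrt(len(draws))
        assert abs(np.mean(draws) - mean_expected) < 3 * se

    def test_determinism_under_seed(self):
        m = make_matrix(np.random.default_rng(5).integers(0, 80, size=(4, 40)))
        a, _ = rarefy(m, depth=500, seed=7)
        b, _ = rarefy(m, depth=500, seed=7)
        assert a.counts.equals(b.counts)


class TestPrevalenceFilter:
    def _matrix(self, occupancy_counts, n_positions=30):
        """One depth with a chosen per-OTU occupancy pattern."""
        rng = np.random.default_rng(17)
        j = len(occupancy_counts)
        counts = np.zeros((n_positions, j), dtype=int)
        for col, occ in enumerate(occupancy_counts):
            rows = rng.choice(n_positions, size=occ, replace=False)
            counts[rows, col] = rng.integers(1, 9, size=occ)
        samples = [make_meta(f"s{i+1}", "d1", 0.0, float(i)) for i in range(n_positions)]
        return make_matrix(counts, samples=samples)

    def test_one_third_boundary(self):
        m = self._matrix([10, 9, 30])
        out = prevalence_filter(m, "d1")
        assert out.otu_ids == ["OTU_01", "OTU_03"]  # 10/30 kept, 9/30 dropped

    def test_exact_fraction_with_awkward_position_count(self):
        # 47 positions: threshold is 47/3 = 15.67, so 16 occurrences needed
        m = self._matrix([16, 15], n_positions=47)
        out = prevalence_filter(m, "d1")
        assert out.otu_ids == ["OTU_01"]

    def test_brute_force_occupancy_oracle(self):
        rng = np.random.default_rng(23)
        counts = (rng.random((20, 40)) < 0.3).astype(int) * rng.integers(1, 5, size=(20, 40))
        samples = [make_meta(f"s{i+1}", "d1", 0.0, float(i)) for i in range(20)]
        m = make_matrix(counts, samples=samples)
        out = prevalence_filter(m, "d1")
        expected = [
            f"OTU_{k+1:02d}" for k in range(40)
            if (counts[:, k] > 0).sum() / 20 >= 1 / 3 - 1e-12
        ]
        assert out.otu_ids == expected

    def test_unknown_depth_rejected(self):
        m = self._matrix([5])
        with pytest.raises(ValueError, match="depth class"):
            prevalence_filter(m, "no-such-depth")


class TestChainProperties:
    def test_chain_monotonic_and_study_retention(self):
        cfg = SyntheticConfig(n_depths=5, n_positions_per_depth=20, n_replicates=2,
                              n_otus=150, seed=31)
        m, _, _ = generate_dataset(cfg)
        merged, _ = merge_replicates(m)
        filtered, _ = filter_low_count_otus(merged)
        assert (filtered.counts.to_numpy() <=
                merged.counts[filtered.otu_ids].to_numpy()).all()
        cleaned, _ = remove_control_otus(filtered)
        rarefied, _ = rarefy(cleaned, 1000, seed=1)
        assert (rarefied.counts.to_numpy() <=
                cleaned.counts.loc[rarefied.sample_ids, rarefied.otu_ids].to_numpy()).all()
        # with the default 40% dropout the retained share matches the design
        retained = rarefied.n_samples / merged.n_samples
        assert 0.5 <= retained <= 0.7
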