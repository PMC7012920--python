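"""SNP-index, co-segregation filter, window deltas, envelopes, intervals."""

import numpy as np
import pandas as pd
import pytest

from poolmap import popsim, qtlseq
from poolmap.qtlseq import (
    compute_snp_index,
    confidence_envelope,
    filter_cosegregating,
    find_candidate_interval,
    partition_reference_sets,
    window_deltas,
)

from conftest import fixed_pool_depths


def depth_table(rows):
    """rows: (chrom, pos, pool, count_a, count_b)"""
    return pd.DataFrame(rows, columns=["chrom", "pos", "pool", "count_a", "count_b"])


def index_oracle(depths, reference_parent, min_depth):
    """Brute-force per-row SNP-index for cross-checking."""
    out = []
    for row in depths.itertuples(index=False):
        total = row.count_a + row.count_b
        ref = row.count_a if reference_parent == "A" else row.count_b
        out.append(ref / total if total >= min_depth else np.nan)
    return np.array(out)


class TestComputeSnpIndex:
    @pytest.mark.parametrize(
        "ca,cb,ref,expected",
        [(12, 18, "A", 0.4), (30, 0, "A", 1.0), (12, 18, "B", 0.6), (0, 30, "A", 0.0)],
    )
    def test_count_ratio(self, ca, cb, ref, expected):
        tbl = depth_table([("c1", 100, "high", ca, cb)])
        idx = compute_snp_index(tbl, ref, min_depth=5)
        assert idx["snp_index"].iloc[0] == pytest.approx(expected)

    def test_low_depth_flagged_missing(self):
        tbl = depth_table([("c1", 100, "high", 2, 1), ("c1", 200, "high", 3, 2)])
        idx = compute_snp_index(tbl, "A", min_depth=5)
        assert np.isnan(idx["snp_index"].iloc[0])
        assert idx["snp_index"].iloc[1] == pytest.approx(0.6)

    def test_unknown_reference_errors(self):
        with pytest.raises(ValueError, match="reference parent"):
            compute_snp_index(depth_table([("c1", 1, "high", 1, 1)]), "Z")

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        n = 1000
        tbl = depth_table(
            [
                ("c1", p, pool, int(a), int(b))
                for p, pool, a, b in zip(
                    np.repeat(np.arange(1, n + 1), 2),
                    ["high", "low"] * n,
                    rng.integers(0, 40, 2 * n),
                    rng.integers(0, 40, 2 * n),
                )
            ]
        )
        for ref in ("A", "B"):
            got = compute_snp_index(tbl, ref, min_depth=5)["snp_index"].to_numpy()
            exp = index_oracle(tbl, ref, 5)
            np.testing.assert_allclose(got, exp, atol=1e-10)


class TestFilterCosegregating:
    def make_idx(self, pairs):
        """pairs: list of (idx_high, idx_low) at successive positions."""
        rows = []
        for i, (h, l) in enumerate(pairs):
            rows.append(("c1", (i + 1) * 100, "high", int(h * 30), 30 - int(h * 30)))
            rows.append(("c1", (i + 1) * 100, "low", int(l * 30), 30 - int(l * 30)))
        return compute_snp_index(depth_table(rows), "A", min_depth=1)

    def test_same_side_extreme_in_both_pools_removed(self):
        idx = self.make_idx([(0.20, 0.25)])
        assert len(filter_cosegregating(idx, 0.3, 0.7)) == 0

    def test_single_pool_extreme_retained(self):
        idx = self.make_idx([(0.95, 0.50)])
        assert len(filter_cosegregating(idx, 0.3, 0.7)) == 2

    def test_mid_range_markers_unchanged(self):
        idx = self.make_idx([(0.4, 0.6), (0.3, 0.7), (0.5, 0.5)])
        out = filter_cosegregating(idx, 0.3, 0.7)
        pd.testing.assert_frame_equal(out, idx)

    def test_either_pool_mode_is_stricter(self):
        idx = self.make_idx([(0.95, 0.50), (0.5, 0.5)])
        assert len(filter_cosegregating(idx, mode="either-pool")) == 2
        assert len(filter_cosegregating(idx, mode="keep-extreme")) == 4

    def test_invalid_bounds(self):
        idx = self.make_idx([(0.5, 0.5)])
        with pytest.raises(ValueError, match="low"):
            filter_cosegregating(idx, 0.7, 0.3)


class TestWindowDeltas:
    def test_window_mean_is_arithmetic_mean(self):
        # three markers with per-marker delta_ref_a 0.2, 0.4, 0.6
        rows = []
        for pos, (h, l) in zip(
            (100, 200, 300), [(0.6, 0.4), (0.7, 0.3), (0.8, 0.2)]
        ):
            rows.append(("c1", pos, "high", int(h * 10), 10 - int(h * 10)))
            rows.append(("c1", pos, "low", int(l * 10), 10 - int(l * 10)))
        idx = compute_snp_index(depth_table(rows), "A", min_depth=1)
        w = window_deltas(idx, idx.copy(), window=1000, step=1000,
                          chrom_lengths={"c1": 1000})
        assert w["delta_ref_a"].iloc[0] == pytest.approx(0.4)

    def test_matches_bruteforce_window_oracle(self, small_marker_set):
        """Window means agree with a per-window loop over raw indices."""
        rng = np.random.default_rng(11)
        ms = small_marker_set
        rows = []
        for row in ms.markers.itertuples(index=False):
            for pool in ("high", "low"):
                a, b = rng.integers(0, 40), rng.integers(0, 40)
                rows.append((row.chrom, row.pos, pool, int(a), int(b)))
        idx = compute_snp_index(depth_table(rows), "A", min_depth=5)
        w = window_deltas(idx, idx.copy(), window=200_000, step=50_000,
                          chrom_lengths=ms.chrom_lengths())
        for win in w.sample(25, random_state=0).itertuples(index=False):
            sub = idx[
                (idx["chrom"] == win.chrom)
                & idx["pos"].between(win.start, win.end)
                & idx["snp_index"].notna()
            ]
            for pool, col in (("high", win.mean_high_ref_a), ("low", win.mean_low_ref_a)):
                vals = sub.loc[sub["pool"] == pool, "snp_index"]
                if len(vals) == 0:
                    assert np.isnan(col)
                else:
                    assert col == pytest.approx(vals.mean(), abs=1e-10)

    def test_fixed_opposite_pools_attain_plus_two(self, small_marker_set):
        depths = fixed_pool_depths(small_marker_set, high_geno=0, low_geno=2)
        idx_a = compute_snp_index(depths, "A")
        idx_b = compute_snp_index(depths, "B")
        w = window_deltas(idx_a, idx_b, chrom_lengths=small_marker_set.chrom_lengths())
        valid = w.dropna(subset=["delta_combined"])
        assert (valid["delta_combined"] == 2.0).all()
        assert (valid["delta_ref_a"] == 1.0).all()
        assert (valid["delta_ref_b"] == -1.0).all()

    def test_combined_equals_twice_ref_a_for_shared_markers(self, desk_population):
        high, low = popsim.select_pools(
            desk_population.phenotypes, 0.0, 0.0, 20, seed=21
        )
        dh = popsim.simulate_pool_reads(desk_population, high, 30, 0.0, seed=22)
        dl = popsim.simulate_pool_reads(desk_population, low, 30, 0.0, seed=23)
        depths = pd.concat([dh, dl], ignore_index=True)
        idx_a = compute_snp_index(depths, "A")
        idx_b = compute_snp_index(depths, "B")
        w = window_deltas(idx_a, idx_b)
        valid = w.dropna(subset=["delta_combined"])
        np.testing.assert_allclose(
            valid["delta_combined"], 2 * valid["delta_ref_a"], atol=1e-10
        )

    def test_delta_bounds(self, desk_population):
        high, low = popsim.select_pools(desk_population.phenotypes, 0.0, 0.0, 15, seed=31)
        dh = popsim.simulate_pool_reads(desk_population, high, 30, 0.01, seed=32)
        dl = popsim.simulate_pool_reads(desk_population, low, 30, 0.01, seed=33)
        idx_a = compute_snp_index(pd.concat([dh, dl]), "A")
        idx_b = compute_snp_index(pd.concat([dh, dl]), "B")
        w = window_deltas(idx_a, idx_b).dropna(subset=["delta_combined"])
        assert (w["delta_ref_a"].abs() <= 1 + 1e-12).all()
        assert (w["delta_ref_b"].abs() <= 1 + 1e-12).all()
        assert (w["delta_combined"].abs() <= 2 + 1e-12).all()

    def test_empty_input_gives_empty_frame(self):
        idx = compute_snp_index(depth_table([]), "A")
        assert len(window_deltas(idx, idx.copy())) == 0

    def test_partial_tail_window_flagged(self):
        rows = [("c1", 50, "high", 10, 10), ("c1", 50, "low", 10, 10)]
        idx = compute_snp_index(depth_table(rows), "A")
        w = window_deltas(idx, idx.copy(), window=40, step=20,
                          chrom_lengths={"c1": 70})
        assert w["partial"].iloc[-1]
        assert w["end"].iloc[-1] == 70

    def test_invalid_window_step(self):
        idx = compute_snp_index(depth_table([("c1", 1, "high", 5, 5)]), "A")
        with pytest.raises(ValueError):
            window_deltas(idx, idx, window=10, step=20)

    def test_partition_reference_sets_disjoint(self):
        rows = [("c1", p, pool, 10, 10) for p in range(1, 101) for pool in ("high", "low")]
        idx = compute_snp_index(depth_table(rows), "A")
        a, b = partition_reference_sets(idx, idx.copy(), seed=1)
        pa = set(a["pos"])
        pb = set(b["pos"])
        assert pa.isdisjoint(pb) and pa | pb == set(range(1, 101))


class TestConfidenceEnvelope:
    @staticmethod
    def uniform_windows(n=3, n_snps=30, depth=30.0):
        return pd.DataFrame(
            {
                "chrom": "c1",
                "start": 1,
                "end": 200_000,
                "n_snps_ref_a": n_snps,
                "n_snps_ref_b": n_snps,
                "mean_depth": depth,
            },
            index=range(n),
        )

    def test_high_depth_large_pool_collapses_to_zero(self):
        w = self.uniform_windows(n=1, depth=10_000)
        env = confidence_envelope(w, pool_size=10_000, n_sims=200, levels=(0.95,), seed=1)
        assert env["ci_high_0.95"].iloc[0] - env["ci_low_0.95"].iloc[0] < 0.05

    def test_halving_depth_widens_envelope(self):
        env30 = confidence_envelope(
            self.uniform_windows(depth=30), 25, 1000, (0.95,), seed=2
        )
        env15 = confidence_envelope(
            self.uniform_windows(depth=15), 25, 1000, (0.95,), seed=2
        )
        width30 = (env30["ci_high_0.95"] - env30["ci_low_0.95"]).median()
        width15 = (env15["ci_high_0.95"] - env15["ci_low_0.95"]).median()
        assert width15 > width30

    def test_zero_depth_window_missing_envelope(self):
        w = self.uniform_windows(n=2)
        w.loc[1, "mean_depth"] = np.nan
        w.loc[1, "n_snps_ref_a"] = 0
        env = confidence_envelope(w, 25, 100, (0.95,), seed=3)
        assert np.isnan(env["ci_low_0.95"].iloc[1])
        assert np.isfinite(env["ci_low_0.95"].iloc[0])

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError, match="n_sims"):
            confidence_envelope(self.uniform_windows(), 25, 50, (0.95,), seed=0)


def make_windows(starts, deltas, window=200_000, chrom="A07"):
    starts = np.asarray(starts)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window - 1,
            "delta_combined": deltas,
        }
    )


class TestFindCandidateInterval:
    def test_five_window_intersection_is_120kb(self):
        starts = np.arange(25_000_001, 25_400_001, 20_000)
        deltas = np.where(
            (starts >= 25_100_001) & (starts <= 25_180_001), 1.5, 0.2
        )
        iv = find_candidate_interval(make_windows(starts, deltas), k=5)
        assert iv.raw_start == 25_180_001
        assert iv.raw_end == 25_300_000
        assert iv.raw_length == 120_000

    def test_k1_returns_peak_window(self):
        starts = [1, 20_001, 40_001]
        iv = find_candidate_interval(make_windows(starts, [0.1, 0.9, 0.2]), k=1)
        assert (iv.raw_start, iv.raw_end) == (20_001, 220_000)

    def test_tie_broken_leftmost(self):
        starts = np.arange(1, 200_002, 20_000)
        deltas = np.full(len(starts), 1.0)
        iv = find_candidate_interval(make_windows(starts, deltas), k=3)
        assert iv.raw_start == 40_001

    def test_snp_refinement_inward(self):
        """Bounds snap to the outermost retained SNPs inside the raw
        intersection, reproducing an interval slightly shorter than the
        window-arithmetic 120 kb."""
        starts = np.arange(25_032_001, 25_132_001, 20_000)  # exactly 5 windows
        w = make_windows(starts, [1.0] * 5)
        snps = pd.DataFrame(
            {
                "chrom": "A07",
                "pos": [25_100_000, 25_112_903, 25_150_000, 25_230_669, 25_240_000],
            }
        )
        iv = find_candidate_interval(w, k=5, snp_positions=snps)
        assert (iv.raw_start, iv.raw_end) == (25_112_001, 25_232_000)
        assert iv.raw_length == 120_000
        assert (iv.refined_start, iv.refined_end) == (25_112_903, 25_230_669)
        assert iv.refined_length == 117_767

    def test_snp_refinement_outward(self):
        starts = np.arange(25_032_001, 25_132_001, 20_000)
        w = make_windows(starts, [1.0] * 5)
        snps = pd.DataFrame({"chrom": "A07", "pos": [25_100_000, 25_240_000]})
        iv = find_candidate_interval(w, k=5, snp_positions=snps, refine="outward")
        assert (iv.refined_start, iv.refined_end) == (25_100_000, 25_240_000)

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="consecutive"):
            find_candidate_interval(make_windows([1, 20_001], [1.0, 1.0]), k=5)

    def test_non_adjacent_windows_not_a_run(self):
        # a gap in the grid breaks the run of high windows
        starts = [1, 20_001, 60_001, 80_001, 100_001]
        w = make_windows(starts, [1.0] * 5)
        with pytest.raises(ValueError):
            find_candidate_interval(w, k=5)

    def test_overlap_with_gene_fixture(self):
        """The refined A07 interval contains the packaged negative-regulator
        gene span used by the candidate stage."""
        from poolmap import candidates as cand

        iv = qtlseq.CandidateInterval(
            "A07", 25_112_001, 25_232_000, 25_112_903, 25_230_669, 1.9
        )
        pathway = cand.packaged_pathway_table()
        annotation = [
            cand.GeneRecord(r["gene_id"], r["chrom"], int(r["start"]), int(r["end"]),
                            name=r["name"])
            for _, r in pathway.iterrows()
        ]
        hits = cand.genes_in_interval(iv, annotation, pathway=pathway)
        assert [g.name for g in hits] == ["BrMYBL2.1"]
        assert hits[0].pathway_role == "negative_regulator"
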