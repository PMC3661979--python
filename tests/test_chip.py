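"""ChIP downstream operations, each checked against a brute-force oracle."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from conftest import make_peaks, make_reads
from pluriexit.chip import (
    AssocConfig,
    association_score,
    association_table,
    bound_genes,
    build_bin_matrix,
    cluster_profiles,
    dedup_reads,
    filter_peaks,
    nearest_factor_distance,
    peak_stats,
    rank_enrichment,
    read_density,
    subsample_equal,
)

read_strategy = st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 10_000), st.sampled_from(["+", "-"])),
    min_size=0,
    max_size=60,
)


class TestDedup:
    def test_example_triplet(self):
        reads = make_reads([("chr1", 100, "+"), ("chr1", 100, "+"), ("chr1", 100, "-")])
        assert len(dedup_reads(reads)) == 2

    def test_unique_set_unchanged(self):
        reads = make_reads([("chr1", 1, "+"), ("chr1", 2, "+"), ("chr2", 1, "+")])
        pd.testing.assert_frame_equal(dedup_reads(reads), reads)

    @given(read_strategy)
    def test_idempotent_and_matches_set_semantics(self, rows):
        reads = make_reads(rows)
        once = dedup_reads(reads)
        twice = dedup_reads(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) == len(set(rows))


class TestSubsample:
    def _samples(self):
        rng = np.random.default_rng(0)
        return [
            make_reads([("chr1", int(p), "+") for p in rng.choice(100_000, size=n, replace=False)])
            for n in (120, 80, 100)
        ]

    def test_all_outputs_at_min_size(self):
        outs = subsample_equal(self._samples(), seed=1)
        assert [len(o) for o in outs] == [80, 80, 80]

    def test_outputs_are_subsets_of_inputs(self):
        samples = self._samples()
        for inp, out in zip(samples, subsample_equal(samples, seed=2)):
            inp_set = set(map(tuple, inp.itertuples(index=False)))
            assert all(tuple(r) in inp_set for r in out.itertuples(index=False))

    def test_equal_sizes_identity_up_to_order(self):
        samples = self._samples()[:2]
        trimmed = [s.head(80) for s in samples]
        outs = subsample_equal(trimmed, seed=3)
        for inp, out in zip(trimmed, outs):
            pd.testing.assert_frame_equal(inp, out)

    def test_seed_contract(self):
        samples = self._samples()
        a = subsample_equal(samples, seed=7)
        b = subsample_equal(samples, seed=7)
        c = subsample_equal(samples, seed=8)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        assert any(not x.equals(y) for x, y in zip(a, c))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subsample_equal([make_reads([]), self._samples()[0]])


class TestPeakFilterAndStats:
    def test_boundary_is_inclusive(self):
        peaks = make_peaks([("chr1", 0, 100, 50, 99.9), ("chr1", 200, 300, 250, 100.0), ("chr1", 400, 500, 450, 250.0)])
        kept = filter_peaks(peaks, min_fold=100.0)
        assert kept["name"].tolist() == ["p1", "p2"]

    def test_zero_threshold_is_identity(self):
        peaks = make_peaks([("chr1", 0, 100, 50, 3.0), ("chr1", 200, 300, 250, 0.0)])
        pd.testing.assert_frame_equal(filter_peaks(peaks, min_fold=0.0), peaks)

    def test_missing_fold_column_errors(self):
        with pytest.raises(ValueError, match="fold_enrichment"):
            filter_peaks(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))

    @given(st.lists(st.floats(0, 500, allow_nan=False), min_size=0, max_size=30), st.floats(0, 300))
    def test_filter_matches_list_comprehension(self, folds, min_fold):
        peaks = make_peaks([("chr1", 100 * i, 100 * i + 50, 100 * i + 10, f) for i, f in enumerate(folds)])
        kept = filter_peaks(peaks, min_fold=min_fold)
        assert kept["fold_enrichment"].tolist() == [f for f in folds if f >= min_fold]

    def test_mean_width(self):
        peaks = make_peaks([("chr1", 100, 700, 300, 10.0)])
        assert peak_stats(peaks) == {"count": 1, "mean_width": 600.0}
        peaks2 = make_peaks([("chr1", 0, 500, 100, 1.0), ("chr1", 1000, 1700, 1200, 1.0)])
        assert peak_stats(peaks2)["mean_width"] == 600.0


class TestReadDensity:
    def test_reads_per_kb_examples(self):
        peaks = make_peaks([("chr1", 1000, 2000, 1500, 10.0), ("chr1", 5000, 7000, 6000, 10.0)])
        reads = make_reads([("chr1", 1000 + i, "+") for i in range(50)] + [("chr1", 5000 + i, "+") for i in range(50)])
        d = read_density(peaks, reads)
        assert d.tolist() == [50.0, 25.0]

    def test_half_open_boundaries(self):
        peaks = make_peaks([("chr1", 100, 200, 150, 1.0)])
        reads = make_reads([("chr1", 99, "+"), ("chr1", 100, "+"), ("chr1", 199, "+"), ("chr1", 200, "+")])
        assert read_density(peaks, reads).item() == pytest.approx(2 / 0.1)

    @given(read_strategy)
    def test_matches_naive_scan(self, rows):
        peaks = make_peaks([("chr1", 0, 4000, 100, 1.0), ("chr1", 3000, 9000, 5000, 1.0), ("chr2", 100, 600, 300, 1.0)])
        reads = make_reads(rows)
        d = read_density(peaks, reads)
        for i, p in enumerate(peaks.itertuples(index=False)):
            naive = sum(1 for c, s, _ in rows if c == p.chrom and p.start <= s < p.end)
            assert d.iloc[i] == pytest.approx(naive / ((p.end - p.start) / 1000))


class TestBinMatrix:
    def test_window_bin_count(self, toy_genes):
        """A 2 kb gene body with +/-25 kb windows tiles into 52 one-kb bins."""
        cfg = AssocConfig(anchor="gene")
        bm = build_bin_matrix({"f": make_peaks([])}, toy_genes.iloc[[0]], cfg)
        assert len(bm.bins) == 52
        assert bm.bins["start"].min() == 30_000 - 25_000
        assert bm.bins["end"].max() == 32_000 + 25_000

    def test_no_peaks_all_zero(self, toy_genes):
        bm = build_bin_matrix({"f": make_peaks([])}, toy_genes, AssocConfig(anchor="gene"))
        assert not bm.matrix.to_numpy().any()

    def test_boundary_spanning_peak_marks_both_bins(self, toy_genes):
        peaks = make_peaks([("chr1", 30_900, 31_100, 31_000, 10.0)])  # spans the 31 kb bin edge
        bm = build_bin_matrix({"f": peaks}, toy_genes.iloc[[0]], AssocConfig(anchor="gene"))
        occupied = bm.bins[bm.matrix.loc["f"].to_numpy().astype(bool)]
        assert [(s, e) for s, e in occupied[["start", "end"]].itertuples(index=False)] == [
            (30_000, 31_000),
            (31_000, 32_000),
        ]

    def test_matches_brute_force_overlap_scan(self, toy_genes, rng):
        """Every entry equals a literal per-bin overlap test on a small genome."""
        peaks = {
            "f1": make_peaks([("chr1", int(s), int(s) + int(w), int(s) + int(w) // 2, 10.0)
                              for s, w in zip(rng.integers(0, 90_000, 15), rng.integers(50, 3000, 15))]),
            "f2": make_peaks([("chr1", int(s), int(s) + 200, int(s) + 100, 10.0)
                              for s in rng.integers(0, 90_000, 10)]),
        }
        cfg = AssocConfig(anchor="gene")
        bm = build_bin_matrix(peaks, toy_genes, cfg)
        for f, pk in peaks.items():
            for j, b in enumerate(bm.bins.itertuples(index=False)):
                expected = any(
                    p.chrom == b.chrom and p.start < b.end and p.end > b.start
                    for p in pk.itertuples(index=False)
                )
                assert bool(bm.matrix.loc[f].iloc[j]) == expected

    def test_tss_anchor_windows(self, toy_genes):
        bm = build_bin_matrix({"f": make_peaks([])}, toy_genes.iloc[[0]], AssocConfig(anchor="tss"))
        assert len(bm.bins) == 50
        assert bm.bins["start"].min() == 30_000 - 25_000


class TestAssociationScore:
    @pytest.mark.parametrize(
        "distances,expected",
        [
            ([0], 1.0),
            ([5_000], math.exp(-1)),
            ([0, 5_000, 25_000], 1 + math.exp(-1) + math.exp(-5)),
        ],
    )
    def test_closed_form_values(self, distances, expected):
        peaks = make_peaks([("chr1", 50_000 + d - 100, 50_000 + d + 100, 50_000 + d, 10.0) for d in distances])
        score = association_score(peaks, tss=50_000, chrom="chr1", cfg=AssocConfig())
        assert score == pytest.approx(expected, abs=1e-6)

    def test_additive_and_order_invariant(self, rng):
        ds = rng.integers(-24_000, 24_000, size=8)
        rows = [("chr1", 50_000 + int(d) - 10, 50_000 + int(d) + 10, 50_000 + int(d), 1.0) for d in ds]
        total = association_score(make_peaks(rows), 50_000, "chr1")
        shuffled = association_score(make_peaks([rows[i] for i in rng.permutation(8)]), 50_000, "chr1")
        parts = sum(association_score(make_peaks([r]), 50_000, "chr1") for r in rows)
        assert total == pytest.approx(shuffled)
        assert total == pytest.approx(parts)
        assert total <= len(rows)  # each term is at most exp(0)

    def test_window_restriction_drops_distant_peaks(self):
        far = make_peaks([("chr1", 99_000, 99_200, 99_100, 1.0)])  # 49.1 kb away
        assert association_score(far, 50_000, "chr1") == 0.0
        global_score = association_score(far, 50_000, "chr1", restrict_to_window=False)
        assert global_score == pytest.approx(math.exp(-49_100 / 5_000))

    def test_other_chromosome_ignored(self):
        peaks = make_peaks([("chr2", 49_900, 50_100, 50_000, 1.0)])
        assert association_score(peaks, 50_000, "chr1") == 0.0

    def test_midpoint_fallback_without_summit(self):
        peaks = make_peaks([("chr1", 49_000, 51_000, 50_000, 1.0)]).drop(columns=["summit"])
        assert association_score(peaks, 50_000, "chr1") == pytest.approx(1.0)


class TestBoundGenes:
    def test_overlap_arithmetic(self, toy_genes):
        peaks = {
            "A": make_peaks([("chr1", 29_000, 29_400, 29_200, 10.0), ("chr1", 61_000, 61_400, 61_200, 10.0)]),
            "B": make_peaks([("chr1", 61_000, 61_400, 61_200, 10.0)]),
        }
        sets = bound_genes(association_table(peaks, toy_genes))
        assert sets["A"] == {"gA", "gB"}
        assert sets["B"] == {"gB"}
        assert len(sets["A"] & sets["B"]) == 1

    def test_membership_matches_brute_force_distance_check(self, toy_genes, rng):
        cfg = AssocConfig()
        starts = rng.integers(0, 99_000, size=25)
        peaks = {"f": make_peaks([("chr1", int(s), int(s) + 400, int(s) + 200, 10.0) for s in starts])}
        table = association_table(peaks, toy_genes, cfg)
        for row in table.itertuples(index=False):
            gene = toy_genes.set_index("gene_id").loc[row.gene_id]
            expected = any(abs((int(s) + 200) - gene["tss"]) <= cfg.window for s in starts)
            assert row.bound == expected
            assert (row.score > 0) >= row.bound  # bound implies positive score

    def test_no_peaks_no_bound_genes(self, toy_genes):
        sets = bound_genes(association_table({"f": make_peaks([])}, toy_genes))
        assert sets["f"] == set()


class TestClustering:
    def test_identical_rows_merge_first_at_zero_distance(self):
        m = pd.DataFrame(
            [[1, 0, 1, 0, 1], [1, 0, 1, 0, 1], [0, 1, 0, 1, 0], [1, 1, 0, 0, 1]],
            index=["a", "a2", "b", "c"], dtype=float,
        )
        res = cluster_profiles(m)
        assert res.distances.loc["a", "a2"] == pytest.approx(0.0, abs=1e-12)
        first = sorted(res.linkage[0, :2].astype(int))
        assert [res.labels[i] for i in first] == ["a", "a2"]
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_at_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["up", "down"])
        res = cluster_profiles(m)
        assert res.distances.loc["up", "down"] == pytest.approx(2.0)

    def test_planted_blocks_merge_before_cross_joins(self, rng):
        """Two pairs of near-identical binding profiles join within-pair first."""
        base1 = rng.integers(0, 2, size=60).astype(float)
        base2 = 1.0 - base1
        noise = lambda: rng.random(60) * 0.05
        m = pd.DataFrame(
            [base1 + noise(), base1 + noise(), base2 + noise(), base2 + noise()],
            index=["a1", "a2", "b1", "b2"],
        )
        res = cluster_profiles(m)
        merges = [sorted(res.labels[int(i)] for i in res.linkage[k, :2] if i < 4) for k in range(2)]
        assert sorted(map(tuple, merges)) == [("a1", "a2"), ("b1", "b2")]

    def test_zero_variance_row_dropped_with_warning(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]], index=["flat", "x", "y"])
        with pytest.warns(UserWarning, match="flat"):
            res = cluster_profiles(m)
        assert res.dropped == ["flat"]
        assert res.labels == ["x", "y"]

    def test_newick_is_parseable_and_complete(self):
        m = pd.DataFrame(np.eye(4), index=list("abcd"))
        nwk = cluster_profiles(m).newick()
        assert nwk.endswith(";")
        for leaf in "abcd":
            assert leaf in nwk


class TestNearestFactorDistance:
    def test_example(self):
        q = make_peaks([("chr1", 9_900, 10_100, 10_000, 1.0)])
        o = make_peaks([("chr1", 7_900, 8_100, 8_000, 1.0), ("chr1", 29_900, 30_100, 30_000, 1.0)])
        assert nearest_factor_distance(q, o).item() == 2_000

    def test_self_distance_zero(self):
        q = make_peaks([("chr1", 0, 200, 100, 1.0), ("chr1", 400, 600, 500, 1.0)])
        assert nearest_factor_distance(q, q).tolist() == [0.0, 0.0]

    def test_absent_chromosome_is_nan(self):
        q = make_peaks([("chr3", 0, 200, 100, 1.0)])
        o = make_peaks([("chr1", 0, 200, 100, 1.0)])
        assert np.isnan(nearest_factor_distance(q, o).item())

    @given(
        st.lists(st.integers(0, 100_000), min_size=1, max_size=20),
        st.lists(st.integers(0, 100_000), min_size=1, max_size=20),
    )
    def test_matches_all_pairs_minimum(self, qs, os_):
        q = make_peaks([("chr1", s, s + 10, s + 5, 1.0) for s in qs])
        o = make_peaks([("chr1", s, s + 10, s + 5, 1.0) for s in os_])
        d = nearest_factor_distance(q, o)
        for i, s in enumerate(qs):
            assert d.iloc[i] == min(abs((s + 5) - (t + 5)) for t in os_)


class TestRankEnrichment:
    def test_full_enumeration_case(self):
        """Top 4 of 20 genes containing 3 of 5 bound ones: P(X>=3) = 155/4845."""
        genes = [f"g{i}" for i in range(20)]
        bound = {"g0", "g1", "g2", "g3", "g4"}
        ranked = ["g0", "g1", "g2", "g10"] + [g for g in genes if g not in {"g0", "g1", "g2", "g10"}]
        res = rank_enrichment(ranked, bound, q=0.2)
        assert res["bound_in_slice"] == 3
        exact = Fraction(math.comb(5, 3) * math.comb(15, 1) + math.comb(5, 4), math.comb(20, 4))
        assert exact == Fraction(155, 4845)
        assert res["p_value"] == pytest.approx(float(exact), rel=1e-12)
        assert res["enrichment"] == pytest.approx((3 / 4) / (5 / 20))

    def test_proportional_slice_has_unit_enrichment(self):
        ranked = ["b0", "u0", "u1", "u2", "b1", "u3", "u4", "u5"]
        res = rank_enrichment(ranked, {"b0", "b1"}, q=0.5)
        assert res["enrichment"] == pytest.approx(1.0)

    def test_hypergeom_tail_matches_permutation_null(self, rng):
        """The analytic tail equals a shuffle null within Monte-Carlo error."""
        genes = [f"g{i}" for i in range(20)]
        bound = set(genes[:5])
        n_shuffles = 100_000
        is_bound = np.array([g in bound for g in genes])
        perms = rng.permuted(np.tile(is_bound, (n_shuffles, 1)), axis=1)
        counts = perms[:, :4].sum(axis=1)
        p_perm = float((counts >= 3).mean())
        p_exact = 155 / 4845
        se = math.sqrt(p_exact * (1 - p_exact) / n_shuffles)
        assert abs(p_perm - p_exact) < 4 * se

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError, match="empty slice"):
            rank_enrichment([f"g{i}" for i in range(10)], set(), q=0.02)

    def test_bound_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            rank_enrichment(["a", "b"], {"zzz"}, q=0.5)


class TestAssocConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [{"window": 0}, {"bin_size": 0}, {"decay": -1}, {"bin_size": 2_000, "window": 1_000},
         {"top_quantiles": (0.0,)}, {"anchor": "middle"}],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AssocConfig(**kwargs)
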