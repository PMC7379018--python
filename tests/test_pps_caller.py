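"""PPS caller: Poisson tails, permutation FDR, interval logic, conservation."""

import math

import numpy as np
import pytest

from pipseq.genome_io import Interval, IntervalSet, LibraryTrack, ScoreTrack, TranscriptModel
from pipseq.pps_caller import (
    EnrichmentTrack,
    annotate_features,
    call_pps,
    classify_condition,
    conservation_compare,
    equalize_depth,
    fdr_threshold,
    feature_distribution,
    feature_enrichment,
    high_confidence,
    merge_intervals,
    overlap_mask,
    poisson_enrichment,
    PPSCallSet,
)


def make_reads(n, chrom="chr1"):
    return IntervalSet([Interval(chrom, i * 10, i * 10 + 5, f"r{i}") for i in range(n)])


def track(scores, **meta):
    return EnrichmentTrack({"chr1": np.asarray(scores, dtype=float)}, meta, {})


def lib(values):
    return LibraryTrack({"chr1": np.asarray(values, dtype=np.int64)})


class TestEqualizeDepth:
    def test_equal_sizes_unchanged(self):
        a, b = make_reads(100), make_reads(100, "chr2")
        a2, b2 = equalize_depth(a, b, seed=1)
        assert a2 is a and b2 is b

    def test_larger_library_downsampled_to_smaller(self):
        a, b = make_reads(200), make_reads(100, "chr2")
        a2, b2 = equalize_depth(a, b, seed=1)
        assert len(a2) == len(b2) == 100
        pool = {(iv.chrom, iv.start) for iv in a}
        assert all((iv.chrom, iv.start) in pool for iv in a2)

    def test_seeded_determinism(self):
        a, b = make_reads(200), make_reads(100, "chr2")
        a2, _ = equalize_depth(a, b, seed=42)
        a3, _ = equalize_depth(a, b, seed=42)
        assert [iv.start for iv in a2] == [iv.start for iv in a3]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            equalize_depth(IntervalSet(), make_reads(5), seed=0)


class TestPoissonEnrichment:
    def test_zero_footprint_scores_zero(self):
        t = poisson_enrichment(lib([0, 0, 3]), lib([5, 0, 1]))
        assert t.data["chr1"][0] == 0.0
        assert t.data["chr1"][1] == 0.0
        assert t.data["chr1"][2] > 0.0

    def test_matches_term_by_term_tail_sum(self):
        # brute-force upper tail of Poisson(lam=3) at f=10 (log-space pmf terms)
        lam = 2 + 1.0
        tail = sum(math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
                   for k in range(10, 200))
        expected = -math.log10(tail)
        t = poisson_enrichment(lib([10]), lib([2]), pseudocount=1.0)
        assert t.data["chr1"][0] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("f,s,pc", [(1, 0, 1.0), (5, 5, 1.0), (30, 3, 0.5)])
    def test_brute_force_grid(self, f, s, pc):
        lam = s + pc
        tail = sum(math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
                   for k in range(f, 400))
        t = poisson_enrichment(lib([f]), lib([s]), pseudocount=pc)
        assert t.data["chr1"][0] == pytest.approx(-math.log10(tail), rel=1e-9)

    def test_equal_high_coverage_scores_small(self, rng):
        x = rng.poisson(100, 2000)
        t = poisson_enrichment(lib(x), lib(x))
        scores = t.data["chr1"]
        assert np.mean(scores) < 1.0
        assert np.quantile(scores, 0.99) < 3.0

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            LibraryTrack({"chr1": np.array([-1, 2])})


class TestFdrThreshold:
    def brute_force(self, obs, nul, q):
        cands = sorted({v for v in obs if v > 0})
        for t in cands:
            n_o = sum(1 for v in obs if v >= t)
            n_n = sum(1 for v in nul if v >= t)
            if n_o and n_n / n_o <= q:
                return t
        return math.inf

    def test_all_null_below_gives_min_observed(self):
        obs = track([3.0, 4.0, 5.0])
        nul = track([0.5, 1.0, 2.0])
        assert fdr_threshold(obs, nul, 0.05) == 3.0

    def test_matches_exhaustive_scan_on_toys(self, rng):
        for _ in range(20):
            obs = rng.exponential(2.0, 10)
            nul = rng.exponential(2.0, 10)
            for q in (0.05, 0.2, 0.5):
                assert fdr_threshold(track(obs), track(nul), q) == self.brute_force(
                    list(obs), list(nul), q
                )

    def test_symmetric_data_controls_discoveries(self, rng):
        x = rng.exponential(1.0, 1000)
        t = fdr_threshold(track(x), track(x), 0.05)
        # identical observed/null: every candidate has FDR estimate 1
        assert t == math.inf

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_q_rejected(self, q):
        with pytest.raises(ValueError):
            fdr_threshold(track([1.0]), track([1.0]), q)


class TestCallAndMerge:
    def test_no_position_above_threshold(self):
        assert len(call_pps(track([1.0, 2.0, 3.0]), 10.0)) == 0

    def test_run_length_logic(self):
        calls = call_pps(track([0, 5, 5, 0, 5]), 4.0)
        lens = sorted(iv.length for iv in calls.intervals)
        assert lens == [1, 2]
        assert calls.intervals[0].score == 5.0

    def test_threshold_is_inclusive(self):
        calls = call_pps(track([4.0, 0.0]), 4.0)
        assert len(calls) == 1

    def test_infinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_pps(track([1.0]), math.inf)

    def test_merge_matches_brute_force_union_find(self, rng):
        # pairwise union-find oracle over the >=1 nt overlap graph
        ivs = [
            Interval("chr1", int(s), int(s) + int(l), f"i{k}")
            for k, (s, l) in enumerate(
                zip(rng.integers(0, 2000, 200), rng.integers(1, 60, 200))
            )
        ]
        merged = merge_intervals(ivs)
        parent = list(range(len(ivs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                if ivs[i].overlaps(ivs[j]):
                    parent[find(i)] = find(j)
        groups = {}
        for i, iv in enumerate(ivs):
            groups.setdefault(find(i), []).append(iv)
        expected = sorted(
            (min(g.start for g in grp), max(g.end for g in grp))
            for grp in groups.values()
        )
        assert sorted((m.start, m.end) for m in merged) == expected

    def test_bookended_intervals_stay_separate(self):
        ivs = [Interval("chr1", 0, 5), Interval("chr1", 5, 8)]
        assert len(merge_intervals(ivs)) == 2


class TestReplicatesAndConditions:
    def cs(self, spans, label="x"):
        return PPSCallSet(
            IntervalSet([Interval("chr1", s, e, f"{label}{i}")
                         for i, (s, e) in enumerate(spans)])
        )

    def test_identical_replicates_returned_whole(self):
        r = self.cs([(0, 10), (20, 30)])
        assert len(high_confidence(r, r)) == 2

    def test_disjoint_replicates_give_empty(self):
        assert len(high_confidence(self.cs([(0, 10)]), self.cs([(50, 60)]))) == 0

    def test_interval_overlapping_two_counted_once(self):
        r1 = self.cs([(0, 100)])
        r2 = self.cs([(10, 20), (50, 60)])
        hc = high_confidence(r1, r2)
        assert len(hc) == 1
        assert hc.intervals[0].end == 100  # anchor geometry is rep1's

    def test_identical_conditions_all_shared(self):
        a = self.cs([(0, 10), (20, 30)])
        res = classify_condition(a, a)
        assert len(res["shared"]) == 2
        assert len(res["control_specific"]) == 0
        assert len(res["salt_specific"]) == 0

    def test_partition_invariant_on_random_sets(self, rng):
        def rand_set(n):
            starts = np.sort(rng.choice(5000, n, replace=False))
            return self.cs([(int(s), int(s) + int(rng.integers(1, 30)))
                            for s in starts])

        control, salt = rand_set(80), rand_set(60)
        res = classify_condition(control, salt)
        assert len(res["control_specific"]) + len(res["shared"]) == len(control)
        n_salt_overlapping = int(
            overlap_mask(list(salt.intervals), list(control.intervals)).sum()
        )
        assert len(res["salt_specific"]) == len(salt) - n_salt_overlapping


class TestAnnotationOfCalls:
    @pytest.fixture
    def annotation(self, toy_mrna):
        return [toy_mrna]

    def test_pps_inside_cds(self, annotation):
        labels = annotate_features([Interval("chr1", 160, 200)], annotation)
        assert labels == [{"CDS"}]

    def test_pps_spanning_junction_counted_for_both(self, annotation):
        labels = annotate_features([Interval("chr1", 290, 310)], annotation)
        assert labels == [{"CDS", "3UTR"}]
        dist = feature_distribution(labels)
        assert dist == {"3UTR": 0.5, "CDS": 0.5}

    def test_unannotated_space_is_intergenic(self, annotation):
        labels = annotate_features([Interval("chr1", 500, 520)], annotation)
        assert labels == [{"intergenic"}]

    def test_enrichment_zero_when_proportional(self):
        # two features of equal size, PPS coverage split equally
        m = TranscriptModel("t", "chr1", "+", [(0, 200)], (0, 100))
        # CDS 0-100 (no 5'UTR), 3'UTR 100-200
        res = feature_enrichment(
            [Interval("chr1", 40, 60), Interval("chr1", 140, 160)], [m]
        )
        assert res["CDS"] == pytest.approx(0.0)
        assert res["3UTR"] == pytest.approx(0.0)

    def test_enrichment_log2_when_concentrated(self):
        m = TranscriptModel("t", "chr1", "+", [(0, 200)], (0, 100))
        res = feature_enrichment([Interval("chr1", 10, 30)], [m])
        assert res["CDS"] == pytest.approx(1.0)  # all obs in 50% of annotation

    def test_empty_pps_set_rejected(self, annotation):
        with pytest.raises(ValueError):
            feature_enrichment([], annotation)


class TestConservation:
    def test_constant_track_gives_zero_statistic(self):
        cons = ScoreTrack({"chr1": np.full(1000, 0.7)})
        ivs = [Interval("chr1", 100, 120), Interval("chr1", 300, 330)]
        res = conservation_compare(ivs, cons)
        assert res.ks_statistic == 0.0

    def test_step_track_gives_unit_statistic(self):
        arr = np.zeros(1000)
        ivs = [Interval("chr1", 100, 120), Interval("chr1", 300, 330)]
        for iv in ivs:
            arr[iv.start : iv.end] = 1.0
        res = conservation_compare(ivs, ScoreTrack({"chr1": arr}))
        assert np.all(res.pps_means == 1.0)
        assert np.all(res.flank5_means == 0.0)
        assert res.ks_statistic == 1.0

    def test_edge_interval_dropped(self):
        cons = ScoreTrack({"chr1": np.ones(100)})
        res = conservation_compare([Interval("chr1", 5, 20)], cons)  # 5' flank off edge
        assert res.n_dropped == 1
        assert res.pps_means.size == 0

    def test_statistic_matches_ecdf_oracle(self, rng):
        cons = ScoreTrack({"chr1": rng.normal(0, 1, 5000)})
        ivs = [
            Interval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(100, 4800, 20), rng.integers(5, 40, 20))
        ]
        res = conservation_compare(ivs, cons)
        flanks = np.concatenate([res.flank5_means, res.flank3_means])

        def ecdf(sample, x):
            return np.mean(sample <= x)

        grid = np.concatenate([res.pps_means, flanks])
        oracle = max(abs(ecdf(res.pps_means, x) - ecdf(flanks, x)) for x in grid)
        assert res.ks_statistic == pytest.approx(oracle, abs=1e-12)


class TestRecallMonotonicity:
    def test_recall_nondecreasing_in_enrichment(self):
        import pipseq
        from pipseq.genome_io import chrom_sizes

        recalls = []
        for enr in (1.2, 2.5, 5.0):
            cfg = pipseq.SimulationConfig(n_transcripts=100, seed=3,
                                          footprint_enrichment=enr)
            ann, truth = pipseq.simulate_annotation(cfg)
            libs = pipseq.simulate_libraries(ann, truth, cfg)
            calls, _ = pipseq.call_pps_pair(
                libs[("control", 1, "footprint", "ds")],
                libs[("control", 1, "structure_only", "ds")],
            )
            sizes = chrom_sizes(ann)
            mask = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
            for iv in truth.planted_footprints[("control", 1)]:
                mask[iv.chrom][iv.start : iv.end] = True
            planted_nt = sum(int(m.sum()) for m in mask.values())
            hit = 0
            for iv in calls.intervals:
                hit += int(mask[iv.chrom][iv.start : iv.end].sum())
            recalls.append(hit / planted_nt if planted_nt else 0.0)
        assert recalls == sorted(recalls)
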