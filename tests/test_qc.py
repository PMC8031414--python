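"""Run QC: counting rules, depth, off-target summary, permutation test."""

import numpy as np
import pytest

from repeatspan.qc import (
    QCParams,
    count_spanning,
    depth_over_target,
    gc_background,
    offtarget_summary,
    on_target_qnames,
    permutation_overlap_test,
    run_qc,
)
from repeatspan.seqio import GenomeInterval, SamRecord, SeqRecord, parse_sam

TARGET = GenomeInterval("chrT", 1000, 2000)


def sam(qname, pos0, cigar, flag=0, mapq=60):
    return SamRecord(qname, flag, "chrT", pos0, mapq, cigar)


class TestCountSpanning:
    def test_ninety_percent_exactly_is_not_spanning(self):
        assert count_spanning([sam("r", 1000, "900M")], TARGET) == 0

    def test_over_ninety_percent_is_spanning(self):
        assert count_spanning([sam("r", 1000, "901M")], TARGET) == 1

    def test_inclusive_flag(self):
        assert count_spanning([sam("r", 1000, "900M")], TARGET, inclusive=True) == 1

    def test_union_of_supplementary_pieces(self):
        records = [sam("r", 1000, "500M"), sam("r", 1500, "500M", flag=2048)]
        assert count_spanning(records, TARGET) == 1


class TestDepth:
    def test_single_full_cover(self):
        assert depth_over_target([sam("r", 1000, "1000M")], TARGET) == 1.0

    def test_two_disjoint_halves_average_to_one(self):
        records = [sam("a", 1000, "500M"), sam("b", 1500, "500M")]
        assert depth_over_target(records, TARGET) == 1.0

    def test_same_read_twice_counts_once(self):
        records = [sam("r", 1000, "600M"), sam("r", 1200, "600M", flag=2048)]
        # union [1000,1800) = 800 bases
        assert depth_over_target(records, TARGET) == pytest.approx(0.8)


class TestQCFixture:
    """Hand-computed values for the frozen 10-read SAM fixture.

    target chrT:[1000,2000), length 1000.
    on-target (>=1 bp): r1, r3, r4, r5, r9, r10 -> 6
    span90 (strict > 900 covered): r3 (901), r5 (union 1000) -> 2
    depth: (1 + 901 + 900 + 1000 + 200 + 10) / 1000 = 3.012
    off-target primary: r2 (100 bp), r7 (300 bp, MapQ 30), r8 (559 bp)
      -> median length 300, MapQ>=60 fraction 2/3
    total qnames: 10; primary mapped with MapQ >= 60: 8
    """

    def test_exact_counts(self, qc_sam):
        records = parse_sam(qc_sam)
        report = run_qc(records, [TARGET])
        assert report.total_reads == 10
        assert report.on_target_reads == 6
        assert report.span90_reads == 2
        assert report.on_target_depth == pytest.approx(3.012)
        assert report.total_reads_mapq_filtered == 8
        assert report.off_target_read_count == 3
        assert report.off_target_median_length == 300
        assert report.off_target_mapq_ge_min_frac == pytest.approx(2 / 3)

    def test_boundary_reads(self, qc_sam):
        records = parse_sam(qc_sam)
        on = on_target_qnames(records, [TARGET])
        assert "r1" in on  # 1 bp overlap
        assert "r2" not in on  # half-open: ends at 1000, 0 bp overlap


class TestOfftargetSummary:
    def test_all_on_target_gives_zero_counts(self):
        records = [sam("r", 1500, "100M")]
        summary = offtarget_summary(records, [TARGET])
        assert summary["off_target_read_count"] == 0
        assert summary["off_target_median_length"] is None

    def test_mapq_all_sixty_fraction_one(self):
        records = [
            SamRecord("a", 0, "chrT", 5000, 60, "50M", "A" * 50),
            SamRecord("b", 0, "chrT", 6000, 60, "50M", "G" * 50),
        ]
        summary = offtarget_summary(records, [TARGET])
        assert summary["off_target_mapq_ge_min_frac"] == 1.0
        assert summary["gc_offtarget_mean"] == pytest.approx(0.5)

    def test_placeholder_seq_resolved_from_fastq(self):
        records = [SamRecord("a", 0, "chrT", 5000, 60, "50M", "*")]
        summary = offtarget_summary(records, [TARGET], read_seqs={"a": "AT" * 30})
        assert summary["off_target_median_length"] == 60


class TestGCBackground:
    def test_uniform_reference_mean(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 50_000))
        ref = SeqRecord("c", seq)
        bg = gc_background(ref, 500, 10_000, seed=1)
        assert 0.48 < bg.mean() < 0.52

    def test_full_length_interval_unique(self):
        ref = SeqRecord("c", "GGCCATAT")
        bg = gc_background(ref, 8, 100, seed=0)
        assert np.all(bg == 0.5)

    def test_seed_determinism(self):
        ref = SeqRecord("c", "ACGT" * 1000)
        a = gc_background(ref, 100, 500, seed=9)
        b = gc_background(ref, 100, 500, seed=9)
        assert np.array_equal(a, b)

    def test_interval_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            gc_background(SeqRecord("c", "ACGT"), 10, 5)


class TestPermutationTest:
    GENOME = {"chr1": 100_000}

    def test_saturated_annotation_gives_p_one(self):
        reads = [GenomeInterval("chr1", i * 1000, i * 1000 + 500) for i in range(10)]
        ann = [GenomeInterval("chr1", 0, 100_000)]
        p = permutation_overlap_test(reads, ann, self.GENOME, n_perm=99, seed=0)
        assert p == 1.0

    def test_empty_annotation_rejected(self):
        reads = [GenomeInterval("chr1", 0, 100)]
        with pytest.raises(ValueError):
            permutation_overlap_test(reads, [], self.GENOME, n_perm=9, seed=0)

    def test_interval_longer_than_chromosome_rejected(self):
        reads = [GenomeInterval("chr1", 0, 200_000)]
        ann = [GenomeInterval("chr1", 0, 10)]
        with pytest.raises(ValueError):
            permutation_overlap_test(reads, ann, self.GENOME, n_perm=9, seed=0)

    def test_p_never_zero_and_bounded(self):
        # highly enriched configuration still gets p >= 1/(n_perm+1)
        reads = [GenomeInterval("chr1", 10, 20)]
        ann = [GenomeInterval("chr1", 0, 30)]
        p = permutation_overlap_test(reads, ann, self.GENOME, n_perm=999, seed=0)
        assert 0 < p <= 1
        assert p >= 1 / 1000

    def test_seed_determinism(self):
        reads = [GenomeInterval("chr1", i * 500, i * 500 + 200) for i in range(20)]
        ann = [GenomeInterval("chr1", i * 3000, i * 3000 + 100) for i in range(30)]
        p1 = permutation_overlap_test(reads, ann, self.GENOME, 199, seed=4)
        p2 = permutation_overlap_test(reads, ann, self.GENOME, 199, seed=4)
        assert p1 == p2


class TestRunQCInvariants:
    def test_monotone_counts_on_simulated_run(self, exact_run):
        from repeatspan.simulate import truth_sam_lines

        lines = truth_sam_lines(exact_run)
        records = []
        import io

        for lineno, line in enumerate(lines):
            if line.startswith("@"):
                continue
            f = line.split("\t")
            records.append(
                SamRecord(f[0], int(f[1]), f[2], int(f[3]) - 1, int(f[4]), f[5], f[9])
            )
        report = run_qc(records, [exact_run.locus.target], exact_run.reference,
                        {r.id: r.seq for r in exact_run.reads})
        n_on_truth = sum(1 for t in exact_run.truth if t.origin == "on_target")
        assert report.on_target_reads == n_on_truth
        assert report.span90_reads <= report.on_target_reads <= report.total_reads

    def test_params_validation(self):
        with pytest.raises(ValueError):
            QCParams(span_frac=1.5)
        with pytest.raises(ValueError):
            QCParams(mapq_min=61)
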