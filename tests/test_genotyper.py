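"""Genotyping pipeline: selection, anchoring, copy number, mixture."""

import numpy as np
import pytest

from repeatspan.align import ScoringScheme
from repeatspan.genotyper import (
    GenotypeParams,
    SpanningCall,
    TargetLocus,
    call_genotype,
    classify_spanning,
    count_peaks,
    estimate_copy_number,
    extract_flanks,
    fit_gmm,
    select_on_target,
)
from repeatspan.seqio import GenomeInterval, SamRecord, SeqRecord, reverse_complement

LOCUS = TargetLocus(
    chrom="chr9",
    target=GenomeInterval("chr9", 1000, 2000),
    repeat=GenomeInterval("chr9", 1400, 1460),
    motif="GGGGCC",
)


def sam(qname, pos0, cigar, flag=0):
    return SamRecord(qname, flag, "chr9", pos0, 60, cigar)


class TestSelectOnTarget:
    def test_one_bp_overlap_selected(self):
        assert select_on_target([sam("r", 999, "2M")], LOCUS) == {"r"}

    def test_zero_overlap_half_open_boundary(self):
        assert select_on_target([sam("r", 900, "100M")], LOCUS) == set()

    def test_supplementary_alignment_counts(self):
        records = [sam("r", 100, "50M"), sam("r", 1500, "50M", flag=2048)]
        assert select_on_target(records, LOCUS) == {"r"}

    def test_empty_input(self):
        assert select_on_target([], LOCUS) == set()


class TestExtractFlanks:
    def test_coordinates(self):
        ref = SeqRecord("c", "A" * 100 + "C" * 100 + "G" * 30 + "T" * 100)
        locus = TargetLocus(
            "c",
            GenomeInterval("c", 50, 300),
            GenomeInterval("c", 200, 230),
            "GGGGCC",
        )
        up, down = extract_flanks(ref, locus, 100)
        assert up == ref.seq[100:200] and down == ref.seq[230:330]

    def test_insufficient_margin(self):
        ref = SeqRecord("c", "ACGT" * 30)
        locus = TargetLocus(
            "c", GenomeInterval("c", 0, 120), GenomeInterval("c", 50, 60), "GGGGCC"
        )
        with pytest.raises(ValueError, match="flank_len"):
            extract_flanks(ref, locus, 100)


@pytest.fixture(scope="module")
def flanks(exact_run):
    return extract_flanks(exact_run.reference, exact_run.locus, 100)


class TestClassifySpanning:
    def test_error_free_read_gives_exact_repeat_bp(self, exact_run, flanks):
        up, down = flanks
        read = SeqRecord("t", up + LOCUS.motif * 8 + down)
        call = classify_spanning(read, flanks, 6)
        assert call is not None
        assert call.repeat_bp == 48 and call.copy_number == 8.0
        assert call.orientation == "as-is"

    def test_truncated_anchor_margin_rejected(self, flanks):
        up, down = flanks
        # keep only the first 5 bp of the downstream flank: the 10 bp
        # anchor margin cannot be covered
        read = SeqRecord("t", up + LOCUS.motif * 8 + down[:5])
        assert classify_spanning(read, flanks, 6) is None

    def test_minus_strand_twin_identical(self, flanks):
        up, down = flanks
        read = SeqRecord("t", up + LOCUS.motif * 12 + down)
        twin = SeqRecord("t_rc", reverse_complement(read.seq))
        a = classify_spanning(read, flanks, 6)
        b = classify_spanning(twin, flanks, 6)
        assert a is not None and b is not None
        assert b.orientation == "reverse-complemented"
        assert a.copy_number == b.copy_number

    def test_low_identity_flank_rejected_by_score_floor(self, flanks, rng):
        up, down = flanks
        noise = "".join(rng.choice(list("ACGT"), 300))
        assert classify_spanning(SeqRecord("t", noise), flanks, 6) is None


class TestEstimateCopyNumber:
    def test_arithmetic(self):
        call = SpanningCall("q", "as-is", 200, 200, 100, 148, 48, 8.0)
        assert estimate_copy_number(call, 6) == 8.0

    def test_empty_repeat(self):
        assert estimate_copy_number(0, 6) == 0.0

    def test_crossed_anchors_rejected(self):
        with pytest.raises(ValueError, match="crossed"):
            estimate_copy_number(-30, 6)


class TestCountPeaks:
    def test_two_separated_modes(self, rng):
        values = np.concatenate([rng.normal(9, 1, 50), rng.normal(749, 2, 20)])
        assert count_peaks(values, 10, 0.02) == 2

    def test_all_equal_is_one_peak(self):
        assert count_peaks([5.0] * 40) == 1

    def test_trimodal(self, rng):
        values = np.concatenate(
            [rng.normal(2, 0.5, 40), rng.normal(808, 3, 40), rng.normal(1538, 3, 40)]
        )
        assert count_peaks(values, 10, 0.02) == 3

    def test_tiny_cluster_below_min_frac_ignored(self, rng):
        values = np.concatenate([rng.normal(9, 1, 200), [500.0]])
        assert count_peaks(values, 10, 0.02) == 1


class TestFitGmm:
    def test_k1_closed_form(self):
        m = fit_gmm([10, 10, 10], 1)
        assert m.means[0] == pytest.approx(10, abs=1e-12)
        assert m.weights[0] == pytest.approx(1.0)

    def test_k1_mean_is_sample_mean(self, rng):
        x = rng.normal(50, 7, 200)
        m = fit_gmm(x, 1)
        assert m.means[0] == pytest.approx(float(x.mean()), abs=1e-9)

    def test_two_component_recovery(self, rng):
        x = np.concatenate([rng.normal(9, 2, 100), rng.normal(749, 2, 100)])
        m = fit_gmm(x, 2)
        assert abs(m.means[0] - 9) / 9 < 0.05
        assert abs(m.means[1] - 749) / 749 < 0.05

    def test_loglik_nondecreasing_and_weights_normalized(self, rng):
        for _ in range(20):
            x = np.concatenate(
                [rng.normal(rng.uniform(0, 50), 1 + rng.uniform(0, 3), 40),
                 rng.normal(rng.uniform(200, 800), 1 + rng.uniform(0, 5), 40)]
            )
            m = fit_gmm(x, 2)
            trace = np.array(m.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1, np.abs(trace[:-1])))
            assert sum(m.weights) == pytest.approx(1.0, abs=1e-9)
            assert min(m.variances) >= GenotypeParams().var_floor

    def test_deterministic_rerun_bit_identical(self, rng):
        x = rng.normal(100, 10, 80)
        assert fit_gmm(x, 2) == fit_gmm(x, 2)

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="smaller k"):
            fit_gmm([1.0, 1.0, 2.0], 3)

    def test_matches_sklearn_on_separated_data(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = np.concatenate([rng.normal(9, 2, 120), rng.normal(749, 5, 60)])
        ours = fit_gmm(x, 2)
        gm = sklearn.GaussianMixture(2, covariance_type="full", random_state=0).fit(
            x.reshape(-1, 1)
        )
        theirs = sorted(gm.means_.ravel())
        assert ours.means[0] == pytest.approx(theirs[0], abs=0.5)
        assert ours.means[1] == pytest.approx(theirs[1], abs=0.5)


class TestCallGenotype:
    def test_rounding(self, rng):
        x = np.concatenate([rng.normal(9.4, 0.2, 50), rng.normal(748.6, 0.2, 50)])
        m = fit_gmm(x, 2)
        call = call_genotype(m, x)
        assert call.alleles == (9, 749)
        assert sum(call.support_frac) == pytest.approx(1.0, abs=1e-9)

    def test_single_component(self):
        x = [2.1] * 30
        call = call_genotype(fit_gmm(x, 1), x)
        assert call.alleles == (2,)
        assert call.n_expanded == 0

    def test_expansion_count(self, rng):
        x = np.concatenate([np.full(40, 9.0), np.full(25, 749.0)])
        call = call_genotype(fit_gmm(x, 2), x, expansion_threshold=30)
        assert call.n_expanded == 25
        assert call.n_spanning == 65


class TestGenotypeRecoveryProperty:
    def test_random_multiallele_configurations(self):
        """20 random 2-3 allele configurations with separation >= 5 sd
        and >= 20 reads per allele recover every allele within 2 copies."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            k = int(rng.integers(2, 4))
            sd = rng.uniform(0.5, 3.0)
            # alleles separated by at least 5 sd (and >= 15 copies apart)
            alleles = np.cumsum(rng.integers(15, 900, k)) + 2
            x = np.concatenate(
                [rng.normal(a, sd, int(rng.integers(20, 60))) for a in alleles]
            )
            m = fit_gmm(x, k)
            call = call_genotype(m, x)
            assert len(call.alleles) == k
            for est, true in zip(call.alleles, sorted(alleles)):
                assert abs(est - true) <= 2, (call.alleles, alleles)
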