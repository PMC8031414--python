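# Methods

## Coordinate and alphabet conventions

All internal coordinates are 0-based, half-open. SAM positions (1-based)
and BED intervals (already 0-based half-open) are converted at the I/O
boundary, so anchoring arithmetic never mixes conventions. Sequences are
uppercased on ingest and restricted to {A, C, G, T, N}; N matches
nothing in alignment.

## Local alignment

Flank realignment uses a Gotoh three-matrix local dynamic program with
affine gaps. A gap of length L costs `gap_open + (L−1)·gap_extend`: the
first gapped base pays the open penalty only. This convention is stated
explicitly because implementations differ; the re-scoring utility
(`score_cigar`) and the brute-force oracle both use it, and a test
asserts score/CIGAR consistency on random pairs.

Default scoring is match +2, mismatch −3, gap open −5, gap extend −2,
the conventional striped Smith–Waterman defaults; all four values are
configurable on the command line. Determinism is part of the contract:
among equal-scoring alignments the smallest query end wins, then the
smallest reference end, and the traceback prefers diagonal over a gap in
the query (reference-consuming move) over a gap in the reference. The
production aligner is a numba-jitted plain DP — "striped" SIMD layout is
an optimization, not a semantic, and the contract is checked against an
independent, unvectorized pure-Python oracle on more than 1,000 random
pairs across three schemes.

## Spanning classification and copy number

The reference flank on each side of the repeat (default `flank_len` =
100 bp) is aligned against each candidate read and against its reverse
complement; the orientation with the larger combined flank score is
kept. Orientation is decided from alignment scores rather than SAM
flags so that reads absent from any alignment file — e.g. a
failed-basecalling FASTQ set, where an expanded repeat may have
interfered with basecalling — are genotypable; when a SAM is provided it
only restricts the candidate pool (any read overlapping the target by
≥ 1 bp, counting supplementary alignments, plus any read the SAM has
never seen).

A read is spanning when both flank alignments (a) score at least
`min_anchor_score_frac` (default 0.4) of the perfect-match flank score,
and (b) cover, **in flank coordinates**, the full `anchor_margin`
(default 10 bp) adjacent to the repeat — the last 10 bp of the upstream
flank and the first 10 bp of the downstream flank. "Aligned 10 bp
upstream/downstream" is ambiguous between read and flank coordinates;
the flank-coordinate reading is implemented because it is the one that
guarantees the subtraction below measures the whole repeat. The score
floor exists because a bare 10 bp micro-alignment can occur by chance
anywhere in a long read; 0.4 lets a flank with ~30% corrupted bases
still anchor while rejecting random placements by a wide margin.

Per-read copy number is `(down_read_start − up_read_end) / motif_len`,
kept real-valued; rounding to integers happens only at the allele level.
A read whose anchors cross (negative repeat length) is discarded with a
logged warning rather than clamped to zero, because clamping would bias
small alleles downward.

## Peak counting and mixture fitting

The allele count *k* is read off a histogram of per-read copy numbers
with fixed `bin_width` (default 10 copies, matching the granularity at
which separate allele populations are visually distinct) starting at 0.
A bin is a peak when it holds at least `min_peak_frac` (default 2%) of
the values and strictly exceeds both adjacent bins, an empty adjacent
bin counting as zero — so an isolated cluster always contributes exactly
one peak regardless of how large a distant cluster is. (Comparing
against the nearest *non-empty* bin across a long empty gap was
considered and rejected: it would let a large cluster suppress a smaller
well-separated one, which contradicts what "counting distinct peaks on
the histogram" means.) `k` can be overridden (`--k`) when the user
prefers to fix it a priori.

The mixture is a univariate Gaussian mixture with free means, variances
and weights, fitted by EM. Initialization is deterministic: means at the
k quantile midpoints (quantiles (i+0.5)/k) of the sorted data, variances
at the within-chunk variance of the k equal-size chunks (floored),
weights uniform — so reruns are bit-identical without any random
restarts, which well-separated repeat-length clusters do not need.
Variances are floored at `var_floor` (default 0.01 copies²) so a
component collapsing onto duplicated values cannot send the likelihood
to infinity; the floor can in principle break the EM monotonicity
guarantee, but only binds for degenerate clusters far tighter than
sequencing noise produces. Convergence is declared at a relative
log-likelihood change below `em_tol` (default 1e−6) or after
`em_max_iter` (500) iterations. Free (rather than shared) variances are
the default because short and very long alleles have visibly different
length-noise scales. scikit-learn's GaussianMixture serves as an
independent cross-check in the test suite, never as the implementation.

Allele calls are the rounded component means; read support is reported
both as a fraction of spanning reads and as a fraction of the candidate
(on-target) pool, since the two denominators are easy to conflate.
`n_expanded` counts reads above `expansion_threshold` (default 30
copies: above the normal range for the GGGGCC locus, below pathogenic
expansions; configurable).

## Run QC

Two "spanning" notions are kept under distinct names: `span90_reads`
(union alignment coverage of the target strictly greater than
`span_frac` = 90%; `--span-inclusive` switches to ≥) and the genotyper's
anchor-based spanning. On-target means ≥ 1 bp overlap, with no MapQ
filter; MapQ-filtered totals are reported separately (default threshold
60, the mapper's unique-placement value). Depth is the mean per-base
count over the target of reads whose reference-consuming alignment
bases cover the position, each read counted once per position however
many alignments it has. "On-target read depth" is not otherwise
standardized, so both the mean depth and the on-target read count are
emitted.

Off-target reads (primary alignments not overlapping any target) are
summarized by length, MapQ and GC; GC is compared against random
reference intervals whose length equals the mean off-target read length
(10,000 intervals by default — a desk-scale stand-in for a
million-interval genome sample; the median length is available by flag).

The permutation overlap test re-places each read interval uniformly at
random within its own chromosome, preserving its length (interchromosomal
shuffling is deliberately not the default), and reports the add-one
estimator `p = (1 + #{null ≥ observed}) / (n_perm + 1)`, which is never
zero. The statistic is the number of read intervals overlapping at least
one annotation interval. Calibration depends on the granularity of that
statistic: with very few reads or sparse annotations the null
distribution is coarse-grained and heavily tied, making the estimator
visibly conservative (rejection well below nominal). The calibration
experiment in the test suite therefore uses 200 read intervals against
100 annotation intervals on a 1 Mb chromosome, where the null statistic
takes enough values for the rejection rate to sit near (slightly below)
the nominal 5%.

## The simulator

The generator emulates what a protection/digestion enrichment run looks
like to the analysis, not the chemistry:

* **Genome.** Uniform random sequence at GC 0.395 (the genome-average GC
  observed for off-target reads), 100 kb by default, with the shortest
  allele's repeat embedded mid-sequence. Both 100 bp flanks are
  regenerated until motif-free in both orientations (bounded retries),
  so flank anchors are unambiguous by construction.
* **On-target fragments.** Cut sites sit `flank_len_genomic` (1,000 bp)
  from the repeat on each side. Each fragment draws an allele by mixture
  weight, carries exactly `2·flank_len_genomic + copies·motif_len`
  bases, and survives digestion with probability
  `(1 − breakage_per_base)^length` — a one-parameter closed form
  standing in for the fact that any break between the two protecting
  Cas9 sites dooms the molecule. This reproduces the qualitative
  observation that the shortest allele dominates spanning reads; the
  quantitative length–capture relationship is not known, so the
  exponential form is an assumption to vary (default rate 1e−5 per
  base; the bias tests use 1e−4, where the effect is strong).
* **Off-target background.** Uniformly placed fragments with lognormal
  lengths (median 559 bp, shape 0.8), placed off the protected target,
  modeling incomplete exonuclease digestion rather than off-target guide
  binding. Real runs have 10⁴–10⁶× more off-target reads than desk scale
  permits; defaults use 2,000.
* **Errors and strands.** Independent per-base substitution (3%),
  insertion (2%) and deletion (2%) — nanopore-scale, with expected
  length `len·(1 + ins − del)`; each read is reverse-complemented with
  probability `minus_strand_frac` (0.5). A `motif_purity` parameter can
  corrupt repeat copies for robustness testing (default off).
* **Truth.** Every emitted read has exactly one truth record (origin,
  allele, strand, true interval); the truth SAM encodes true intervals
  at MapQ 60 with `*` SEQ placeholders. Outputs are byte-identical per
  seed.

What the simulator does **not** model — basecalling quality strings,
homopolymer-context error correlation, multi-mapping, chimeric reads,
repeat interruptions (by default), pore dynamics — bounds what passing
tests show: they validate the estimation logic under a clean error
model, not performance on any particular real flow cell.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the whole
suite completes in well under a minute of simulation per scenario:
150–300 on-target fragments per run (tens of spanning reads per allele,
comparable to the spanning-read yield of real runs), 10,000 off-target
reads where off-target statistics are measured, 200 replicates × 999
permutations for calibration, and ≥ 1,200 random pairs for
aligner/oracle agreement.

## Known limitations

* Copy-number resolution is limited by indel noise in the repeat tract
  (~2% of tract length per read at default rates); alleles closer than
  the histogram bin width merge into one peak unless `k` is overridden.
* The EM has no split/merge moves; with a badly misspecified `k` it
  converges to a local optimum (deterministically, given the fixed
  initialization).
* Anchoring requires both flank boundaries to survive sequencing intact
  at the repeat junction, so the spanning yield drops roughly as the
  square of the per-base accuracy at the two junctions (~60–80% at
  default error rates).
* The permutation test assumes reads are placeable anywhere on their
  chromosome (no mappability mask).
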