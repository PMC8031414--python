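"""Flank-anchored repeat copy-number estimation.

The estimation logic for a targeted enrichment run over a short tandem
repeat locus:

1. candidate selection — any read whose alignment (primary or
   supplementary) overlaps the cut-to-cut enrichment target by >= 1 bp;
   reads absent from the SAM (e.g. a failed-basecalling FASTQ set) can be
   scanned directly;
2. flank anchoring — the reference flanks on either side of the repeat
   are locally realigned to each read and to its reverse complement; a
   read is *spanning* only if both flank alignments cover the 10 bp of
   flank immediately adjacent to the repeat;
3. per-read copy number — the read coordinate where the downstream-flank
   alignment starts minus the coordinate where the upstream-flank
   alignment ends, divided by the motif length; real-valued per read;
4. genotyping — the number of allele populations is read off a fixed-bin
   histogram of per-read copy numbers (automating peak counting), then a
   univariate Gaussian mixture is fitted by EM and component means are
   rounded to integer allele copy numbers.

Copy numbers stay real-valued per read; rounding happens only at the
allele level, so small systematic shifts do not accumulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import LocalAlignment, ScoringScheme, local_align
from .seqio import GenomeInterval, SamRecord, SeqRecord, ref_span, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetLocus:
    """The enrichment target (cut site to cut site) and the repeat
    interval nested inside it, with the repeat motif."""

    chrom: str
    target: GenomeInterval
    repeat: GenomeInterval
    motif: str

    def __post_init__(self):
        if not self.motif:
            raise ValueError("empty repeat motif")
        if not (
            self.target.chrom == self.repeat.chrom == self.chrom
            and self.target.start <= self.repeat.start
            and self.repeat.end <= self.target.end
        ):
            raise ValueError("repeat interval must nest inside the target interval")

    @property
    def motif_len(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class GenotypeParams:
    """Tunable parameters of the genotyping pipeline.

    flank_len
        Reference bases extracted on each side of the repeat for
        realignment.  100 bp gives alignment signal far above what a
        random placement can score while keeping each alignment cheap.
    anchor_margin
        Bases of flank immediately adjacent to the repeat that a flank
        alignment must cover (in flank coordinates) for the read to count
        as spanning; 10 bp on each side.
    min_anchor_score_frac
        Minimum flank alignment score as a fraction of the perfect-match
        score; guards against spurious short micro-alignments.
    bin_width, min_peak_frac
        Histogram granularity (copies) and minimal fraction of spanning
        reads a bin must hold to count as an allele peak.
    k_override
        Fix the mixture component count instead of counting peaks.
    expansion_threshold
        Per-read copy number above which a read counts as supporting an
        expanded allele.
    """

    flank_len: int = 100
    anchor_margin: int = 10
    min_anchor_score_frac: float = 0.4
    bin_width: float = 10.0
    min_peak_frac: float = 0.02
    k_override: int | None = None
    em_tol: float = 1e-6
    em_max_iter: int = 500
    var_floor: float = 1e-2
    expansion_threshold: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.anchor_margin > self.flank_len:
            raise ValueError("anchor_margin must not exceed flank_len")
        if not (0 < self.min_peak_frac < 1):
            raise ValueError("min_peak_frac must lie in (0,1)")
        if self.var_floor <= 0:
            raise ValueError("var_floor must be positive")


@dataclass(frozen=True)
class SpanningCall:
    """Anchor coordinates and copy number for one spanning read."""

    qname: str
    orientation: str  # "as-is" or "reverse-complemented"
    up_score: int
    down_score: int
    up_read_end: int
    down_read_start: int
    repeat_bp: int
    copy_number: float


@dataclass(frozen=True)
class MixtureModel:
    """Fitted univariate Gaussian mixture over per-read copy numbers."""

    k: int
    means: tuple[float, ...]
    variances: tuple[float, ...]
    weights: tuple[float, ...]
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: tuple[float, ...] = field(default=(), compare=False)


@dataclass(frozen=True)
class GenotypeCall:
    """Rounded allele copy numbers with per-allele read support."""

    alleles: tuple[int, ...]
    support_frac: tuple[float, ...]
    n_spanning: int
    n_expanded: int


def select_on_target(records: Sequence[SamRecord], locus: TargetLocus) -> set[str]:
    """qnames with any mapped alignment overlapping the target by >= 1 bp.

    Reads are frequently soft-clipped within an expanded repeat, with the
    up- and downstream sequence represented as multiple alignments, so
    supplementary alignments count.  No MapQ filter at this stage.
    """
    selected: set[str] = set()
    for rec in records:
        if rec.is_unmapped or rec.qname in selected:
            continue
        if ref_span(rec).overlap(locus.target) >= 1:
            selected.add(rec.qname)
    return selected


def extract_flanks(
    reference: SeqRecord, locus: TargetLocus, flank_len: int = 100
) -> tuple[str, str]:
    """Reference sequence immediately up- and downstream of the repeat."""
    start, end = locus.repeat.start, locus.repeat.end
    if start - flank_len < 0 or end + flank_len > len(reference.seq):
        raise ValueError(
            f"flank_len {flank_len} exceeds the reference margin around the "
            "repeat; reduce flank_len"
        )
    return (
        reference.seq[start - flank_len : start],
        reference.seq[end : end + flank_len],
    )


def _anchored_upstream(aln: LocalAlignment, flank_len: int, margin: int) -> bool:
    # upstream flank: alignment must cover its last `margin` bases
    return aln.r_end == flank_len and aln.r_start <= flank_len - margin


def _anchored_downstream(aln: LocalAlignment, margin: int) -> bool:
    # downstream flank: alignment must cover its first `margin` bases
    return aln.r_start == 0 and aln.r_end >= margin


def classify_spanning(
    read: SeqRecord,
    flanks: tuple[str, str],
    motif_len: int,
    params: GenotypeParams | None = None,
    scheme: ScoringScheme | None = None,
) -> SpanningCall | None:
    """Anchor both flanks in the read; return a call iff both anchor.

    Both flanks are aligned against the read and against its reverse
    complement; the orientation with the larger combined score wins, so
    reads never seen by a mapper (failed-basecalling sets) are handled
    identically to mapped ones.  Returns None for non-spanning reads —
    a normal outcome, not an error.
    """
    if params is None:
        params = GenotypeParams()
    if scheme is None:
        scheme = ScoringScheme()
    up_flank, down_flank = flanks
    flank_len = len(up_flank)
    if len(down_flank) != flank_len:
        raise ValueError("flanks must have equal length")

    fwd = read.seq
    rev = reverse_complement(fwd)
    up_f = local_align(fwd, up_flank, scheme)
    down_f = local_align(fwd, down_flank, scheme)
    up_r = local_align(rev, up_flank, scheme)
    down_r = local_align(rev, down_flank, scheme)

    if up_f.score + down_f.score >= up_r.score + down_r.score:
        orientation, up, down = "as-is", up_f, down_f
    else:
        orientation, up, down = "reverse-complemented", up_r, down_r

    min_score = params.min_anchor_score_frac * scheme.match * flank_len
    if up.score < min_score or down.score < min_score:
        return None
    if not _anchored_upstream(up, flank_len, params.anchor_margin):
        return None
    if not _anchored_downstream(down, params.anchor_margin):
        return None

    repeat_bp = down.q_start - up.q_end
    if repeat_bp < 0:
        logger.warning(
            "read %s: flank anchors cross (upstream ends at %d, downstream "
            "starts at %d); read discarded",
            read.id,
            up.q_end,
            down.q_start,
        )
        return None
    return SpanningCall(
        qname=read.id,
        orientation=orientation,
        up_score=up.score,
        down_score=down.score,
        up_read_end=up.q_end,
        down_read_start=down.q_start,
        repeat_bp=repeat_bp,
        copy_number=repeat_bp / motif_len,
    )


def estimate_copy_number(call_or_bp, motif_len: int) -> float:
    """Repeat copy number: anchored repeat base pairs / motif length."""
    repeat_bp = call_or_bp.repeat_bp if isinstance(call_or_bp, SpanningCall) else call_or_bp
    if repeat_bp < 0:
        raise ValueError("crossed anchors: repeat_bp < 0; call must be discarded")
    return repeat_bp / motif_len


def count_peaks(
    copy_numbers: Sequence[float],
    bin_width: float = 10.0,
    min_peak_frac: float = 0.02,
) -> int:
    """Allele count from a fixed-bin histogram of per-read copy numbers.

    Bins of ``bin_width`` copies start at 0.  A bin is a peak if it holds
    at least ``min_peak_frac`` of all values and strictly exceeds both
    adjacent bins (an empty adjacent bin counts as 0, so an isolated
    cluster always yields its own peak).  Automates eyeballing distinct
    peaks on the read-length histogram; always returns at least 1.
    """
    values = np.asarray(list(copy_numbers), dtype=float)
    if values.size == 0:
        raise ValueError("count_peaks requires at least one value")
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx)
    padded = np.concatenate([[0], counts, [0]])
    min_count = min_peak_frac * values.size
    peaks = (
        (padded[1:-1] > padded[:-2])
        & (padded[1:-1] > padded[2:])
        & (padded[1:-1] >= min_count)
    )
    return max(int(peaks.sum()), 1)


def _em_loglik(x: np.ndarray, means, variances, weights) -> float:
    # log-sum-exp over components
    log_comp = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    mx = log_comp.max(axis=1, keepdims=True)
    return float((mx[:, 0] + np.log(np.exp(log_comp - mx).sum(axis=1))).sum())


def fit_gmm(
    copy_numbers: Sequence[float], k: int, params: GenotypeParams | None = None
) -> MixtureModel:
    """Univariate Gaussian mixture EM with free means/variances/weights.

    Deterministic: means initialize at the k quantile midpoints of the
    sorted data (quantiles (i+0.5)/k), variances at the within-chunk
    variance of the k equal-size chunks of the sorted data, weights
    uniform.  Variances are floored at ``var_floor`` so a component
    collapsing onto duplicated values cannot drive the likelihood to
    infinity.  Stops when the relative log-likelihood change falls below
    ``em_tol`` or after ``em_max_iter`` iterations.
    """
    if params is None:
        params = GenotypeParams()
    x = np.asarray(list(copy_numbers), dtype=float)
    if x.size == 0:
        raise ValueError("fit_gmm requires data")
    n_distinct = np.unique(x).size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct copy-number values; "
            "choose a smaller k"
        )

    xs = np.sort(x)
    means = np.quantile(xs, (np.arange(k) + 0.5) / k)
    chunks = np.array_split(xs, k)
    variances = np.array([max(np.var(c), params.var_floor) for c in chunks])
    weights = np.full(k, 1.0 / k)

    loglik = _em_loglik(x, means, variances, weights)
    trace = [loglik]
    converged = False
    n_iter = 0
    for n_iter in range(1, params.em_max_iter + 1):
        # E step: responsibilities via stable log-space computation
        log_comp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        mx = log_comp.max(axis=1, keepdims=True)
        p = np.exp(log_comp - mx)
        resp = p / p.sum(axis=1, keepdims=True)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, params.var_floor)
        weights = nk / x.size

        new_loglik = _em_loglik(x, means, variances, weights)
        trace.append(new_loglik)
        denom = max(abs(loglik), 1.0)
        if abs(new_loglik - loglik) / denom < params.em_tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    order = np.argsort(means)
    return MixtureModel(
        k=k,
        means=tuple(float(m) for m in means[order]),
        variances=tuple(float(v) for v in variances[order]),
        weights=tuple(float(w) for w in weights[order]),
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        loglik_trace=tuple(trace),
    )


def call_genotype(
    model: MixtureModel,
    copy_numbers: Sequence[float],
    expansion_threshold: float = 30.0,
) -> GenotypeCall:
    """Round component means to allele copy numbers; hard-assign reads.

    Support fractions come from maximum-posterior assignment of each
    spanning read to a component; ``n_expanded`` counts reads whose copy
    number exceeds the expansion threshold (default 30 copies, above the
    normal range for the hexanucleotide locus and below pathogenic
    expansions).
    """
    x = np.asarray(list(copy_numbers), dtype=float)
    means = np.asarray(model.means)
    variances = np.asarray(model.variances)
    weights = np.asarray(model.weights)
    log_comp = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    assign = log_comp.argmax(axis=1)
    support = np.bincount(assign, minlength=model.k) / x.size
    return GenotypeCall(
        alleles=tuple(int(round(m)) for m in model.means),
        support_frac=tuple(float(s) for s in support),
        n_spanning=int(x.size),
        n_expanded=int((x > expansion_threshold).sum()),
    )


def genotype_reads(
    reads: Iterable[SeqRecord],
    flanks: tuple[str, str],
    motif_len: int,
    params: GenotypeParams | None = None,
    scheme: ScoringScheme | None = None,
) -> tuple[list[SpanningCall], MixtureModel | None, GenotypeCall | None]:
    """Run anchoring + genotyping over a read set.

    Returns the spanning calls and, when any read spans, the fitted
    mixture and the genotype call.
    """
    if params is None:
        params = GenotypeParams()
    if scheme is None:
        scheme = ScoringScheme()
    calls: list[SpanningCall] = []
    for read in reads:
        call = classify_spanning(read, flanks, motif_len, params, scheme)
        if call is not None:
            calls.append(call)
    if not calls:
        return [], None, None
    copy_numbers = [c.copy_number for c in calls]
    k = params.k_override or count_peaks(
        copy_numbers, params.bin_width, params.min_peak_frac
    )
    k = min(k, int(np.unique(copy_numbers).size))
    model = fit_gmm(copy_numbers, k, params)
    genotype = call_genotype(model, copy_numbers, params.expansion_threshold)
    return calls, model, genotype
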