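"""Enrichment-run QC: coverage, spanning and off-target statistics.

Two distinct notions of "spanning" exist in this pipeline and are kept
apart deliberately: ``span90_reads`` here means reads whose alignments
cover more than 90% of the cut-to-cut target (an alignment-level QC
statistic), while the genotyper's anchor-based spanning
(``anchor_spanning_reads``) requires both repeat flanks to realign.

Off-target background in a protection/digestion run consists of short
fragments that escaped exonuclease digestion; the module characterizes
their length, mapping-quality and GC distributions and compares GC
against random reference intervals, and offers a permutation test for
overlap with an annotation set (e.g. G-quadruplex tracks).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .seqio import GenomeInterval, SamRecord, SeqRecord, gc_fraction, ref_span


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the run QC report.

    span_frac: fraction of the target a read must cover to count as
    span90 (strict > by default; ``span_inclusive`` switches to >=).
    mapq_min: mapping-quality threshold for the filtered counts.
    """

    span_frac: float = 0.9
    span_inclusive: bool = False
    mapq_min: int = 60
    n_gc_intervals: int = 10_000
    n_perm: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.span_frac < 1):
            raise ValueError("span_frac must lie in (0,1)")
        if not (0 <= self.mapq_min <= 60):
            raise ValueError("mapq_min must lie in [0,60]")


@dataclass
class RunQCReport:
    total_reads: int
    total_reads_mapq_filtered: int
    on_target_reads: int
    on_target_depth: float
    span90_reads: int
    off_target_read_count: int
    off_target_median_length: float | None
    off_target_mapq_ge_min_frac: float | None
    gc_offtarget_mean: float | None
    gc_background_mean: float | None
    perm_p: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _union_segments(segments: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge [start,end) segments into disjoint sorted segments."""
    if not segments:
        return []
    segments = sorted(segments)
    merged = [segments[0]]
    for s, e in segments[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _per_qname_target_segments(
    records: Sequence[SamRecord], target: GenomeInterval
) -> dict[str, list[tuple[int, int]]]:
    segs: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        span = ref_span(rec)
        if span.chrom != target.chrom:
            continue
        s = max(span.start, target.start)
        e = min(span.end, target.end)
        if s < e:
            segs.setdefault(rec.qname, []).append((s, e))
    return segs


def count_spanning(
    records: Sequence[SamRecord],
    locus_target: GenomeInterval,
    span_frac: float = 0.9,
    inclusive: bool = False,
) -> int:
    """Reads whose union alignment coverage exceeds span_frac of target.

    Coverage is the union over all of a read's alignments clipped to the
    target, so a read split into supplementary pieces still counts when
    the pieces jointly cover the target.  Strict > by default.
    """
    threshold = span_frac * len(locus_target)
    count = 0
    for segs in _per_qname_target_segments(records, locus_target).values():
        covered = sum(e - s for s, e in _union_segments(segs))
        if covered >= threshold if inclusive else covered > threshold:
            count += 1
    return count


def on_target_qnames(
    records: Sequence[SamRecord], targets: Sequence[GenomeInterval]
) -> set[str]:
    """qnames with any alignment overlapping any target by >= 1 bp."""
    out: set[str] = set()
    for rec in records:
        if rec.is_unmapped or rec.qname in out:
            continue
        span = ref_span(rec)
        if any(span.overlap(t) >= 1 for t in targets):
            out.add(rec.qname)
    return out


def depth_over_target(
    records: Sequence[SamRecord], locus_target: GenomeInterval
) -> float:
    """Mean per-base depth over the target; each read counts once per
    position regardless of how many alignments cover it."""
    tlen = len(locus_target)
    diff = np.zeros(tlen + 1, dtype=np.int64)
    for segs in _per_qname_target_segments(records, locus_target).values():
        for s, e in _union_segments(segs):
            diff[s - locus_target.start] += 1
            diff[e - locus_target.start] -= 1
    depth = np.cumsum(diff[:-1])
    return float(depth.mean())


def offtarget_summary(
    records: Sequence[SamRecord],
    targets: Sequence[GenomeInterval],
    mapq_min: int = 60,
    read_seqs: Mapping[str, str] | None = None,
) -> dict:
    """Length / MapQ / GC summary of off-target reads.

    Length and GC statistics use primary alignments only; sequence comes
    from the SAM SEQ field or, when that is the ``*`` placeholder, from
    ``read_seqs`` keyed by qname.
    """
    on = on_target_qnames(records, targets)
    lengths: list[int] = []
    mapqs: list[int] = []
    gcs: list[float] = []
    for rec in records:
        if rec.is_unmapped or not rec.is_primary or rec.qname in on:
            continue
        seq = rec.seq
        if seq == "*" and read_seqs is not None:
            seq = read_seqs.get(rec.qname, "*")
        mapqs.append(rec.mapq)
        if seq != "*":
            lengths.append(len(seq))
            gcs.append(gc_fraction(seq))
    n = len(mapqs)
    return {
        "off_target_read_count": n,
        "off_target_median_length": float(np.median(lengths)) if lengths else None,
        "off_target_mean_length": float(np.mean(lengths)) if lengths else None,
        "mapq_histogram": {int(q): int(c) for q, c in zip(*np.unique(mapqs, return_counts=True))}
        if n
        else {},
        "off_target_mapq_ge_min_frac": float(np.mean([q >= mapq_min for q in mapqs]))
        if n
        else None,
        "gc_values": [float(g) for g in gcs],
        "gc_offtarget_mean": float(np.mean(gcs)) if gcs else None,
    }


def gc_background(
    reference: SeqRecord, interval_len: int, n_intervals: int, seed: int = 0
) -> np.ndarray:
    """GC of uniform random reference intervals of fixed length.

    Emulates comparing off-target GC against a random interval sample
    from the reference; interval length should match the mean (or, by
    choice, median) off-target read length.
    """
    L = len(reference.seq)
    if interval_len > L:
        raise ValueError(f"interval_len {interval_len} exceeds reference length {L}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, L - interval_len + 1, size=n_intervals)
    arr = np.frombuffer(reference.seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    return (csum[starts + interval_len] - csum[starts]) / interval_len


def _merge_numpy(intervals: Sequence[GenomeInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, segs in by_chrom.items():
        merged = _union_segments(segs)
        out[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )
    return out


def _count_overlapping(
    starts: np.ndarray, ends: np.ndarray, ann: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """For each [start,end) row, 1 if it overlaps any merged annotation
    interval.  ``starts``/``ends`` may be of any matching shape."""
    a_starts, a_ends = ann
    # candidate: last annotation starting before the read end
    idx = np.searchsorted(a_starts, ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(starts.shape, dtype=bool)
    # merged intervals are disjoint and sorted so ends are increasing:
    # the candidate has the largest end among those starting before
    hit[ok] = a_ends[idx[ok]] > starts[ok]
    return hit


def permutation_overlap_test(
    reads: Sequence[GenomeInterval],
    annotation: Sequence[GenomeInterval],
    genome_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for read/annotation overlap enrichment.

    Observed statistic: number of read intervals overlapping at least one
    annotation interval.  Null: each read interval is re-placed uniformly
    at random within its own chromosome, preserving its length, and the
    statistic recomputed; p = (1 + #{null >= observed}) / (n_perm + 1),
    so p is never 0.
    """
    if not reads or not annotation:
        raise ValueError("permutation test requires non-empty interval sets")
    for iv in reads:
        if iv.chrom not in genome_sizes:
            raise ValueError(f"no genome size for chromosome {iv.chrom!r}")
        if len(iv) > genome_sizes[iv.chrom]:
            raise ValueError(
                f"interval length {len(iv)} exceeds chromosome {iv.chrom!r}"
            )
    ann = _merge_numpy(annotation)
    rng = np.random.default_rng(seed)

    observed = 0
    null = np.zeros(n_perm, dtype=np.int64)
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in reads:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        lens = np.array([len(iv) for iv in ivs], dtype=np.int64)
        if chrom in ann:
            s = np.array([iv.start for iv in ivs], dtype=np.int64)
            observed += int(_count_overlapping(s, s + lens, ann[chrom]).sum())
            high = genome_sizes[chrom] - lens + 1
            perm_starts = rng.integers(0, high[None, :], size=(n_perm, lens.size))
            null += _count_overlapping(
                perm_starts, perm_starts + lens[None, :], ann[chrom]
            ).sum(axis=1)
        else:
            # no annotation on this chromosome: contributes 0 overlap both
            # observed and permuted, but random draws keep the stream
            # aligned across configurations
            rng.integers(0, 1 + genome_sizes[chrom] - lens[None, :], size=(n_perm, lens.size))
    return (1 + int((null >= observed).sum())) / (n_perm + 1)


def run_qc(
    records: Sequence[SamRecord],
    targets: Sequence[GenomeInterval],
    reference: SeqRecord | None = None,
    read_seqs: Mapping[str, str] | None = None,
    annotations: Sequence[GenomeInterval] | None = None,
    genome_sizes: Mapping[str, int] | None = None,
    params: QCParams | None = None,
) -> RunQCReport:
    """Assemble the full QC report for one run (one or more targets).

    Depth and span90 statistics are computed over the first target (the
    enrichment locus); on/off-target partitioning considers all targets.
    """
    if params is None:
        params = QCParams()
    mapped_primary = [r for r in records if not r.is_unmapped and r.is_primary]
    total = len({r.qname for r in records})
    total_filtered = len({r.qname for r in mapped_primary if r.mapq >= params.mapq_min})
    on = on_target_qnames(records, targets)
    off = offtarget_summary(records, targets, params.mapq_min, read_seqs)

    target = targets[0]
    span90 = count_spanning(records, target, params.span_frac, params.span_inclusive)
    depth = depth_over_target(records, target)

    gc_bg_mean = None
    if reference is not None and off["off_target_mean_length"]:
        bg = gc_background(
            reference,
            int(round(off["off_target_mean_length"])),
            params.n_gc_intervals,
            params.seed,
        )
        gc_bg_mean = float(bg.mean())

    perm_p = None
    if annotations:
        if genome_sizes is None:
            raise ValueError("annotations given but genome_sizes missing")
        read_ivs = [ref_span(r) for r in mapped_primary if r.qname not in on]
        if read_ivs:
            perm_p = permutation_overlap_test(
                read_ivs, list(annotations), genome_sizes, params.n_perm, params.seed
            )

    report = RunQCReport(
        total_reads=total,
        total_reads_mapq_filtered=total_filtered,
        on_target_reads=len(on),
        on_target_depth=depth,
        span90_reads=span90,
        off_target_read_count=off["off_target_read_count"],
        off_target_median_length=off["off_target_median_length"],
        off_target_mapq_ge_min_frac=off["off_target_mapq_ge_min_frac"],
        gc_offtarget_mean=off["gc_offtarget_mean"],
        gc_background_mean=gc_bg_mean,
        perm_p=perm_p,
    )
    assert report.span90_reads <= report.on_target_reads <= report.total_reads
    return report
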