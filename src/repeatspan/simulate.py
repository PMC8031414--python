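"""Synthetic Cas9-protection / exonuclease-digestion run generator.

Emulates the data structure of a targeted enrichment nanopore run over a
repeat-expansion locus, with full per-read ground truth:

* a random toy genome at a configurable GC content, with a repeat locus
  embedded and guaranteed motif-free flanks (so flank anchors are
  unambiguous);
* 2-3 allele-length populations at the locus (mosaic cell lines show a
  third population), drawn per fragment by mixture weight;
* protection bias: a cut-to-cut fragment survives digestion with
  probability (1 - breakage_per_base)^length — a single interpretable
  parameter standing in for the observation that any break between the
  two protecting Cas9 sites dooms the molecule, which biases sequencing
  toward short alleles;
* off-target background from incomplete digestion: uniformly placed
  fragments with lognormal lengths (median configurable, 559 bp by
  default), not guide-driven off-target capture;
* a per-base substitution/insertion/deletion error channel at
  nanopore-scale rates and a configurable strand split.

The generator emits FASTQ reads, a truth SAM (true origin intervals,
MapQ 60, ``*`` SEQ placeholders) and a JSON truth table; everything is
deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genotyper import TargetLocus
from .seqio import (
    GenomeInterval,
    SeqRecord,
    reverse_complement,
    write_fasta,
    write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated enrichment run.

    Defaults mirror the characteristics of real runs: off-target
    fragments with median length 559 bp, genome-average GC of 0.395,
    a GGGGCC hexanucleotide repeat, and roughly balanced strands.
    ``alleles`` is a list of (copy_number, weight) pairs; the default is
    a triallelic mosaic-like configuration with the shortest allele most
    abundant before protection bias is applied.
    """

    genome_len: int = 100_000
    gc: float = 0.395
    motif: str = "GGGGCC"
    alleles: tuple[tuple[int, float], ...] = ((9, 0.4), (749, 0.3), (1893, 0.3))
    flank_len_genomic: int = 1_000
    n_on_target_fragments: int = 300
    breakage_per_base: float = 1e-5
    n_off_target_reads: int = 2_000
    off_target_len_median: float = 559.0
    off_target_len_sigma: float = 0.8
    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.02
    minus_strand_frac: float = 0.5
    motif_purity: float = 1.0
    flank_clearance: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.motif:
            raise ValueError("motif must be non-empty")
        total = sum(w for _, w in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele weights sum to {total}, expected 1")
        for rate in (self.sub_rate, self.ins_rate, self.del_rate, self.breakage_per_base):
            if not (0 <= rate < 1):
                raise ValueError("rates must lie in [0,1)")
        max_copies = max(c for c, _ in self.alleles)
        needed = 2 * (self.flank_len_genomic + self.flank_clearance) + len(self.motif) * min(
            c for c, _ in self.alleles
        )
        if needed >= self.genome_len:
            raise ValueError("genome too small for the repeat locus and margins")
        if max_copies < 0:
            raise ValueError("allele copy numbers must be non-negative")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one emitted read."""

    qname: str
    origin: str  # "on_target" | "off_target"
    allele_copy_number: int | None
    strand: str
    chrom: str
    start: int
    end: int
    survived_protection: bool = True


@dataclass
class SimulatedRun:
    reference: SeqRecord
    locus: TargetLocus
    reads: list[SeqRecord]
    truth: list[SimTruth]
    config: SimConfig


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


def build_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random genome with the shortest allele's repeat embedded mid-way.

    Guarantees zero occurrences of the motif (either orientation) within
    ``flank_clearance`` bases of the repeat boundaries, so flank anchors
    cannot land inside spurious motif copies; flank windows are
    regenerated under a bounded retry budget.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    motif = config.motif
    rc_motif = reverse_complement(motif)
    min_copies = min(c for c, _ in config.alleles)
    repeat_seq = motif * min_copies

    clearance = config.flank_clearance
    repeat_start = config.genome_len // 2
    left_end = repeat_start
    right_start = repeat_start + len(repeat_seq)

    genome = list(_random_seq(rng, config.genome_len, config.gc))

    def regenerate_clear(lo: int, hi: int) -> None:
        # rewrite [lo,hi) until motif-free in both orientations
        for _ in range(200):
            window = "".join(genome[max(0, lo - len(motif) + 1) : hi + len(motif) - 1])
            if motif not in window and rc_motif not in window:
                return
            genome[lo:hi] = list(_random_seq(rng, hi - lo, config.gc))
        raise RuntimeError(
            "could not build motif-free flanks after 200 retries; "
            "lower gc or use a less probable motif"
        )

    genome[left_end:right_start] = list(repeat_seq)
    regenerate_clear(left_end - clearance, left_end)
    regenerate_clear(right_start, right_start + clearance)

    reference = SeqRecord(id="chrSim", seq="".join(genome))
    repeat = GenomeInterval("chrSim", left_end, right_start)
    target = GenomeInterval(
        "chrSim",
        left_end - config.flank_len_genomic,
        right_start + config.flank_len_genomic,
    )
    return reference, TargetLocus("chrSim", target, repeat, motif)


def simulate_fragments(
    config: SimConfig,
    locus: TargetLocus,
    reference: SeqRecord,
    rng: np.random.Generator,
) -> list[tuple[int, str, bool]]:
    """Draw cut-to-cut on-target fragments and apply protection survival.

    Returns (allele_copies, fragment_sequence, survived) for every
    attempted fragment; only survivors are sequenced.  Fragment length is
    exactly 2*flank_len_genomic + copies*motif_len.
    """
    copies = np.array([c for c, _ in config.alleles])
    weights = np.array([w for _, w in config.alleles])
    left = reference.seq[locus.target.start : locus.repeat.start]
    right = reference.seq[locus.repeat.end : locus.target.end]
    out = []
    draws = rng.choice(len(copies), size=config.n_on_target_fragments, p=weights)
    for a in draws:
        n_copies = int(copies[a])
        repeat = _repeat_tract(config, n_copies, rng)
        frag = left + repeat + right
        p_survive = (1.0 - config.breakage_per_base) ** len(frag)
        survived = bool(rng.random() < p_survive)
        out.append((n_copies, frag, survived))
    return out


def _repeat_tract(config: SimConfig, n_copies: int, rng: np.random.Generator) -> str:
    tract = config.motif * n_copies
    if config.motif_purity >= 1.0 or not tract:
        return tract
    arr = np.frombuffer(tract.encode("ascii"), dtype=np.uint8).copy()
    impure = rng.random(len(arr)) > config.motif_purity
    arr[impure] = _BASES[rng.integers(0, 4, impure.sum())]
    return arr.tobytes().decode("ascii")


def apply_error_channel(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    """Independent per-base substitution / insertion / deletion.

    Expected output length is len * (1 + ins_rate - del_rate).
    """
    if config.sub_rate == config.ins_rate == config.del_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    deleted = rng.random(n) < config.del_rate
    substituted = rng.random(n) < config.sub_rate
    inserted = rng.random(n) < config.ins_rate
    # substitution rotates the base by 1..3 within ACGT, guaranteeing a
    # different base; N substitutes to a uniform base
    base_index = np.zeros(256, dtype=np.int64)
    for i, c in enumerate(b"ACGT"):
        base_index[c] = i
    offsets = rng.integers(1, 4, n)
    sub_bases = _BASES[(base_index[arr] + offsets) % 4]
    ins_bases = _BASES[rng.integers(0, 4, n)]
    out = bytearray()
    for i in range(n):
        if not deleted[i]:
            out.append(sub_bases[i] if substituted[i] else arr[i])
        if inserted[i]:
            out.append(ins_bases[i])
    return out.decode("ascii")


def simulate_run(config: SimConfig) -> SimulatedRun:
    """Full in-memory run: genome, fragments, errors, strands, truth."""
    rng = np.random.default_rng(config.seed)
    reference, locus = build_genome(config, rng)

    reads: list[SeqRecord] = []
    truth: list[SimTruth] = []

    fragments = simulate_fragments(config, locus, reference, rng)
    n_on = 0
    for allele, frag, survived in fragments:
        if not survived:
            continue
        n_on += 1
        qname = f"on_{n_on:05d}"
        seq = apply_error_channel(frag, config, rng)
        strand = "-" if rng.random() < config.minus_strand_frac else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(SeqRecord(id=qname, seq=seq, qual="I" * len(seq)))
        truth.append(
            SimTruth(
                qname=qname,
                origin="on_target",
                allele_copy_number=allele,
                strand=strand,
                chrom=locus.chrom,
                start=locus.target.start,
                end=locus.target.end,
            )
        )

    # off-target background: uniform placement avoiding the protected
    # target (those molecules are full cut-to-cut fragments), lognormal
    # lengths with the configured median
    mu = float(np.log(config.off_target_len_median))
    for i in range(config.n_off_target_reads):
        qname = f"off_{i + 1:05d}"
        for _ in range(1000):
            length = max(30, int(round(rng.lognormal(mu, config.off_target_len_sigma))))
            length = min(length, config.genome_len)
            start = int(rng.integers(0, config.genome_len - length + 1))
            iv = GenomeInterval(locus.chrom, start, start + length)
            if iv.overlap(locus.target) == 0:
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not place off-target fragment off the target")
        frag = reference.seq[start : start + length]
        seq = apply_error_channel(frag, config, rng)
        strand = "-" if rng.random() < config.minus_strand_frac else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(SeqRecord(id=qname, seq=seq, qual="I" * len(seq)))
        truth.append(
            SimTruth(
                qname=qname,
                origin="off_target",
                allele_copy_number=None,
                strand=strand,
                chrom=locus.chrom,
                start=start,
                end=start + length,
            )
        )

    assert len(reads) == len(truth)
    return SimulatedRun(reference=reference, locus=locus, reads=reads, truth=truth, config=config)


def truth_sam_lines(run: SimulatedRun) -> list[str]:
    """Truth alignments: true origin interval, MapQ 60, SEQ placeholder."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{run.locus.chrom}\tLN:{len(run.reference.seq)}",
    ]
    for t in run.truth:
        flag = 16 if t.strand == "-" else 0
        cigar = f"{t.end - t.start}M"
        lines.append(
            f"{t.qname}\t{flag}\t{t.chrom}\t{t.start + 1}\t60\t{cigar}\t*\t0\t0\t*\t*"
        )
    return lines


def emit_run(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated run to disk: FASTQ, reference FASTA, truth SAM,
    truth JSON, locus JSON.  Byte-identical outputs per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = simulate_run(config)

    paths = {
        "fastq": outdir / "reads.fastq",
        "reference": outdir / "reference.fasta",
        "sam": outdir / "truth.sam",
        "truth": outdir / "truth.json",
        "locus": outdir / "locus.json",
    }
    write_fastq(run.reads, paths["fastq"])
    write_fasta([run.reference], paths["reference"])
    with open(paths["sam"], "w") as fh:
        fh.write("\n".join(truth_sam_lines(run)) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": {**asdict(config), "alleles": [list(a) for a in config.alleles]},
                "truth": [asdict(t) for t in run.truth],
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    with open(paths["locus"], "w") as fh:
        json.dump(
            {
                "chrom": run.locus.chrom,
                "target_start": run.locus.target.start,
                "target_end": run.locus.target.end,
                "repeat_start": run.locus.repeat.start,
                "repeat_end": run.locus.repeat.end,
                "motif": run.locus.motif,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths
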