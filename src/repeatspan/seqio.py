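"""Sequence, alignment and interval I/O with a single coordinate convention.

All coordinates inside the package are 0-based, half-open.  SAM input
(1-based) and BED input (already 0-based half-open) are converted at this
boundary, so downstream overlap and anchoring arithmetic never mixes
conventions.

Sequences are uppercased on ingest and restricted to the closed DNA
alphabet {A, C, G, T, N}; the simulator and the aligner both assume this
alphabet.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# CIGAR operations that consume reference / query, per the SAM spec.
_REF_CONSUMING = frozenset("MDN=X")
_QRY_CONSUMING = frozenset("MIS=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence with optional per-base quality."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.id) or not self.id:
            raise ValueError(f"invalid record id {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a named reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SamRecord:
    """One alignment line of a SAM file, coordinates already 0-based."""

    qname: str
    flag: int
    rname: str
    pos0: int
    mapq: int
    cigar: str
    seq: str = "*"
    line: int | None = field(default=None, compare=False)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)


def _validate_seq(seq: str, line: int | None = None) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"non-DNA characters {sorted(bad)} in sequence", line=line
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    seq = seq.upper()
    if set(seq) - DNA_ALPHABET:
        raise ValueError(f"non-DNA characters in {seq[:30]!r}...")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; N counts in the denominator only."""
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file into records, uppercasing sequences.

    Raises :class:`FormatError` (with line number) on a sequence line
    before any header, an empty header, or a header with no sequence.
    """
    records: list[SeqRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        if not chunks:
            raise FormatError(f"record {header!r} has no sequence", line=header_line)
        records.append(SeqRecord(id=header, seq=_validate_seq("".join(chunks), header_line)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith(">"):
                flush()
                header = text[1:].split()[0] if len(text) > 1 else ""
                if not header:
                    raise FormatError("empty FASTA header", line=lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence before any FASTA header", line=lineno)
                chunks.append(text)
        flush()
    return records


def read_fastq(path: str | Path, dedup: bool = False) -> list[SeqRecord]:
    """Parse 4-line FASTQ records; quality retained.

    ``dedup`` keeps only the first record per id (re-basecalled read sets
    may repeat qnames); default keeps every record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # trailing blank lines are tolerated
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"FASTQ line count {len(lines)} is not a multiple of 4", line=len(lines)
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError("FASTQ record does not start with '@'", line=lineno)
        rid = head[1:].split()[0] if len(head) > 1 else ""
        if not rid:
            raise FormatError("empty FASTQ read id", line=lineno)
        if not plus.startswith("+"):
            raise FormatError("missing '+' separator line", line=lineno + 2)
        if len(qual) != len(seq):
            raise FormatError(
                f"quality length {len(qual)} != sequence length {len(seq)}",
                line=lineno + 3,
            )
        if dedup and rid in seen:
            continue
        seen.add(rid)
        records.append(SeqRecord(id=rid, seq=_validate_seq(seq, lineno + 1), qual=qual))
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def parse_sam(path: str | Path) -> list[SamRecord]:
    """Parse SAM text (header optional) into 0-based records.

    Unmapped records are retained (``is_unmapped`` true).  SEQ may be the
    ``*`` placeholder — read sequences are taken from FASTQ, keyed by
    qname, because supplementary alignments carry hard-clipped or absent
    sequence.
    """
    records: list[SamRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"SAM record has {len(fields)} fields (need >= 11)", line=lineno
                )
            try:
                flag = int(fields[1])
                pos1 = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"non-integer SAM field: {exc}", line=lineno) from exc
            if mapq > 60:
                raise FormatError(f"MapQ {mapq} > 60", line=lineno)
            pos0 = pos1 - 1
            if not (flag & 0x4) and pos0 < 0:
                raise FormatError("mapped record with POS < 1", line=lineno)
            records.append(
                SamRecord(
                    qname=fields[0],
                    flag=flag,
                    rname=fields[2],
                    pos0=max(pos0, 0),
                    mapq=mapq,
                    cigar=fields[5],
                    seq=fields[9],
                    line=lineno,
                )
            )
    return records


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs; validates ops."""
    if cigar == "*":
        return []
    pairs = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in pairs) != cigar:
        raise FormatError(f"invalid CIGAR {cigar!r}")
    return [(int(n), op) for n, op in pairs]


def ref_span(rec: SamRecord) -> GenomeInterval:
    """Reference interval consumed by a mapped record's CIGAR."""
    if rec.is_unmapped:
        raise ValueError(f"ref_span of unmapped record {rec.qname!r}")
    consumed = sum(n for n, op in parse_cigar(rec.cigar) if op in _REF_CONSUMING)
    if consumed == 0:
        raise FormatError(f"CIGAR {rec.cigar!r} consumes no reference")
    return GenomeInterval(rec.rname, rec.pos0, rec.pos0 + consumed)


def read_bed(path: str | Path) -> list[GenomeInterval]:
    """Parse BED3(+) into intervals (BED is already 0-based half-open)."""
    intervals: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED line has fewer than 3 fields", line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer BED coordinate: {exc}", line=lineno) from exc
            if start >= end:
                raise FormatError(f"BED start {start} >= end {end}", line=lineno)
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            intervals.append(GenomeInterval(fields[0], start, end, strand))
    return intervals


def write_tsv(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write a list of homogeneous dicts as a TSV table with header."""
    rows = list(rows)
    with open(path, "w") as fh:
        if not rows:
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    cols = lines[0].split("\t")
    return [dict(zip(cols, ln.split("\t"))) for ln in lines[1:]]


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
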