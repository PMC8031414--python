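"""Model/Results interface over the genotyping pipeline.

``RepeatGenotyper`` is constructed from data (reads, reference, locus,
optional alignments); ``fit()`` runs candidate selection, flank
anchoring, peak counting and mixture fitting, and returns a
``RepeatGenotypeResults`` carrying per-read calls, the fitted mixture,
the allele calls with read support, and a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import ScoringScheme
from .genotyper import (
    GenotypeCall,
    GenotypeParams,
    MixtureModel,
    SpanningCall,
    TargetLocus,
    extract_flanks,
    genotype_reads,
    select_on_target,
)
from .seqio import (
    GenomeInterval,
    SamRecord,
    SeqRecord,
    parse_sam,
    read_fasta,
    read_fastq,
    read_json,
)


def locus_from_dict(d: dict) -> TargetLocus:
    """Build a TargetLocus from config keys (chrom, target_start/_end,
    repeat_start/_end, motif)."""
    chrom = d["chrom"]
    return TargetLocus(
        chrom=chrom,
        target=GenomeInterval(chrom, int(d["target_start"]), int(d["target_end"])),
        repeat=GenomeInterval(chrom, int(d["repeat_start"]), int(d["repeat_end"])),
        motif=str(d["motif"]).upper(),
    )


class RepeatGenotyper:
    """Repeat copy-number genotyping model for one target locus.

    Parameters
    ----------
    reads
        Read records (FASTQ content, possibly several sets merged —
        including reads that failed basecalling, which never appear in
        the SAM).
    reference
        Reference sequence containing the locus.
    locus
        Target and repeat intervals plus the repeat motif.
    sam_records
        Optional alignments; when given, only reads whose alignments
        overlap the target by >= 1 bp are realigned (plus reads absent
        from the SAM entirely, which cannot be excluded by mapping).
        When omitted, every read is scanned.
    """

    def __init__(
        self,
        reads: Sequence[SeqRecord],
        reference: SeqRecord,
        locus: TargetLocus,
        sam_records: Sequence[SamRecord] | None = None,
        params: GenotypeParams | None = None,
        scheme: ScoringScheme | None = None,
    ):
        self.reads = list(reads)
        self.reference = reference
        self.locus = locus
        self.sam_records = list(sam_records) if sam_records is not None else None
        self.params = params or GenotypeParams()
        self.scheme = scheme or ScoringScheme()
        self.flanks = extract_flanks(reference, locus, self.params.flank_len)

    @classmethod
    def from_files(
        cls,
        reference_fasta: str | Path,
        fastq_paths: Iterable[str | Path],
        locus: TargetLocus | str | Path,
        sam_path: str | Path | None = None,
        params: GenotypeParams | None = None,
        scheme: ScoringScheme | None = None,
        dedup: bool = False,
    ) -> "RepeatGenotyper":
        reference = read_fasta(reference_fasta)[0]
        reads: list[SeqRecord] = []
        seen: set[str] = set()
        for path in fastq_paths:
            for rec in read_fastq(path, dedup=False):
                if dedup and rec.id in seen:
                    continue
                seen.add(rec.id)
                reads.append(rec)
        if not isinstance(locus, TargetLocus):
            locus = locus_from_dict(read_json(locus))
        sam = parse_sam(sam_path) if sam_path is not None else None
        return cls(reads, reference, locus, sam, params, scheme)

    def candidate_reads(self) -> list[SeqRecord]:
        """Reads passed to flank realignment.

        With a SAM: reads on-target by the >=1 bp overlap rule, plus any
        read absent from the SAM (it may have failed basecalling or
        mapping while still containing the repeat).  Without: all reads.
        """
        if self.sam_records is None:
            return self.reads
        on = select_on_target(self.sam_records, self.locus)
        in_sam = {r.qname for r in self.sam_records}
        return [r for r in self.reads if r.id in on or r.id not in in_sam]

    def fit(self) -> "RepeatGenotypeResults":
        candidates = self.candidate_reads()
        calls, mixture, genotype = genotype_reads(
            candidates,
            self.flanks,
            self.locus.motif_len,
            self.params,
            self.scheme,
        )
        return RepeatGenotypeResults(
            model=self,
            n_candidates=len(candidates),
            calls=calls,
            mixture=mixture,
            genotype=genotype,
        )


class RepeatGenotypeResults:
    """Fitted genotype for one locus.

    Attributes
    ----------
    calls : list of SpanningCall
    mixture : MixtureModel or None
    genotype : GenotypeCall or None
    """

    def __init__(
        self,
        model: RepeatGenotyper,
        n_candidates: int,
        calls: list[SpanningCall],
        mixture: MixtureModel | None,
        genotype: GenotypeCall | None,
    ):
        self.model = model
        self.n_candidates = n_candidates
        self.calls = calls
        self.mixture = mixture
        self.genotype = genotype

    @property
    def n_spanning(self) -> int:
        return len(self.calls)

    @property
    def copy_numbers(self) -> np.ndarray:
        return np.array([c.copy_number for c in self.calls])

    @property
    def alleles(self) -> tuple[int, ...]:
        return self.genotype.alleles if self.genotype else ()

    def spanning_table(self) -> pd.DataFrame:
        """Per-read spanning table (one row per anchored read)."""
        return pd.DataFrame(
            [
                {
                    "qname": c.qname,
                    "orientation": c.orientation,
                    "up_score": c.up_score,
                    "down_score": c.down_score,
                    "repeat_bp": c.repeat_bp,
                    "copy_number": c.copy_number,
                }
                for c in self.calls
            ]
        )

    def histogram_table(self) -> pd.DataFrame:
        """Copy-number histogram at the genotyping bin width."""
        if not self.calls:
            return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
        width = self.model.params.bin_width
        idx = np.floor(self.copy_numbers / width).astype(int)
        bins, counts = np.unique(idx, return_counts=True)
        return pd.DataFrame(
            {
                "bin_start": bins * width,
                "bin_end": (bins + 1) * width,
                "count": counts,
            }
        )

    def report_dict(self) -> dict:
        """Genotype report (JSON-serializable)."""
        out = {
            "n_candidates": self.n_candidates,
            "n_spanning": self.n_spanning,
            "alleles": list(self.alleles),
        }
        if self.mixture is not None and self.genotype is not None:
            n_on = self.n_candidates
            out.update(
                {
                    "k": self.mixture.k,
                    "means": list(self.mixture.means),
                    "variances": list(self.mixture.variances),
                    "weights": list(self.mixture.weights),
                    "loglik": self.mixture.loglik,
                    "converged": self.mixture.converged,
                    "support_frac_spanning": list(self.genotype.support_frac),
                    "support_frac_on_target": [
                        s * self.n_spanning / n_on if n_on else 0.0
                        for s in self.genotype.support_frac
                    ],
                    "n_expanded": self.genotype.n_expanded,
                }
            )
        return out

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Repeat copy-number genotype",
            "=" * 60,
            f"Locus: {self.model.locus.chrom}:"
            f"{self.model.locus.repeat.start}-{self.model.locus.repeat.end} "
            f"motif={self.model.locus.motif}",
            f"Candidate reads: {self.n_candidates}",
            f"Anchor-spanning reads: {self.n_spanning}",
        ]
        if self.mixture is None or self.genotype is None:
            lines.append("No spanning reads; genotype not estimable.")
            return "\n".join(lines)
        lines += [
            f"Mixture components: {self.mixture.k} "
            f"(loglik {self.mixture.loglik:.2f}, "
            f"{'converged' if self.mixture.converged else 'not converged'} "
            f"in {self.mixture.n_iter} iter)",
            "-" * 60,
            f"{'allele':>8} {'mean':>10} {'sd':>8} {'weight':>8} {'support':>9}",
        ]
        for a, m, v, w, s in zip(
            self.genotype.alleles,
            self.mixture.means,
            self.mixture.variances,
            self.mixture.weights,
            self.genotype.support_frac,
        ):
            lines.append(f"{a:>8d} {m:>10.2f} {np.sqrt(v):>8.2f} {w:>8.3f} {s:>8.1%}")
        lines.append("-" * 60)
        lines.append(
            f"Reads above expansion threshold "
            f"({self.model.params.expansion_threshold:g} copies): "
            f"{self.genotype.n_expanded}"
        )
        return "\n".join(lines)
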