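"""Shared fixtures: simulated runs (session-scoped, they drive several
test modules) and the hand-built SAM fixture used for QC exactness."""

import numpy as np
import pytest

from repeatspan.model import RepeatGenotyper
from repeatspan.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def exact_run():
    """Error-free biallelic run: alleles 9 and 749, no breakage, no
    off-target background, ~75 reads per allele."""
    cfg = SimConfig(
        alleles=((9, 0.5), (749, 0.5)),
        n_on_target_fragments=150,
        n_off_target_reads=0,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        breakage_per_base=0.0,
        seed=7,
    )
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def exact_results(exact_run):
    return RepeatGenotyper(exact_run.reads, exact_run.reference, exact_run.locus).fit()


@pytest.fixture(scope="session")
def noisy_run():
    """Trimodal mosaic-like run at default nanopore error rates."""
    cfg = SimConfig(
        alleles=((2, 1 / 3), (808, 1 / 3), (1538, 1 / 3)),
        n_on_target_fragments=240,
        n_off_target_reads=0,
        breakage_per_base=0.0,
        seed=11,
    )
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def noisy_results(noisy_run):
    return RepeatGenotyper(noisy_run.reads, noisy_run.reference, noisy_run.locus).fit()


def _seq(n, period="ACGT"):
    return (period * (n // len(period) + 1))[:n]


@pytest.fixture(scope="session")
def qc_sam(tmp_path_factory):
    """Ten-read SAM over target chrT:[1000,2000) with hand-computed QC
    statistics (see test_qc for the arithmetic)."""
    rows = [
        # qname flag pos1 mapq cigar seq
        ("r1", 0, 1000, 60, "2M", _seq(2)),          # 1 bp overlap -> on-target
        ("r2", 0, 901, 60, "100M", _seq(100, "AT")),  # ends at 1000, 0 bp overlap
        ("r3", 0, 1001, 60, "901M", "*"),             # covers 901 > 900 -> span90
        ("r4", 0, 1001, 60, "900M", "*"),             # covers 900, strict > fails
        ("r5", 0, 1001, 60, "500M", "*"),             # union with supplementary
        ("r5", 2048, 1501, 60, "500M", "*"),          #   covers all 1000 -> span90
        ("r6", 4, 0, 0, "*", "*"),                    # unmapped
        ("r7", 0, 1, 30, "300M", _seq(300, "GC")),    # off-target, low MapQ
        ("r8", 16, 5001, 60, "559M", _seq(559, "GGCA")),  # off-target
        ("r9", 0, 1101, 60, "50M100D50M", "*"),       # D consumes ref: 200 bp
        ("r10", 0, 1991, 60, "20M", _seq(20)),        # 10 bp overlap
    ]
    lines = ["@HD\tVN:1.6", "@SQ\tSN:chrT\tLN:10000"]
    for q, flag, pos, mapq, cigar, seq in rows:
        lines.append(f"{q}\t{flag}\tchrT\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*")
    path = tmp_path_factory.mktemp("qc") / "fixture.sam"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
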