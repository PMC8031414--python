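"""Affine-gap local alignment for flank realignment.

The genotyping pipeline realigns short reference flanks against each
candidate read to find anchor coordinates on either side of the repeat.
The aligner is a Gotoh three-matrix local dynamic program with affine gap
costs: a gap of length L costs ``gap_open + (L-1)*gap_extend`` (the first
gapped base pays the open penalty only).  Striped/SIMD layouts are an
optimization, not part of the contract — the contract is the score, the
coordinates, and the deterministic tie-breaking:

* among equal-scoring end cells, smallest query end, then smallest
  reference end wins;
* during traceback, diagonal beats a gap in the query (reference-consuming
  move), which beats a gap in the reference.

``oracle_align`` is an intentionally naive, unvectorized re-implementation
of the same recurrence, used to verify the production aligner on random
sequence pairs; it must stay independent of ``local_align``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import DNA_ALPHABET

_NEG = -(1 << 30)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Match reward and subtractive mismatch/gap penalties (all >= 0)."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


@dataclass(frozen=True)
class LocalAlignment:
    """Result of a local alignment of a query (read) against a reference
    (flank): score and 0-based half-open extents on both sequences.

    The CIGAR is query-centric: M consumes both sequences, I the query
    only, D the reference only.
    """

    score: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    cigar: str

    @property
    def is_empty(self) -> bool:
        return self.score == 0 and self.q_start == self.q_end


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = r.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    # pointers: H 0=stop 1=diag 2=E 3=F; E/F 0=open-from-H 1=extend
    pH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi < 4) else -mismatch
            diag = H[i - 1, j - 1] + s
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 0
            else:
                E[i, j] = e_ext
                pE[i, j] = 1
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 0
            else:
                F[i, j] = f_ext
                pF[i, j] = 1
            h = diag
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                H[i, j] = 0
                pH[i, j] = 0
            else:
                H[i, j] = h
                pH[i, j] = p
                if h > best:
                    best = h
                    bi = i
                    bj = j
    return H, pH, pE, pF, best, bi, bj


def local_align(query: str, ref: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Maximal-scoring local alignment of ``query`` vs ``ref``.

    Returns an empty alignment (score 0, zero-length extents) when no
    positive-scoring alignment exists.  Deterministic under the module's
    tie-breaking rule.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not query or not ref:
        raise ValueError("local_align requires non-empty sequences")
    if set(query.upper()) - DNA_ALPHABET or set(ref.upper()) - DNA_ALPHABET:
        raise ValueError("sequences must be over {A,C,G,T,N}")
    q = _encode(query)
    r = _encode(ref)
    _, pH, pE, pF, best, bi, bj = _sw_fill(
        q, r, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, "")

    ops: list[str] = []
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops.append("D")
            ext = pE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            ops.append("I")
            ext = pF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    ops.reverse()
    cigar_parts: list[str] = []
    k = 0
    while k < len(ops):
        run = k
        while run < len(ops) and ops[run] == ops[k]:
            run += 1
        cigar_parts.append(f"{run - k}{ops[k]}")
        k = run
    return LocalAlignment(
        score=int(best),
        q_start=int(i),
        q_end=int(bi),
        r_start=int(j),
        r_end=int(bj),
        cigar="".join(cigar_parts),
    )


def score_cigar(query: str, ref: str, aln: LocalAlignment, scheme: ScoringScheme) -> int:
    """Re-score a reported alignment from its CIGAR; used to verify that
    score, coordinates and CIGAR are mutually consistent."""
    import re

    qi, rj = aln.q_start, aln.r_start
    score = 0
    for num, op in re.findall(r"(\d+)([MID])", aln.cigar):
        n = int(num)
        if op == "M":
            for _ in range(n):
                a, b = query[qi].upper(), ref[rj].upper()
                score += scheme.match if (a == b and a != "N") else -scheme.mismatch
                qi += 1
                rj += 1
        elif op == "D":
            score -= scheme.gap_open + (n - 1) * scheme.gap_extend
            rj += n
        else:
            score -= scheme.gap_open + (n - 1) * scheme.gap_extend
            qi += n
    if qi != aln.q_end or rj != aln.r_end:
        raise ValueError("CIGAR does not reach the reported alignment ends")
    return score


def oracle_align(query: str, ref: str, scheme: ScoringScheme | None = None) -> int:
    """Exact maximal local alignment score by plain exhaustive DP.

    Three dense matrices (M / gap-in-query / gap-in-reference), no
    vectorization, intended for short sequences only.  Serves as the
    independent oracle for :func:`local_align`.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not query or not ref:
        raise ValueError("oracle_align requires non-empty sequences")
    q = query.upper()
    r = ref.upper()
    n, m = len(q), len(r)
    neg = float("-inf")
    Hrow = [0.0] * (m + 1)
    Erow = [neg] * (m + 1)
    Frow = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        prev_H = Hrow
        prev_F = Frow
        Hrow = [0.0] * (m + 1)
        Erow = [neg] * (m + 1)
        Frow = [neg] * (m + 1)
        for j in range(1, m + 1):
            match = q[i - 1] == r[j - 1] and q[i - 1] != "N"
            s = scheme.match if match else -scheme.mismatch
            Erow[j] = max(Hrow[j - 1] - scheme.gap_open, Erow[j - 1] - scheme.gap_extend)
            Frow[j] = max(prev_H[j] - scheme.gap_open, prev_F[j] - scheme.gap_extend)
            h = max(0.0, prev_H[j - 1] + s, Erow[j], Frow[j])
            Hrow[j] = h
            if h > best:
                best = h
    return int(best)
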