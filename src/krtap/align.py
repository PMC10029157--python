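"""Pairwise local alignment with affine gaps and Expect-value statistics.

The in-package replacement for one-on-one BLAST-style protein comparisons:
exact Smith-Waterman dynamic programming (no word seeding, no
low-complexity masking, no compositional adjustment) under a
:class:`~krtap.scoring.ScoringScheme`, reporting raw score, bit score,
Expect value over the full m*n search space, percent identity and the
aligned strings.  Also provides ungapped dot-plot segment extraction for
visualising repeat structure.

A gap run of length L costs ``gap_open + gap_extend * (L - 1)``.
Determinism: among co-optimal alignments the one with the smallest query
end, then smallest subject end, is reported; traceback prefers diagonal,
then vertical (gap in subject), then horizontal moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scoring import ScoringScheme
from .seqstore import SequenceRecord

_NEG = np.int64(-(10**15))


@dataclass(frozen=True)
class LocalAlignment:
    """A scored optimal local alignment between two sequences.

    Spans are 1-based inclusive; `m` and `n` are the *full* query/subject
    lengths (the search-space factors of the Expect value).  A raw score of
    0 denotes "no significant local match": empty alignment, zero-length
    spans.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str
    identities: int
    alignment_length: int
    percent_identity: float
    m: int
    n: int

    @property
    def is_empty(self) -> bool:
        return self.alignment_length == 0


@njit(cache=True)
def _sw_fill(a, b, matrix, gap_open, gap_extend):  # pragma: no cover - numba
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # ends with gap in query row
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # ends with gap in subject col
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            ee = E[i, j - 1] - gap_extend
            if ee > e:
                e = ee
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            ff = F[i - 1, j] - gap_extend
            if ff > f:
                f = ff
            F[i, j] = f
            h = H[i - 1, j - 1] + matrix[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _sw_score(a, b, matrix, gap_open, gap_extend):  # pragma: no cover - numba
    """Score-only Smith-Waterman with two rolling rows (for batch search)."""
    m = a.shape[0]
    n = b.shape[0]
    Hprev = np.zeros(n + 1, dtype=np.int64)
    Hcur = np.zeros(n + 1, dtype=np.int64)
    Fprev = np.full(n + 1, _NEG, dtype=np.int64)
    Fcur = np.full(n + 1, _NEG, dtype=np.int64)
    best = np.int64(0)
    for i in range(1, m + 1):
        ai = a[i - 1]
        e = _NEG
        Hcur[0] = 0
        for j in range(1, n + 1):
            enew = Hcur[j - 1] - gap_open
            eext = e - gap_extend
            e = enew if enew > eext else eext
            fnew = Hprev[j] - gap_open
            fext = Fprev[j] - gap_extend
            f = fnew if fnew > fext else fext
            Fcur[j] = f
            h = Hprev[j - 1] + matrix[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
        Fprev, Fcur = Fcur, Fprev
    return best


def raw_local_score(query: SequenceRecord, subject: SequenceRecord,
                    scheme: ScoringScheme) -> int:
    """Optimal local alignment raw score only (fast path for searches)."""
    a = scheme.encode(query.residues)
    b = scheme.encode(subject.residues)
    return int(_sw_score(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend))


def _traceback(a_str: str, b_str: str, H, E, F, bi: int, bj: int,
               scheme: ScoringScheme) -> tuple[str, str, int, int]:
    """Walk back from the best cell; returns aligned strings and start coords."""
    go, ge = scheme.gap_open, scheme.gap_extend
    qa: list[str] = []
    qb: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + scheme.score_pair(a_str[i - 1], b_str[j - 1])
            if H[i, j] == diag:
                qa.append(a_str[i - 1])
                qb.append(b_str[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject: consume a[i]
            qa.append(a_str[i - 1])
            qb.append("-")
            close = H[i - 1, j] - go
            if F[i, j] == close:  # prefer closing the gap
                state = "H"
            else:
                assert F[i, j] == F[i - 1, j] - ge
            i -= 1
        else:  # state == "E": gap in query: consume b[j]
            qa.append("-")
            qb.append(b_str[j - 1])
            close = H[i, j - 1] - go
            if E[i, j] == close:
                state = "H"
            else:
                assert E[i, j] == E[i, j - 1] - ge
            j -= 1
    qa.reverse()
    qb.reverse()
    return "".join(qa), "".join(qb), i + 1, j + 1


def local_align(query: SequenceRecord, subject: SequenceRecord,
                scheme: ScoringScheme) -> LocalAlignment:
    """Maximum-scoring local alignment of two protein records.

    Returns a :class:`LocalAlignment`; if no positive-scoring local pairing
    exists the result is the empty alignment with raw score 0.
    """
    a = scheme.encode(query.residues)
    b = scheme.encode(subject.residues)
    H, E, F, best, bi, bj = _sw_fill(
        a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    m, n = len(a), len(b)
    best = int(best)
    if best == 0:
        return LocalAlignment(
            query_id=query.id, subject_id=subject.id,
            raw_score=0, bit_score=scheme.bit_score(0),
            evalue=scheme.evalue(0, m, n),
            query_span=(0, 0), subject_span=(0, 0),
            aligned_query="", aligned_subject="",
            identities=0, alignment_length=0, percent_identity=0.0,
            m=m, n=n,
        )
    aq, ab, qstart, sstart = _traceback(
        query.residues, subject.residues, H, E, F, bi, bj, scheme
    )
    identities = sum(1 for x, y in zip(aq, ab) if x == y and x != "-")
    alen = len(aq)
    return LocalAlignment(
        query_id=query.id, subject_id=subject.id,
        raw_score=best,
        bit_score=scheme.bit_score(best),
        evalue=scheme.evalue(best, m, n),
        query_span=(qstart, bi), subject_span=(sstart, bj),
        aligned_query=aq, aligned_subject=ab,
        identities=identities, alignment_length=alen,
        percent_identity=100.0 * identities / alen,
        m=m, n=n,
    )


def percent_identity_no_filter(a: SequenceRecord, b: SequenceRecord,
                               scheme: ScoringScheme) -> float:
    """Percent identity of the optimal local alignment, no masking.

    This mirrors a two-sequence comparison run with the low-complexity
    filter off and no compositional adjustment, the only mode in which a
    percent identity is meaningful for highly repetitive proteins.
    """
    return local_align(a, b, scheme).percent_identity


@dataclass(frozen=True)
class DotSegment:
    """A maximal ungapped diagonal segment of a dot plot (1-based spans)."""

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    score: int
    bit_score: float

    def __len__(self) -> int:
        return self.query_span[1] - self.query_span[0] + 1


def dotplot_segments(a: SequenceRecord, b: SequenceRecord,
                     scheme: ScoringScheme, min_bits: float) -> list[DotSegment]:
    """All maximal positive ungapped diagonal segments with >= `min_bits`.

    Each diagonal of the comparison matrix is partitioned into maximal runs
    of positive cumulative score (the cumulative sum is reset whenever it
    drops to zero or below); the maximum-sum segment of each run is
    reported if its bit score reaches `min_bits`.  Repetitive sequences
    produce the characteristic checkerboard of off-diagonal segments.
    """
    if min_bits <= 0:
        raise ValueError("min_bits must be positive")
    ca = scheme.encode(a.residues)
    cb = scheme.encode(b.residues)
    m, n = len(ca), len(cb)
    segments: list[DotSegment] = []
    for d in range(-(m - 1), n):
        i0 = max(0, -d)   # 0-based query index at diagonal start
        j0 = i0 + d
        length = min(m - i0, n - j0)
        cur = 0
        run_start = 0
        best_sum = 0
        best_end = -1
        for k in range(length + 1):
            s = (
                int(scheme.matrix[ca[i0 + k], cb[j0 + k]])
                if k < length
                else None
            )
            if s is None or cur + s <= 0:
                if best_end >= run_start and best_sum > 0:
                    bits = scheme.bit_score(best_sum)
                    if bits >= min_bits:
                        segments.append(DotSegment(
                            query_span=(i0 + run_start + 1, i0 + best_end + 1),
                            subject_span=(j0 + run_start + 1, j0 + best_end + 1),
                            score=best_sum,
                            bit_score=bits,
                        ))
                cur = 0
                run_start = k + 1
                best_sum = 0
                best_end = -1
            else:
                cur += s
                if cur > best_sum:
                    best_sum = cur
                    best_end = k
    segments.sort(key=lambda seg: (seg.query_span[0], seg.subject_span[0]))
    return segments
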