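"""Independent oracles used by the test suite.

Each oracle re-derives an expected value by a route disjoint from the
implementation it checks: plain recursive enumeration of gapped pairings
(optionally memoised) for local alignment, Biopython's PairwiseAligner as
a third-party aligner, full enumeration of rank assignments for the
Mann-Whitney null, position-marking for GYG coverage, and an explicit
split scan for caterpillar-tree bipartition purity.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

# --- local alignment ------------------------------------------------------


def enum_local_score(a: str, b: str, scheme) -> int:
    """Best local score by brute-force enumeration of every gapped pairing.

    Explores every monotone extension path from every start cell, charging
    a gap run of length L as open + ext*(L-1); a path may stop anywhere
    (score floor 0).  Exponential — only for very short sequences.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(a), len(b)

    def extend(i: int, k: int, last: str) -> int:
        best = 0  # stopping here is always allowed
        if i < m and k < n:
            best = max(best, scheme.score_pair(a[i], b[k])
                       + extend(i + 1, k + 1, "M"))
        if i < m:
            cost = ge if last == "X" else go
            best = max(best, -cost + extend(i + 1, k, "X"))
        if k < n:
            cost = ge if last == "Y" else go
            best = max(best, -cost + extend(i, k + 1, "Y"))
        return best

    best = 0
    for i in range(m):
        for k in range(n):
            best = max(best, extend(i, k, "M"))
    return best


def memo_local_score(a: str, b: str, scheme) -> int:
    """Same recursion as :func:`enum_local_score` with memoisation.

    Validated against the pure enumeration on small cases, then used for
    the larger exhaustive sweeps.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(a), len(b)

    @lru_cache(maxsize=None)
    def extend(i: int, k: int, last: str) -> int:
        best = 0
        if i < m and k < n:
            best = max(best, scheme.score_pair(a[i], b[k])
                       + extend(i + 1, k + 1, "M"))
        if i < m:
            best = max(best, -(ge if last == "X" else go)
                       + extend(i + 1, k, "X"))
        if k < n:
            best = max(best, -(ge if last == "Y" else go)
                       + extend(i, k + 1, "Y"))
        return best

    best = 0
    for i in range(m):
        for k in range(n):
            best = max(best, extend(i, k, "M"))
    return best


def biopython_local_score(a: str, b: str, gap_open: int = 11,
                          gap_extend: int = 1) -> float:
    """Optimal local score from Biopython's PairwiseAligner (BLOSUM62)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner.score(a, b)


# --- Mann-Whitney ---------------------------------------------------------


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """(U of x, exact two-sided p) by enumerating all rank assignments.

    Requires tie-free data.  The two-sided p-value is the null probability
    of a U at least as far from its mean n1*n2/2 as the observed one.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    total = 0
    extreme = 0
    for positions in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(positions) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


# --- GYG coverage ---------------------------------------------------------


def gyg_coverage_marking(residues: str) -> float:
    """Fraction of positions covered by any GYG triple, by marking."""
    marked = set()
    for i in range(len(residues) - 2):
        if residues[i:i + 3] == "GYG":
            marked.update((i, i + 1, i + 2))
    return len(marked) / len(residues)


# --- caterpillar-tree purity ---------------------------------------------


def caterpillar_purity(leaf_order: list[str], labels: dict[str, str]) -> float:
    """Best split purity over the internal edges of a caterpillar tree.

    A caterpillar with leaves L1..Ln (Newick
    ``(L1,(L2,(...,(Ln-1,Ln))))``) has internal edges inducing exactly the
    splits {L1..Lk} vs rest for k = 1..n-1; scan them all directly.
    """
    values = sorted(set(labels.values()))
    total = len(leaf_order)
    best = 0.0
    for k in range(1, total):
        left = leaf_order[:k]
        right = leaf_order[k:]
        score = (
            max(sum(1 for l in left if labels[l] == v) for v in values)
            + max(sum(1 for l in right if labels[l] == v) for v in values)
        ) / total
        best = max(best, score)
    return best


# --- misc -----------------------------------------------------------------


def evalue_closed_form(kappa: float, lam: float, score: float,
                       m: int, n: int) -> float:
    return kappa * m * n * math.exp(-lam * score)
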