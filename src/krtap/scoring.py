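"""Substitution scoring and Karlin-Altschul alignment statistics.

A :class:`ScoringScheme` bundles everything needed to score a gapped local
alignment and convert its raw score into a bit score and an Expect value:

* a symmetric substitution matrix (BLOSUM62 by default, via Biopython),
* affine gap costs in the BLAST convention named by existence/extension,
  where a gap run of length L costs ``gap_open + gap_extend * (L - 1)``,
* the Karlin-Altschul parameters lambda (nats per score unit) and K, and
* background residue frequencies (Robinson & Robinson by default).

For gapped BLOSUM62/11/1 scoring, lambda and K are not derivable in closed
form; the standard published values 0.267 and 0.041 are the defaults.  For
*ungapped* scoring the pair (lambda, K) is computable, and
:func:`solve_ungapped_lambda` finds the unique positive root of

    sum_ij  p_i p_j exp(lambda * s_ij) = 1,

which serves as a sanity check on any configured lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

LN2 = math.log(2.0)

#: Amino-acid alphabet accepted everywhere: the 20 standard residues plus
#: ambiguity/rare letters B, Z, X and selenocysteine U.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZXU"

#: The 20 standard residues (order matches the BLOSUM62 matrix header).
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

# Robinson & Robinson (1991) background amino-acid frequencies, the
# composition BLAST uses for its null model.
ROBINSON_FREQUENCIES = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def _blosum62_matrix(alphabet: str) -> np.ndarray:
    """BLOSUM62 scores over `alphabet` as an integer array.

    Letters absent from Biopython's BLOSUM62 header (only U here) are scored
    through the X column, the catch-all ambiguity scoring.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    known = set(blosum.alphabet)
    n = len(alphabet)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(alphabet):
        aa = a if a in known else "X"
        for j, b in enumerate(alphabet):
            bb = b if b in known else "X"
            mat[i, j] = int(blosum[aa, bb])
    return mat


@dataclass
class ScoringScheme:
    """Scoring parameters for local alignment and E-value statistics.

    Parameters
    ----------
    alphabet:
        Residue letters; row/column order of `matrix`.
    matrix:
        Symmetric integer substitution scores, shape (len(alphabet),) ** 2.
    gap_open:
        Cost charged for the first position of a gap run (BLAST "existence").
    gap_extend:
        Cost per additional gap position.
    lam, kappa:
        Karlin-Altschul lambda (nats per raw-score unit) and K for the
        configured (matrix, gap) regime.
    background:
        Background residue frequencies over `alphabet` (zero-padded for
        ambiguity letters); sums to 1.
    """

    alphabet: str
    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041
    background: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        n = len(self.alphabet)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")
        if self.background is None:
            bg = np.zeros(n)
            for i, a in enumerate(self.alphabet):
                bg[i] = ROBINSON_FREQUENCIES.get(a, 0.0)
            bg /= bg.sum()
            self.background = bg
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (n,):
                raise ValueError("background length does not match alphabet")
            if abs(self.background.sum() - 1.0) > 1e-6:
                raise ValueError("background frequencies must sum to 1")
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    @classmethod
    def blosum62(cls, gap_open: int = 11, gap_extend: int = 1) -> "ScoringScheme":
        """The paper-default scheme: BLOSUM62, existence 11, extension 1."""
        return cls(
            alphabet=PROTEIN_ALPHABET,
            matrix=_blosum62_matrix(PROTEIN_ALPHABET),
            gap_open=gap_open,
            gap_extend=gap_extend,
        )

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to integer codes; raises on unscorable letters."""
        try:
            return np.fromiter(
                (self._index[c] for c in residues), dtype=np.int64, count=len(residues)
            )
        except KeyError:
            for pos, c in enumerate(residues, start=1):
                if c not in self._index:
                    raise ValueError(
                        f"unscorable residue {c!r} at position {pos}"
                    ) from None
            raise  # pragma: no cover

    def score_pair(self, a: str, b: str) -> int:
        return int(self.matrix[self._index[a], self._index[b]])

    def expected_score(self) -> float:
        """Expected per-position score under the background composition."""
        p = self.background
        return float(p @ self.matrix @ p)

    def bit_score(self, raw_score: float) -> float:
        """S' = (lambda * S - ln K) / ln 2."""
        return (self.lam * raw_score - math.log(self.kappa)) / LN2

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        """E = K * m * n * exp(-lambda * S), the expected chance-hit count.

        `m` and `n` are the full query/subject lengths (no length
        adjustment, matching a search with compositional adjustments off).
        """
        if m < 1 or n < 1:
            raise ValueError("sequence lengths must be >= 1")
        return self.kappa * m * n * math.exp(-self.lam * raw_score)


def solve_ungapped_lambda(scheme: ScoringScheme, tol: float = 1e-12) -> float:
    """Unique positive root lambda* of  sum_ij p_i p_j exp(lambda s_ij) = 1.

    Only letters with nonzero background frequency participate.  Requires a
    valid ungapped scoring regime: negative expected score with at least one
    positive entry; otherwise no positive root exists and a ValueError is
    raised.  Solved by Brent's method on a bracketing interval; the residual
    at the returned root is below 1e-10.
    """
    p = scheme.background
    live = p > 0
    pp = np.outer(p[live], p[live])
    s = scheme.matrix[np.ix_(live, live)].astype(float)
    if float((pp * s).sum()) >= 0:
        raise ValueError("expected score must be negative (no positive root)")
    if s.max() <= 0:
        raise ValueError("matrix has no positive score (no positive root)")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    # f(0) = 0 with f'(0) < 0; walk right until f > 0 to bracket the root.
    lo = 1e-6
    while f(lo) >= 0:  # pathological: root below 1e-6
        lo /= 10.0
        if lo < 1e-300:  # pragma: no cover
            raise ValueError("failed to bracket lambda")
    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover
            raise ValueError("failed to bracket lambda")
    root = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)
    assert abs(f(root)) < 1e-10
    return float(root)
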