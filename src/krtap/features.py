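"""Sequence-feature diagnostics of the two KRTAP lineages.

KRTAPs fall into compositional classes: ultra-high sulphur (UHS) and high
sulphur (HS) proteins owe their sulphur to cysteine, while the high
glycine-tyrosine (HGT) class is dominated by G/Y.  The occludin-derived (O)
lineage is characterised by the GYG triplet — almost every O-lineage member
has at least one seventh of its residues inside a GYG occurrence — while
metallothionein-derived (M) proteins carry tandem low-complexity repeats of
five-residue CC-prefixed units, and the KRTAP5 sub-family carries the
diagnostic motif CCCKPVCC (once CCCKPMCC).  This module computes those
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqstore import SequenceRecord

GYG = "GYG"
DEFAULT_MOTIFS = ("CCCKPVCC", "CCCKPMCC")

#: Compositional class thresholds (fractions of residues).  These cut-offs
#: are package conventions — compositional class lists in the literature
#: come from curated databases — chosen so that metallothionein-like
#: (cysteine-rich) sequences classify UHS/HS and GYG-rich sequences HGT.
DEFAULT_THRESHOLDS = {"t_uhs": 0.30, "t_hs": 0.15, "t_gy": 0.30}


@dataclass(frozen=True)
class RepeatHit:
    """Non-overlapping occurrences of one repeated k-mer unit."""

    unit: str
    k: int
    count: int
    positions: tuple[int, ...]  # 1-based starts, strictly increasing, gaps >= k


@dataclass(frozen=True)
class FeatureProfile:
    protein_id: str
    length: int
    cys_count: int
    cys_fraction: float
    gly_tyr_fraction: float
    gyg_coverage: float
    gyg_pass: bool
    motif_hits: tuple[tuple[str, int], ...]
    repeat_units: tuple[RepeatHit, ...]
    total_repeats: int
    longest_gy_run: int
    sulphur_group: str = "other"


def composition(seq: SequenceRecord) -> tuple[int, float, float]:
    """(cysteine count, cysteine fraction, glycine+tyrosine fraction)."""
    r = seq.residues
    n = len(r)
    cys = r.count("C")
    gy = r.count("G") + r.count("Y")
    return cys, cys / n, gy / n


def gyg_coverage(seq: SequenceRecord) -> tuple[float, bool]:
    """Fraction of residues covered by any (overlapping) GYG occurrence.

    The pass criterion is coverage >= 1/7 — the "one-seventh or more of
    their amino acids in a GYG triplet" diagnostic of the O lineage.
    """
    r = seq.residues
    covered = [False] * len(r)
    start = r.find(GYG)
    while start != -1:
        for p in range(start, start + 3):
            covered[p] = True
        start = r.find(GYG, start + 1)
    cov = sum(covered) / len(r)
    return cov, cov >= 1.0 / 7.0


def find_motifs(seq: SequenceRecord,
                motifs: tuple[str, ...] = DEFAULT_MOTIFS) -> list[tuple[str, int]]:
    """All (possibly overlapping) exact motif occurrences, 1-based."""
    if not motifs:
        raise ValueError("motifs must be non-empty")
    hits = []
    for motif in motifs:
        start = seq.residues.find(motif)
        while start != -1:
            hits.append((motif, start + 1))
            start = seq.residues.find(motif, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def find_repeats(seq: SequenceRecord, k: int = 5, prefix: str = "CC",
                 min_count: int = 2) -> list[RepeatHit]:
    """Repeated k-mer units (CC-prefixed by default) in a sequence.

    For each distinct k-mer starting with `prefix` (pass ``prefix=""`` to
    consider every k-mer), occurrences are placed greedily left-to-right
    without overlap; units placed at least `min_count` times are reported,
    sorted by descending count then unit.  The pooled total over units is
    exposed via :func:`total_repeat_count` / ``FeatureProfile.total_repeats``.
    """
    r = seq.residues
    if not (2 <= k <= len(r)):
        raise ValueError("require 2 <= k <= sequence length")
    if len(prefix) >= k:
        raise ValueError("prefix must be shorter than k")
    units = sorted({
        r[i:i + k] for i in range(len(r) - k + 1)
        if r[i:i + k].startswith(prefix)
    })
    hits = []
    for unit in units:
        positions = []
        i = r.find(unit)
        while i != -1:
            positions.append(i + 1)
            i = r.find(unit, i + k)  # greedy non-overlapping placement
        if len(positions) >= min_count:
            hits.append(RepeatHit(unit=unit, k=k, count=len(positions),
                                  positions=tuple(positions)))
    hits.sort(key=lambda h: (-h.count, h.unit))
    return hits


def total_repeat_count(hits: list[RepeatHit]) -> int:
    """Pooled non-overlapping placements across all repeated units."""
    return sum(h.count for h in hits)


def longest_pair_run(seq: SequenceRecord, pair: str = "GY") -> int:
    """Length of the longest contiguous chain of `pair`, in residues.

    A chain is a concatenation of the two-letter pair, optionally ending in
    a single trailing first letter, so "GYG" counts 3 — the convention
    under which an odd-length GYGY...G triplet chain is fully counted.
    Returns 0 if the pair never occurs.
    """
    if len(pair) != 2:
        raise ValueError("pair must be exactly two residues")
    r = seq.residues
    x, y = pair[0], pair[1]
    best = 0
    i = 0
    n = len(r)
    while i < n - 1:
        if r[i] == x and r[i + 1] == y:
            j = i
            while j + 1 < n and r[j] == x and r[j + 1] == y:
                j += 2
            run = j - i  # full pairs
            if j < n and r[j] == x:  # trailing single first letter
                run += 1
            best = max(best, run)
            i = j
        else:
            i += 1
    return best


def classify_sulphur_group(cys_fraction: float, gly_tyr_fraction: float,
                           thresholds: dict | None = None) -> str:
    """Total classification into UHS / HS / HGT / other by composition."""
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    if cys_fraction >= t["t_uhs"]:
        return "UHS"
    if cys_fraction >= t["t_hs"]:
        return "HS"
    if gly_tyr_fraction >= t["t_gy"]:
        return "HGT"
    return "other"


def profile(seq: SequenceRecord, k: int = 5, prefix: str = "CC",
            motifs: tuple[str, ...] = DEFAULT_MOTIFS,
            thresholds: dict | None = None) -> FeatureProfile:
    """Full :class:`FeatureProfile` for one sequence."""
    cys, cys_frac, gy_frac = composition(seq)
    cov, ok = gyg_coverage(seq)
    repeats = tuple(find_repeats(seq, k=k, prefix=prefix)) if len(seq) >= k else ()
    return FeatureProfile(
        protein_id=seq.id,
        length=len(seq),
        cys_count=cys,
        cys_fraction=cys_frac,
        gly_tyr_fraction=gy_frac,
        gyg_coverage=cov,
        gyg_pass=ok,
        motif_hits=tuple(find_motifs(seq, motifs)),
        repeat_units=repeats,
        total_repeats=total_repeat_count(list(repeats)),
        longest_gy_run=longest_pair_run(seq),
        sulphur_group=classify_sulphur_group(cys_frac, gy_frac, thresholds),
    )
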