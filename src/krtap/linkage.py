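"""Harvest rules and O/M lineage assignment.

The classification procedure for tracing KRTAP ancestry works in two rounds
over an all-against-one search of a proteome:

1. *Direct* assignment.  Each candidate bait (occludin for the O lineage,
   a metallothionein for the M lineage) is searched against the proteome.
   The top ``top_n`` ranked subjects form the **linked** set of that bait;
   the subset with Expect value <= ``similar_threshold`` is the **similar**
   set.  A KRTAP found in exactly one bait's linked set gets the direct
   label of that lineage.  A KRTAP linked to both baits contradicts the
   disjointness the procedure relies on and is surfaced as an error.

2. *Indirect* assignment.  Each still-unlabelled KRTAP is itself used as a
   bait; directly-labelled KRTAPs among its sub-threshold hits vote for a
   lineage.  Hits to one lineage only give ``O_indirect``/``M_indirect``,
   hits to both give ``dual_indirect``, none leaves the protein
   ``unlinked``.  Exactly one indirect round is performed.

Ranking is by ascending Expect value with ties broken by descending bit
score then lexicographic subject id, so assignment tables are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .align import raw_local_score
from .scoring import ScoringScheme
from .seqstore import SequenceRecord, SequenceStore

#: Paper-protocol defaults: top-500 rank harvest, similarity at E <= 1e-3,
#: search Expect ceiling 200000.
DEFAULT_TOP_N = 500
DEFAULT_SIMILAR_THRESHOLD = 1e-3
DEFAULT_EXPECT_CEILING = 200000.0


class Label(str, Enum):
    O_DIRECT = "O_direct"
    M_DIRECT = "M_direct"
    O_INDIRECT = "O_indirect"
    M_INDIRECT = "M_indirect"
    DUAL_INDIRECT = "dual_indirect"
    UNLINKED = "unlinked"

    @property
    def lineage(self) -> str:
        """'O', 'M', 'dual' or 'none' — the lineage this label implies."""
        if self in (Label.O_DIRECT, Label.O_INDIRECT):
            return "O"
        if self in (Label.M_DIRECT, Label.M_INDIRECT):
            return "M"
        if self is Label.DUAL_INDIRECT:
            return "dual"
        return "none"


@dataclass(frozen=True)
class SearchHit:
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    rank: int


@dataclass(frozen=True)
class SearchResult:
    bait_id: str
    hits: tuple[SearchHit, ...]
    db_size: int

    def hit(self, subject_id: str) -> SearchHit | None:
        for h in self.hits:
            if h.subject_id == subject_id:
                return h
        return None


@dataclass(frozen=True)
class LineageAssignment:
    protein_id: str
    label: Label
    evidence: tuple[tuple[str, float], ...] = field(default_factory=tuple)


def search(bait: SequenceRecord, db: SequenceStore, scheme: ScoringScheme,
           expect_ceiling: float = DEFAULT_EXPECT_CEILING) -> SearchResult:
    """Rank every db record against the bait by Expect value.

    One hit per db record with E <= `expect_ceiling` (the bait's own entry,
    if present, simply ranks first).  m is the bait length and n the
    subject length.
    """
    if len(db) == 0:
        raise ValueError("search database is empty")
    m = len(bait)
    scored = []
    for rec in db:
        s = raw_local_score(bait, rec, scheme)
        e = scheme.evalue(s, m, len(rec))
        if e <= expect_ceiling:
            scored.append((e, -scheme.bit_score(s), rec.id, s))
    scored.sort()
    hits = tuple(
        SearchHit(subject_id=rid, raw_score=s, bit_score=-negbits,
                  evalue=e, rank=rank)
        for rank, (e, negbits, rid, s) in enumerate(scored, start=1)
    )
    return SearchResult(bait_id=bait.id, hits=hits, db_size=len(db))


def linked_set(result: SearchResult, top_n: int = DEFAULT_TOP_N) -> set[str]:
    """The 'linked to the bait' harvest: the top `top_n` ranked subjects."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    return {h.subject_id for h in result.hits[:top_n]}


def similar_set(result: SearchResult,
                threshold: float = DEFAULT_SIMILAR_THRESHOLD) -> set[str]:
    """The 'similar in sequence' harvest: subjects with E <= `threshold`."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {h.subject_id for h in result.hits if h.evalue <= threshold}


class DirectOverlapError(ValueError):
    """A KRTAP fell in both baits' linked sets (disjointness violated)."""

    def __init__(self, overlap: set[str]):
        self.overlap = sorted(overlap)
        super().__init__(
            "KRTAPs linked to both baits (expected disjoint direct sets): "
            + ", ".join(self.overlap)
        )


def assign_direct(occludin_result: SearchResult, mt_result: SearchResult,
                  krtap_ids: set[str],
                  top_n: int = DEFAULT_TOP_N) -> list[LineageAssignment]:
    """Directly-linked O/M labels from the two ancestor-bait searches.

    Only ids in `krtap_ids` are labelled; bait self-hits are ignored.  Ids
    in neither linked set are left out (they go to the indirect round).
    """
    if not krtap_ids:
        raise ValueError("krtap_ids must be non-empty")
    o_linked = linked_set(occludin_result, top_n) & krtap_ids
    m_linked = linked_set(mt_result, top_n) & krtap_ids
    o_linked.discard(occludin_result.bait_id)
    m_linked.discard(mt_result.bait_id)
    overlap = o_linked & m_linked
    if overlap:
        raise DirectOverlapError(overlap)
    out = []
    for pid in sorted(o_linked):
        hit = occludin_result.hit(pid)
        out.append(LineageAssignment(
            pid, Label.O_DIRECT, ((occludin_result.bait_id, hit.evalue),)
        ))
    for pid in sorted(m_linked):
        hit = mt_result.hit(pid)
        out.append(LineageAssignment(
            pid, Label.M_DIRECT, ((mt_result.bait_id, hit.evalue),)
        ))
    return out


def assign_indirect(unlabelled: set[str], db: SequenceStore,
                    direct: list[LineageAssignment], scheme: ScoringScheme,
                    top_n: int = DEFAULT_TOP_N,
                    threshold: float = DEFAULT_SIMILAR_THRESHOLD,
                    expect_ceiling: float = DEFAULT_EXPECT_CEILING,
                    rule: str = "similar") -> list[LineageAssignment]:
    """Second-round labels for KRTAPs not directly linked to either bait.

    Each unlabelled protein is used as bait against `db`; the directly-
    labelled KRTAPs among its harvest decide its lineage.  With
    ``rule="similar"`` (default) a vote requires E <= `threshold` within
    the top `top_n`; with ``rule="linked"`` bare top-`top_n` co-occurrence
    suffices.
    """
    if rule not in ("similar", "linked"):
        raise ValueError(f"unknown indirect rule {rule!r}")
    direct_label = {a.protein_id: a.label for a in direct}
    out = []
    for pid in sorted(unlabelled):
        bait = db.lookup(pid)
        result = search(bait, db, scheme, expect_ceiling)
        top_hits = [h for h in result.hits[:top_n] if h.subject_id != pid]
        if rule == "similar":
            top_hits = [h for h in top_hits if h.evalue <= threshold]
        o_ev = [(h.subject_id, h.evalue) for h in top_hits
                if direct_label.get(h.subject_id) is Label.O_DIRECT]
        m_ev = [(h.subject_id, h.evalue) for h in top_hits
                if direct_label.get(h.subject_id) is Label.M_DIRECT]
        if o_ev and m_ev:
            label = Label.DUAL_INDIRECT
            evidence = (o_ev[0], m_ev[0])
        elif o_ev:
            label, evidence = Label.O_INDIRECT, (o_ev[0],)
        elif m_ev:
            label, evidence = Label.M_INDIRECT, (m_ev[0],)
        else:
            label, evidence = Label.UNLINKED, ()
        out.append(LineageAssignment(pid, label, tuple(evidence)))
    return out


def classify(occludin_bait: SequenceRecord, mt_bait: SequenceRecord,
             db: SequenceStore, krtap_ids: set[str], scheme: ScoringScheme,
             top_n: int = DEFAULT_TOP_N,
             threshold: float = DEFAULT_SIMILAR_THRESHOLD,
             expect_ceiling: float = DEFAULT_EXPECT_CEILING,
             indirect_rule: str = "similar") -> list[LineageAssignment]:
    """Full two-round assignment of every id in `krtap_ids`.

    Returns one :class:`LineageAssignment` per KRTAP id — the labels
    partition the id set.
    """
    occ_res = search(occludin_bait, db, scheme, expect_ceiling)
    mt_res = search(mt_bait, db, scheme, expect_ceiling)
    direct = assign_direct(occ_res, mt_res, krtap_ids, top_n)
    labelled = {a.protein_id for a in direct}
    indirect = assign_indirect(
        krtap_ids - labelled, db, direct, scheme,
        top_n=top_n, threshold=threshold,
        expect_ceiling=expect_ceiling, rule=indirect_rule,
    )
    return sorted(direct + indirect, key=lambda a: a.protein_id)


def assignments_frame(assignments: list[LineageAssignment]) -> pd.DataFrame:
    """Tabular view: protein_id, label, best evidence id and Expect value."""
    rows = []
    for a in assignments:
        best = min(a.evidence, key=lambda ev: ev[1]) if a.evidence else (None, None)
        rows.append({
            "protein_id": a.protein_id,
            "label": a.label.value,
            "lineage": a.label.lineage,
            "best_evidence_id": best[0],
            "best_evidence_evalue": best[1],
        })
    return pd.DataFrame(rows)
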