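"""Harvest rules (linked / similar) and two-round lineage assignment."""

import pytest

from krtap import (
    Label,
    SequenceRecord,
    SequenceStore,
    assign_direct,
    assign_indirect,
    classify,
    linked_set,
    search,
    similar_set,
)
from krtap.linkage import DirectOverlapError, SearchHit, SearchResult
from krtap.synthetic import evolve_family, make_ancestors, make_decoy_proteome, FamilyConfig


def _result(bait_id, evalues_by_id, db_size=None):
    ordered = sorted(evalues_by_id.items(), key=lambda kv: (kv[1], kv[0]))
    hits = tuple(
        SearchHit(subject_id=sid, raw_score=0, bit_score=-i, evalue=e, rank=i)
        for i, (sid, e) in enumerate(ordered, start=1)
    )
    return SearchResult(bait_id=bait_id, hits=hits,
                        db_size=db_size or len(hits))


class TestSearch:
    def test_self_hit_ranks_first(self, scheme):
        bait, _ = make_ancestors(1)
        db = make_decoy_proteome(10, seed=1)
        db.add(bait)
        res = search(bait, db, scheme)
        assert res.hits[0].subject_id == bait.id
        assert res.hits[0].bit_score == max(h.bit_score for h in res.hits)

    def test_stringent_ceiling_excludes_unrelated(self, scheme):
        bait, _ = make_ancestors(2)
        db = make_decoy_proteome(10, length_range=(50, 50), seed=3)
        res = search(bait, db, scheme, expect_ceiling=1e-3)
        assert len(res.hits) == 0

    def test_planted_homologs_outrank_decoys(self, scheme):
        bait, _ = make_ancestors(3)
        fam, _ = evolve_family(
            bait, FamilyConfig(n_members=5, sub_rate=0.3, seed=5,
                               id_prefix="HOM"), scheme)
        db = make_decoy_proteome(200, seed=7)
        for rec in fam:
            db.add(rec)
        res = search(bait, db, scheme)
        assert {h.subject_id for h in res.hits[:5]} == set(fam.ids())

    def test_ranks_are_consecutive_and_sorted(self, scheme):
        bait, _ = make_ancestors(4)
        db = make_decoy_proteome(30, seed=9)
        res = search(bait, db, scheme)
        assert [h.rank for h in res.hits] == list(range(1, len(res.hits) + 1))
        evs = [h.evalue for h in res.hits]
        assert evs == sorted(evs)


class TestHarvestSets:
    def test_linked_returns_all_when_few_hits(self):
        res = _result("b", {"x": 1.0, "y": 2.0, "z": 3.0})
        assert linked_set(res, top_n=500) == {"x", "y", "z"}

    def test_linked_truncates_to_lowest_evalues(self):
        res = _result("b", {f"s{i:03d}": float(i) for i in range(600)})
        got = linked_set(res, top_n=500)
        assert len(got) == 500
        assert "s000" in got and "s599" not in got

    def test_boundary_ties_broken_deterministically(self):
        # three subjects tie at the boundary E; bit score then id decide
        hits = (
            SearchHit("a", 50, 30.0, 1e-4, 1),
            SearchHit("b", 40, 20.0, 5e-4, 2),
            SearchHit("c", 40, 20.0, 5e-4, 3),
        )
        res = SearchResult("bait", hits, 3)
        assert linked_set(res, top_n=2) == {"a", "b"}

    def test_similar_is_inclusive_at_threshold(self):
        res = _result("b", {"p": 1e-5, "q": 9e-4, "r": 2e-3})
        assert similar_set(res, 1e-3) == {"p", "q"}
        assert similar_set(_result("b", {}), 1e-3) == set()

    def test_similar_subset_of_linked(self, scheme):
        bait, _ = make_ancestors(5)
        db = make_decoy_proteome(50, seed=11)
        db.add(bait)
        res = search(bait, db, scheme)
        assert similar_set(res) <= linked_set(res, top_n=len(res.hits))


class TestAssignDirect:
    def test_disjoint_sets_fully_labelled(self):
        occ = _result("OCLN", {"k1": 1e-5, "k2": 1e-4, "d1": 1.0})
        mt = _result("MT1A", {"k3": 1e-6, "d2": 2.0})
        got = assign_direct(occ, mt, {"k1", "k2", "k3"}, top_n=500)
        labels = {a.protein_id: a.label for a in got}
        assert labels == {"k1": Label.O_DIRECT, "k2": Label.O_DIRECT,
                          "k3": Label.M_DIRECT}
        evidence = {a.protein_id: a.evidence[0][0] for a in got}
        assert evidence == {"k1": "OCLN", "k2": "OCLN", "k3": "MT1A"}

    def test_unlinked_ids_left_for_indirect_round(self):
        occ = _result("OCLN", {"k1": 1e-5})
        mt = _result("MT1A", {"k2": 1e-6})
        got = assign_direct(occ, mt, {"k1", "k2", "k9"}, top_n=500)
        assert {a.protein_id for a in got} == {"k1", "k2"}

    def test_overlap_surfaces_as_error(self):
        occ = _result("OCLN", {"k1": 1e-5})
        mt = _result("MT1A", {"k1": 1e-6})
        with pytest.raises(DirectOverlapError, match="k1"):
            assign_direct(occ, mt, {"k1"}, top_n=500)


def _indirect_db(scheme):
    """A db with one O-direct member, one M-direct member and decoys."""
    m_anc, o_anc = make_ancestors(6)
    db = make_decoy_proteome(60, seed=13)
    m_member = SequenceRecord(id="Mdir", residues=m_anc.residues)
    o_member = SequenceRecord(id="Odir", residues=o_anc.residues)
    db.add(m_member)
    db.add(o_member)
    direct = [
        LineageAssignmentFactory("Odir", Label.O_DIRECT, "OCLN"),
        LineageAssignmentFactory("Mdir", Label.M_DIRECT, "MT1A"),
    ]
    return db, direct, m_anc, o_anc


def LineageAssignmentFactory(pid, label, via):
    from krtap import LineageAssignment

    return LineageAssignment(pid, label, ((via, 1e-9),))


class TestAssignIndirect:
    def test_single_lineage_evidence(self, scheme):
        db, direct, m_anc, _ = _indirect_db(scheme)
        # bait nearly identical to the M member only
        bait = SequenceRecord(id="q", residues=m_anc.residues[:55])
        db.add(bait)
        got = assign_indirect({"q"}, db, direct, scheme, top_n=60)
        assert got == [a for a in got]  # deterministic list
        assert got[0].label is Label.M_INDIRECT
        assert got[0].evidence[0][0] == "Mdir"

    def test_both_lineages_give_dual(self, scheme):
        db, direct, m_anc, o_anc = _indirect_db(scheme)
        bait = SequenceRecord(
            id="q", residues=m_anc.residues[:40] + o_anc.residues[:40])
        db.add(bait)
        got = assign_indirect({"q"}, db, direct, scheme, top_n=62)
        assert got[0].label is Label.DUAL_INDIRECT
        assert {ev[0] for ev in got[0].evidence} == {"Mdir", "Odir"}

    def test_no_subthreshold_hits_gives_unlinked(self, scheme):
        db, direct, _, _ = _indirect_db(scheme)
        decoy = next(iter(make_decoy_proteome(1, length_range=(45, 45),
                                              seed=99)))
        rec = SequenceRecord(id="lone_decoy", residues=decoy.residues)
        db.add(rec)
        got = assign_indirect({rec.id}, db, direct, scheme, top_n=62)
        assert got[0].label is Label.UNLINKED and got[0].evidence == ()


class TestClassifyPartition:
    def test_labels_partition_krtap_ids(self, scheme):
        m_anc, o_anc = make_ancestors(8)
        m_fam, _ = evolve_family(m_anc, FamilyConfig(
            n_members=6, sub_rate=0.2, seed=21, id_prefix="KM"), scheme)
        o_fam, _ = evolve_family(o_anc, FamilyConfig(
            n_members=6, sub_rate=0.2, seed=22, id_prefix="KO"), scheme)
        db = make_decoy_proteome(120, seed=23)
        db.add(m_anc)
        db.add(o_anc)
        for rec in list(m_fam) + list(o_fam):
            db.add(rec)
        ids = set(m_fam.ids()) | set(o_fam.ids())
        got = classify(o_anc, m_anc, db, ids, scheme, top_n=7)
        assert [a.protein_id for a in got] == sorted(ids)
        lineages = {a.protein_id: a.label.lineage for a in got}
        assert all(lineages[i] == "M" for i in m_fam.ids())
        assert all(lineages[i] == "O" for i in o_fam.ids())

    def test_classification_is_deterministic(self, scheme):
        m_anc, o_anc = make_ancestors(9)
        fam, _ = evolve_family(m_anc, FamilyConfig(
            n_members=4, sub_rate=0.25, seed=31, id_prefix="K"), scheme)
        db = make_decoy_proteome(60, seed=33)
        db.add(m_anc)
        db.add(o_anc)
        for rec in fam:
            db.add(rec)
        first = classify(o_anc, m_anc, db, set(fam.ids()), scheme, top_n=5)
        again = classify(o_anc, m_anc, db, set(fam.ids()), scheme, top_n=5)
        assert first == again
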