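"""Distance matrices, neighbor joining and the two-branch purity check."""

import random

import numpy as np
import pytest
from scipy.stats import spearmanr

from krtap import (
    DistanceMatrix,
    ScoringScheme,
    bipartition_purity,
    distance_matrix,
    nj_tree,
)
from krtap.phylo import tree_from_newick, tree_to_newick
from krtap.synthetic import FamilyConfig, evolve_family, make_ancestors

from oracles import caterpillar_purity


def _random_additive_tree(n_taxa: int, rng: random.Random):
    """A random binary tree with rational branch lengths and its leaf-path
    distance matrix, built by successive leaf attachment."""
    # adjacency with edge lengths over node ids; leaves are 0..n_taxa-1
    import itertools

    adj: dict[int, dict[int, float]] = {}
    next_id = n_taxa

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    # start from a 2-leaf tree
    connect(0, 1, rng.randint(1, 9) / 4)
    edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        a, b = edges[rng.randrange(len(edges))]
        mid = next_id
        next_id += 1
        adj[a].pop(b)
        adj[b].pop(a)
        edges.remove((a, b))
        # fresh positive lengths keep the path metric additive
        connect(a, mid, rng.randint(1, 6) / 4)
        connect(b, mid, rng.randint(1, 6) / 4)
        connect(leaf, mid, rng.randint(1, 9) / 4)
        edges += [(a, mid), (b, mid), (leaf, mid)]

    def dist(u, v):
        seen = {u}
        stack = [(u, 0.0)]
        while stack:
            node, acc = stack.pop()
            if node == v:
                return acc
            for nxt, w in adj[node].items():
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, acc + w))
        raise AssertionError("disconnected")

    ids = tuple(f"T{i}" for i in range(n_taxa))
    d = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d[i, j] = d[j, i] = dist(i, j)
    return DistanceMatrix(ids, d), adj


def _tree_distances(tree):
    """Leaf-to-leaf path lengths of a TreeNode."""
    tips = list(tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 7.0}

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) gives these path distances
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        got = _tree_distances(tree)
        for pair, expected in {
            frozenset("AB"): 3, frozenset("AC"): 5, frozenset("AD"): 3,
            frozenset("BC"): 6, frozenset("BD"): 4, frozenset("CD"): 4,
        }.items():
            assert got[pair] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_taxa):
        rng = random.Random(100 + n_taxa)
        for _ in range(5):
            dm, _ = _random_additive_tree(n_taxa, rng)
            tree = nj_tree(dm)
            got = _tree_distances(tree)
            for i, a in enumerate(dm.ids):
                for j in range(i + 1, n_taxa):
                    assert got[frozenset((a, dm.ids[j]))] == pytest.approx(
                        dm.d[i, j], abs=1e-9)

    def test_newick_round_trip_lossless(self):
        rng = random.Random(77)
        dm, _ = _random_additive_tree(6, rng)
        tree = nj_tree(dm)
        back = tree_from_newick(tree_to_newick(tree))
        assert _tree_distances(back) == pytest.approx(_tree_distances(tree))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 2], [1, 0, -1], [2, -1, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0.0]]))

    def test_topology_independent_of_input_order(self):
        rng = random.Random(5)
        dm, _ = _random_additive_tree(7, rng)
        perm = list(range(7))
        random.Random(8).shuffle(perm)
        dm2 = DistanceMatrix(tuple(dm.ids[i] for i in perm),
                             dm.d[np.ix_(perm, perm)])
        assert _tree_distances(nj_tree(dm)) == pytest.approx(
            _tree_distances(nj_tree(dm2)))


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self, scheme):
        from krtap import SequenceRecord, SequenceStore

        rec = "CCGYSTACDEFGHIK"
        store = SequenceStore([
            SequenceRecord(id=f"s{i}", residues=rec) for i in range(3)
        ])
        dm = distance_matrix(store, scheme)
        assert np.allclose(dm.d, 0.0)

    def test_symmetric_zero_diagonal(self, scheme):
        m_anc, _ = make_ancestors(12)
        fam, _ = evolve_family(m_anc, FamilyConfig(
            n_members=4, sub_rate=0.2, seed=41, id_prefix="F"), scheme)
        dm = distance_matrix(fam, scheme)
        assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)

    def test_distance_grows_with_substitution_rate(self, scheme):
        m_anc, _ = make_ancestors(13)
        rates = [0.05, 0.15, 0.25, 0.35, 0.5]
        means = []
        for rate in rates:
            fam, _ = evolve_family(m_anc, FamilyConfig(
                n_members=5, sub_rate=rate, seed=43, id_prefix="F"), scheme)
            dm = distance_matrix(fam, scheme)
            means.append(dm.d[np.triu_indices(5, 1)].mean())
        rho, _ = spearmanr(rates, means)
        assert rho > 0.9


class TestBipartitionPurity:
    def test_perfect_segregation(self):
        tree = tree_from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1,(b3:1,b4:1):1);")
        labels = {"a1": "O", "a2": "O", "b1": "M", "b2": "M",
                  "b3": "M", "b4": "M"}
        side, purity = bipartition_purity(tree, labels)
        assert purity == 1.0
        assert side in (frozenset({"a1", "a2"}),
                        frozenset(labels) - {"a1", "a2"})

    def test_matches_caterpillar_edge_scan(self):
        leaves = [f"L{i}" for i in range(10)]
        newick = ""
        for name in leaves[:-1]:
            newick += f"({name}:1,"
        newick = newick[:-len(f"({leaves[-2]}:1,")]  # rebuild below
        # caterpillar: (L0,(L1,(...,(L8,L9)...)))
        newick = leaves[-1]
        for name in reversed(leaves[:-1]):
            newick = f"({name}:1,{newick}:1)"
        tree = tree_from_newick(newick + ";")
        rng = random.Random(17)
        labels = {name: rng.choice("OM") for name in leaves}
        _, purity = bipartition_purity(tree, labels)
        assert purity == pytest.approx(caterpillar_purity(leaves, labels))

    def test_singleton_branch_does_not_crash(self):
        # one leaf hangs alone off the root (a single-membered branch)
        tree = tree_from_newick("(solo:2,(a:1,b:1):1,(c:1,d:1):1);")
        labels = {"solo": "O", "a": "M", "b": "M", "c": "M", "d": "M"}
        _, purity = bipartition_purity(tree, labels)
        assert purity == 1.0

    def test_purity_at_least_majority_frequency(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        labels = {"a": "O", "b": "M", "c": "O", "d": "M", "e": "M"}
        _, purity = bipartition_purity(tree, labels)
        assert purity >= 3 / 5

    def test_single_label_rejected(self):
        tree = tree_from_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="labels"):
            bipartition_purity(tree, {"a": "O", "b": "O", "c": "O"})

    def test_unlabelled_leaves_warn_and_are_ignored(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        with pytest.warns(UserWarning, match="unlabelled"):
            _, purity = bipartition_purity(
                tree, {"a": "O", "b": "O", "c": "M", "d": "M"})
        assert purity == 1.0


def test_two_family_tree_segregates(scheme):
    from krtap import SequenceStore

    m_anc, o_anc = make_ancestors(14)
    m_fam, _ = evolve_family(m_anc, FamilyConfig(
        n_members=6, sub_rate=0.25, seed=51, id_prefix="M"), scheme)
    o_fam, _ = evolve_family(o_anc, FamilyConfig(
        n_members=6, sub_rate=0.25, seed=52, id_prefix="O"), scheme)
    store = SequenceStore(list(m_fam) + list(o_fam))
    tree = nj_tree(distance_matrix(store, scheme))
    labels = {i: "M" for i in m_fam.ids()} | {i: "O" for i in o_fam.ids()}
    _, purity = bipartition_purity(tree, labels)
    assert purity >= 0.95
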