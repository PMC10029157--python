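"""Distance trees over protein sets and the two-branch lineage check.

A pairwise distance matrix is derived from the local-alignment engine
(default distance: 1 minus the identity fraction of the optimal local
alignment) and a tree is built by classical neighbor joining (Saitou-Nei
Q criterion with Studier-Keppler updates).  The headline topological claim
for the human KRTAP set — O- and M-lineage members segregating into two
main branches — is made testable by :func:`bipartition_purity`, which scans
every edge for the split that best separates the two labels.

Trees are scikit-bio ``TreeNode`` objects (trifurcating root, unrooted
convention) so Newick round-trips are lossless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .align import local_align
from .scoring import ScoringScheme
from .seqstore import SequenceStore

#: Distance assigned to a zero-identity pair under the -ln transform.
NEG_LOG_CAP = 5.0


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, finite, nonnegative

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite and nonnegative")
        object.__setattr__(self, "d", d)


def distance_matrix(store: SequenceStore, scheme: ScoringScheme,
                    transform: str = "one_minus_scaled_identity",
                    cap: float = NEG_LOG_CAP) -> DistanceMatrix:
    """Pairwise distances from optimal local-alignment identity.

    ``one_minus_scaled_identity`` (default):
    d = 1 - identities/min(len_i, len_j) — identical residues of the
    optimal local alignment, normalised by the shorter sequence.  Unrelated
    sequences share only a short high-identity local segment, so the
    per-column identity of that segment saturates; scaling by the shorter
    sequence measures how much of the protein is actually alignable and
    separates families cleanly.

    ``one_minus_identity``: d = 1 - identities/alignment_length (the raw
    per-column identity of the optimal local alignment).

    ``neg_log_identity``: d = -ln(per-column identity), capped at `cap`
    for zero-identity pairs (stretches diverged pairs that saturate the
    linear transform).
    """
    transforms = ("one_minus_scaled_identity", "one_minus_identity",
                  "neg_log_identity")
    if transform not in transforms:
        raise ValueError(f"unknown transform {transform!r}")
    records = list(store)
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(records[i], records[j], scheme)
            ident = (aln.identities / aln.alignment_length
                     if aln.alignment_length else 0.0)
            if transform == "one_minus_scaled_identity":
                shorter = min(len(records[i]), len(records[j]))
                dij = 1.0 - aln.identities / shorter
            elif transform == "one_minus_identity":
                dij = 1.0 - ident
            else:
                if ident <= 0 or -math.log(ident) > cap:
                    warnings.warn(
                        f"capping distance for pair ({records[i].id}, "
                        f"{records[j].id}) at {cap}"
                    )
                    dij = cap
                else:
                    dij = -math.log(ident)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=tuple(r.id for r in records), d=d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Classical NJ: at each step join the pair (i, j) minimising
    Q(i, j) = (r - 2) d(i, j) - R_i - R_j (R = row sums, r = live taxa),
    with the lowest-index pair chosen on ties; branch lengths from the
    standard three-point formulas and the Studier-Keppler distance update.
    Additive matrices are recovered exactly.  Negative branch-length
    estimates are clamped to zero.  The returned tree has a trifurcating
    root (unrooted convention).
    """
    n = len(dm.ids)
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        # Studier-Keppler update: distance from the new node to each other
        # taxon k is (d_ik + d_jk - d_ij) / 2.
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new_idx, k] = d[k, new_idx] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # Final trifurcation: three-point formulas.
    i, j, k = active
    root = TreeNode()
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    for node in (nodes[i], nodes[j], nodes[k]):
        root.append(node)
    return root


def tree_to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read([newick])


def bipartition_purity(tree: TreeNode, labels: dict[str, str]
                       ) -> tuple[frozenset[str], float]:
    """Best two-clade split of the tree under a two-label leaf colouring.

    Every edge partitions the leaves into two sides; purity of a split is
    (majority-label count on side 1 + majority-label count on side 2) /
    total labelled leaves.  Returns the leaf set of one side of the best
    edge and its purity (ties broken toward the first edge in postorder).
    Unlabelled leaves are ignored with a warning; fewer than two distinct
    labels is an error.
    """
    leaf_names = [leaf.name for leaf in tree.tips()]
    unlabelled = [name for name in leaf_names if name not in labels]
    if unlabelled:
        warnings.warn(f"ignoring {len(unlabelled)} unlabelled leaves")
    labelled = {name: labels[name] for name in leaf_names if name in labels}
    values = sorted(set(labelled.values()))
    if len(values) < 2:
        raise ValueError("need at least 2 distinct leaf labels")
    total = len(labelled)
    counts_total = {v: sum(1 for lab in labelled.values() if lab == v)
                    for v in values}

    best_side: frozenset[str] = frozenset()
    best_purity = -1.0
    for node in tree.postorder(include_self=False):
        side = frozenset(
            leaf.name for leaf in node.tips(include_self=True)
            if leaf.name in labelled
        )
        if not side or len(side) == total:
            continue
        counts_in = {v: sum(1 for name in side if labelled[name] == v)
                     for v in values}
        purity = (
            max(counts_in.values())
            + max(counts_total[v] - counts_in[v] for v in values)
        ) / total
        if purity > best_purity:
            best_purity = purity
            best_side = side
    return best_side, best_purity
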