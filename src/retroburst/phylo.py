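"""Distance-based tree building and monophyly classification.

Neighbor joining with negative-branch clamping, column-bootstrap supports on
bipartitions, and rooted monophyly/paraphyly/polyphyly calls (midpoint
rooting by default). Trees are dendropy objects, so Newick round-trips use a
mature parser.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import Alignment

logger = logging.getLogger("retroburst")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None) -> None:
        self.label = label
        self.children: list[tuple["_Node", float]] = []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})" + (self.label or "")


def neighbor_joining(dist, taxa: list[str] | None = None) -> dendropy.Tree:
    """Standard NJ agglomeration from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit absorbed by
    the sibling edge (their sum stays equal to the joined distance).
    """
    D = np.array(dist, dtype=float)
    n = D.shape[0]
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n)]
    if D.shape != (n, n) or len(taxa) != n:
        raise ValueError("distance matrix and taxa are inconsistent")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    bad = np.argwhere(np.isnan(D))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"missing distance between {taxa[i]!r} and {taxa[j]!r}")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[_Node] = [_Node(t) for t in taxa]
    active = list(range(n))
    W = D.copy()

    while len(active) > 3:
        k = len(active)
        sub = W[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        d_ij = W[i, j]
        li = 0.5 * d_ij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        parent = _Node()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        # new row of distances
        new_idx = W.shape[0]
        newrow = np.zeros(new_idx + 1)
        grown = np.zeros((new_idx + 1, new_idx + 1))
        grown[:new_idx, :new_idx] = W
        for m in active:
            if m in (i, j):
                continue
            grown[new_idx, m] = grown[m, new_idx] = 0.5 * (
                W[i, m] + W[j, m] - d_ij)
        W = grown
        nodes.append(parent)
        active = [m for m in active if m not in (i, j)] + [new_idx]

    # closed-form star resolution of the final three nodes
    a, b, c = active
    la = max(0.0, 0.5 * (W[a, b] + W[a, c] - W[b, c]))
    lb = max(0.0, 0.5 * (W[a, b] + W[b, c] - W[a, c]))
    lc = max(0.0, 0.5 * (W[a, c] + W[b, c] - W[a, b]))
    root = _Node()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    newick = root.newick() + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap supports
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree, taxa: list[str] | None = None
                      ) -> set[frozenset[str]]:
    """Canonical internal-edge bipartitions as frozensets of leaf labels.

    Each bipartition is represented by the side not containing the first
    taxon (alphabetically first leaf if ``taxa`` is None).
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = (taxa or labels)[0]
    full = set(labels)
    bips: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        canon = frozenset(side) if anchor not in side else frozenset(full - side)
        if 2 <= len(canon) <= len(full) - 2:
            bips.add(canon)
    return bips


def bootstrap_support(alignment: Alignment, distance: str = "f84",
                      reps: int = 1000, seed: int = 0
                      ) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree with column-bootstrap supports on its internal edges.

    Supports (percent of replicates containing each original bipartition)
    are written as internal node labels and also returned keyed by
    bipartition.
    """
    from .evostats import distance_matrix

    if reps < 1:
        raise ValueError("reps must be >= 1")
    taxa = list(alignment.ids)
    D = distance_matrix(alignment, model=distance)
    tree = neighbor_joining(D, taxa)
    original = tree_bipartitions(tree, sorted(taxa))
    counts = {b: 0 for b in original}
    rng = np.random.default_rng(seed)
    L = alignment.length
    from .seqio import SequenceRecord

    for _ in range(reps):
        idx = rng.integers(0, L, size=L)
        rows = [SequenceRecord(r.id, "".join(r.seq[c] for c in idx))
                for r in alignment.records]
        rep_aln = Alignment(records=rows, region_label=alignment.region_label,
                            groups=dict(alignment.groups))
        rep_tree = neighbor_joining(distance_matrix(rep_aln, model=distance),
                                    taxa)
        rep_bips = tree_bipartitions(rep_tree, sorted(taxa))
        for b in original:
            if b in rep_bips:
                counts[b] += 1
    supports = {b: 100.0 * c / reps for b, c in counts.items()}

    full = set(taxa)
    anchor = sorted(taxa)[0]
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        canon = frozenset(side) if anchor not in side else frozenset(full - side)
        if canon in supports:
            node.label = f"{supports[canon]:.0f}"
    return tree, supports


# ---------------------------------------------------------------------------
# Monophyly classification
# ---------------------------------------------------------------------------

@dataclass
class MonophylyReport:
    classification: dict[str, str]
    supporting_edge: dict[str, frozenset[str] | None]


def check_monophyly(tree: dendropy.Tree, groups: dict[str, str],
                    root: str = "midpoint") -> MonophylyReport:
    """Classify each group as monophyletic, paraphyletic, or polyphyletic.

    The tree is rooted (midpoint by default, or at a named outgroup leaf).
    A group is monophyletic when it is exactly the leaf set of a clade;
    paraphyletic when the foreign taxa under its MRCA form a single nested
    clade (the group's complement within the MRCA is monophyletic);
    polyphyletic otherwise.
    """
    members: dict[str, set[str]] = {}
    for leaf_label, g in groups.items():
        members.setdefault(g, set()).add(leaf_label)
    if not members:
        raise ValueError("no groups given")
    for g, mem in members.items():
        if not mem:
            raise ValueError(f"group {g!r} has no members")

    work = tree.clone(depth=1)
    leaf_labels = {lf.taxon.label for lf in work.leaf_node_iter()}
    for g, mem in members.items():
        missing = mem - leaf_labels
        if missing:
            raise ValueError(f"group {g!r} members missing from tree: "
                             f"{sorted(missing)}")
    if root == "midpoint":
        work.reroot_at_midpoint(update_bipartitions=False)
    else:
        og = [lf for lf in work.leaf_node_iter() if lf.taxon.label == root]
        if not og:
            raise ValueError(f"outgroup leaf {root!r} not in tree")
        work.to_outgroup_position(og[0], update_bipartitions=False)

    def clade_leafset(node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    clades: set[frozenset[str]] = set()
    clade_sets: list[frozenset[str]] = []
    for node in work.preorder_node_iter():
        cs = frozenset(clade_leafset(node))
        clades.add(cs)
        clade_sets.append(cs)

    classification: dict[str, str] = {}
    supporting: dict[str, frozenset[str] | None] = {}
    for g, mem in sorted(members.items()):
        fmem = frozenset(mem)
        if fmem in clades or mem == leaf_labels or len(mem) == 1:
            classification[g] = "monophyletic"
            supporting[g] = fmem
            continue
        # MRCA leaf set = smallest clade containing all members (bitmask-free,
        # robust to rerooting)
        under = min((cs for cs in clade_sets if fmem <= cs), key=len)
        rest = frozenset(under - mem)
        if rest and rest in clades:
            classification[g] = "paraphyletic"
            supporting[g] = rest
        else:
            classification[g] = "polyphyletic"
            supporting[g] = None
    return MonophylyReport(classification=classification,
                           supporting_edge=supporting)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
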