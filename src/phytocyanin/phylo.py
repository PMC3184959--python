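"""Distance-based neighbor-joining phylogeny with bootstrap supports.

Distances are uncorrected p-distances (proportion of differing sites, with
pairwise deletion of gap-containing columns) unless a Poisson correction is
requested. Trees are reconstructed with the Saitou–Nei neighbor-joining
algorithm: at each step the pair minimising the Q criterion

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

is joined, with branch lengths from the standard three-point formulas and
ties broken by the smallest index pair. The result is an unrooted binary
tree (internal nodes of degree 3) serialised as Newick; bootstrap supports
are the percentage of column-resampled replicate trees containing each
split of the full-data tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GAP_CHARS = {"-", "."}


@dataclass
class TreeNode:
    """Simple rooted representation of the unrooted NJ tree (rooted at the
    final join point, an internal node of degree 3)."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def to_newick(self) -> str:
        return self._newick_inner(top=True) + ";"

    def _newick_inner(self, top: bool = False) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        if top:
            return f"({inner}){label}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class PhyloTree:
    root: TreeNode
    negative_lengths_clamped: bool = False

    def to_newick(self) -> str:
        return self.root.to_newick()

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions (as the smaller-or-canonical leaf side)
        induced by internal edges."""
        all_leaves = frozenset(self.root.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(_canonical_split(below, all_leaves))
            return below

        for child in self.root.children:
            walk(child)
        return out


def _canonical_split(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Symmetric-difference (Robinson–Foulds) distance between two unrooted
    trees on the same taxa."""
    if set(a.root.leaf_names()) != set(b.root.leaf_names()):
        raise ValueError("trees have different taxon sets")
    return len(a.splits() ^ b.splits())


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m


def p_distance(ids: Sequence[str], rows: Sequence[str],
               correction: Optional[str] = None) -> DistanceMatrix:
    """Pairwise proportion of differing sites with pairwise deletion of
    columns where either sequence has a gap. ``correction="poisson"``
    applies -ln(1-p) (a stand-in for model-corrected protein distances)."""
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                comparable += 1
                diffs += a != b
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = diffs / comparable
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated distance under Poisson correction")
                p = -math.log(1.0 - p)
            mat[i, j] = mat[j, i] = p
    return DistanceMatrix(list(ids), mat)


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining. Ties on the Q criterion are broken by
    the lexicographically smallest (i, j) pair of current node indices;
    negative branch-length estimates are clamped to zero and flagged."""
    n = len(dist.ids)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dist.ids]
    if n == 2:
        d = float(dist.matrix[0, 1])
        nodes[0].length = d
        root = TreeNode(children=[nodes[0], nodes[1]])
        return PhyloTree(root)

    d = dist.matrix.astype(float).copy()
    active = list(range(n))  # indices into d
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (math.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (d[i, c] + d[j, c] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = clamp(li)
    nodes[j].length = clamp(lj)
    nodes[k].length = clamp(lk)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root, negative_lengths_clamped=clamped)


def bootstrap_support(
    ids: Sequence[str],
    rows: Sequence[str],
    n_reps: int = 1000,
    seed: Optional[int] = None,
    correction: Optional[str] = None,
) -> PhyloTree:
    """Bootstrap the alignment columns, rebuild the NJ tree per replicate,
    and annotate each internal split of the full-data tree with the
    percentage of replicates containing it."""
    tree = nj_tree(p_distance(ids, rows, correction))
    length = len(rows[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree.splits()}
    universe = frozenset(ids)
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(row[c] for c in cols) for row in rows]
        try:
            rep = nj_tree(p_distance(ids, resampled, correction))
        except ValueError:  # a pair lost all comparable columns
            continue
        rep_splits = rep.splits()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        key = _canonical_split(below, universe)
        if key in counts and 1 < len(below) < len(universe) - 1:
            node.support = 100.0 * counts[key] / n_reps
        return below

    for child in tree.root.children:
        annotate(child)
    return tree
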