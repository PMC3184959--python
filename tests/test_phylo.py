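"""p-distances, neighbor joining and bootstrap supports."""

import itertools

import numpy as np
import pytest

from phytocyanin import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    p_distance,
    robinson_foulds,
)


def test_p_distance_examples():
    d = p_distance(["a", "b"], ["AAAA", "AAAA"])
    assert d.matrix[0, 1] == 0.0
    d = p_distance(["a", "b"], ["AAAA", "AATT"])
    assert d.matrix[0, 1] == 0.5
    d = p_distance(["a", "b"], ["A-AA", "AGAT"])  # pairwise deletion
    assert d.matrix[0, 1] == pytest.approx(1 / 3)


def test_p_distance_errors():
    with pytest.raises(ValueError):
        p_distance(["a", "b"], ["A-", "-A"])  # no comparable columns
    with pytest.raises(ValueError):
        p_distance(["a", "b"], ["AA", "AAA"])


def test_p_distance_poisson_correction():
    d = p_distance(["a", "b"], ["AAAA", "AATT"], correction="poisson")
    assert d.matrix[0, 1] == pytest.approx(-np.log(0.5))


def test_nj_three_taxa_closed_form():
    # additive three-point: d(a,b)=3, d(a,c)=4, d(b,c)=5
    dist = DistanceMatrix(["a", "b", "c"], np.array(
        [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
    ))
    tree = nj_tree(dist)
    lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
    assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                       "c": pytest.approx(3.0)}


def test_nj_four_taxa_recovers_true_split():
    # additive matrix with internal edge separating {a,b} | {c,d}
    names = ["a", "b", "c", "d"]
    m = np.array(
        [
            [0.0, 0.3, 0.9, 1.0],
            [0.3, 0.0, 1.0, 1.1],
            [0.9, 1.0, 0.0, 0.3],
            [1.0, 1.1, 0.3, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(names, m))
    assert tree.splits() == {frozenset({"a", "b"})}


def test_nj_star_matrix_is_deterministic():
    names = list("abcde")
    m = np.ones((5, 5)) - np.eye(5)
    t1 = nj_tree(DistanceMatrix(names, m.copy()))
    t2 = nj_tree(DistanceMatrix(names, m.copy()))
    assert t1.to_newick() == t2.to_newick()


def test_nj_two_taxa_degenerate():
    tree = nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 0.7], [0.7, 0.0]])))
    assert sorted(tree.root.leaf_names()) == ["a", "b"]


def _random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree as an edge list; returns (taxa, distance
    matrix, true nontrivial splits) computed with networkx path lengths."""
    import networkx as nx

    g = nx.Graph()
    taxa = [f"t{i}" for i in range(n_taxa)]
    internal = ["x0"]
    g.add_edges_from(
        ("x0", t, {"w": rng.uniform(0.05, 1.0)}) for t in taxa[:3]
    )
    for k, taxon in enumerate(taxa[3:], start=1):
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["w"]
        g.remove_edge(u, v)
        node = f"x{k}"
        internal.append(node)
        split = rng.uniform(0.2, 0.8) * w
        g.add_edge(u, node, w=split)
        g.add_edge(node, v, w=w - split)
        g.add_edge(node, taxon, w=rng.uniform(0.05, 1.0))
    dists = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    m = np.array([[dists[a][b] for b in taxa] for a in taxa])
    # true splits: remove each internal-internal edge
    splits = set()
    for u, v in list(g.edges()):
        if u in internal and v in internal:
            h = g.copy()
            h.remove_edge(u, v)
            side = frozenset(t for t in taxa if t in nx.node_connected_component(h, u))
            other = frozenset(taxa) - side
            splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return taxa, m, splits


def test_nj_consistency_on_additive_matrices():
    rng = np.random.default_rng(123)
    for _ in range(20):
        n = int(rng.integers(4, 13))
        taxa, m, true_splits = _random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(taxa, m))
        assert tree.splits() == true_splits


def test_nj_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    from io import StringIO
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj, TreeNode as SkbioTree

    rng = np.random.default_rng(5)
    taxa, m, _ = _random_additive_tree(8, rng)
    m = (m + m.T) / 2.0  # symmetrize float error for skbio
    mine = nj_tree(DistanceMatrix(taxa, m))
    other = skbio_nj(SkbioDM(m, ids=taxa))
    mine_parsed = SkbioTree.read(StringIO(mine.to_newick()))
    assert int(mine_parsed.compare_rfd(other)) == 0


def test_newick_round_trip():
    skbio = pytest.importorskip("skbio")
    from io import StringIO
    from skbio import TreeNode as SkbioTree

    rng = np.random.default_rng(9)
    taxa, m, _ = _random_additive_tree(7, rng)
    tree = nj_tree(DistanceMatrix(taxa, m))
    parsed = SkbioTree.read(StringIO(tree.to_newick()))
    assert sorted(t.name for t in parsed.tips()) == sorted(taxa)


def _two_clade_alignment(cols_per_block=30):
    # two clearly separated 3-taxon clades with many diagnostic columns
    left, right = "A" * cols_per_block, "T" * cols_per_block
    rows = {
        "a1": left + "AAGG", "a2": left + "AATG", "a3": left + "ATGG",
        "b1": right + "GGAA", "b2": right + "GGTA", "b3": right + "GTAA",
    }
    return list(rows), list(rows.values())


def test_bootstrap_central_split_strongly_supported():
    ids, rows = _two_clade_alignment()
    tree = bootstrap_support(ids, rows, n_reps=200, seed=7)
    supports = {}

    def walk(node):
        for c in node.children:
            if not c.is_leaf:
                supports[frozenset(c.leaf_names())] = c.support
                walk(c)

    walk(tree.root)
    central = [
        s for key, s in supports.items()
        if {x[0] for x in key} in ({"a"}, {"b"}) and len(key) == 3
    ]
    assert central and all(s >= 95 for s in central)


def test_bootstrap_reproducible_with_seed():
    ids, rows = _two_clade_alignment(10)
    t1 = bootstrap_support(ids, rows, n_reps=50, seed=3)
    t2 = bootstrap_support(ids, rows, n_reps=50, seed=3)
    assert t1.to_newick() == t2.to_newick()


def test_identical_sequences_tree_is_valid():
    ids = ["a", "b", "c", "d"]
    rows = ["AAAA"] * 4
    tree = bootstrap_support(ids, rows, n_reps=20, seed=1)
    assert sorted(tree.root.leaf_names()) == ids

    # zero-distance star: every reported support (if any split exists) is 100
    def walk(node):
        for c in node.children:
            if not c.is_leaf:
                if c.support is not None:
                    assert c.support == 100.0
                walk(c)

    walk(tree.root)


def test_robinson_foulds_self_zero():
    rng = np.random.default_rng(2)
    taxa, m, _ = _random_additive_tree(6, rng)
    t = nj_tree(DistanceMatrix(taxa, m))
    assert robinson_foulds(t, t) == 0
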