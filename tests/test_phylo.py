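"""Distance matrices, neighbor joining on additive data, presence overlay."""

import math

import numpy as np
import pytest

from alkatlas.phylo import (AnnotatedTree, DistanceMatrix, PhyloTree, TreeNode,
                            distance_matrix, neighbor_joining, overlay_presence)
from alkatlas.synteny_classifier import Arrangement, ArrangementCall


# ---------------------------------------------------------------------------
# additive-tree machinery: generate a random tree, derive exact leaf
# distances, and compare NJ output splits/lengths against it
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary topology with strictly positive branch lengths.

    Returned as (children, length, label) nested tuples.
    """
    nodes = [("leaf", None, 0.0, f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0))
        nodes.append(("internal",
                      ((a[0], a[1], la, a[3]), (b[0], b[1], lb, b[3])),
                      0.0, None))
    return nodes[0]


def leaf_distances(tree) -> dict[frozenset, float]:
    """Path lengths between all leaf pairs, by recursion."""
    def walk(node):
        kind, children, _, label = node
        if kind == "leaf":
            return {label: 0.0}
        depths = {}
        for child in children:
            sub = walk(child)
            for leaf, d in sub.items():
                depths[leaf] = d + child[2]
        return depths

    def pairs(node, acc):
        kind, children, _, _ = node
        if kind == "leaf":
            return {node[3]: 0.0}
        sides = []
        for child in children:
            sub = pairs(child, acc)
            sides.append({l: d + child[2] for l, d in sub.items()})
        for a in sides[0]:
            for b in sides[1]:
                acc[frozenset((a, b))] = sides[0][a] + sides[1][b]
        merged = {}
        for s in sides:
            merged.update(s)
        return merged

    acc: dict[frozenset, float] = {}
    pairs(tree, acc)
    return acc


def tree_splits(tree, all_taxa: frozenset) -> dict[frozenset, float]:
    """Edge set of an additive tuple-tree as {canonical leaf bipartition: length}."""
    out = {}

    def walk(node):
        kind, children, _, label = node
        if kind == "leaf":
            return frozenset([label])
        below = frozenset()
        for child in children:
            sub = walk(child)
            key = canonical_split(sub, all_taxa)
            if 0 < len(key) < len(all_taxa):
                out[key] = out.get(key, 0.0) + child[2]
            below = below | sub
        return below

    walk(tree)
    return out


def canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def nj_splits(tree: PhyloTree, all_taxa: frozenset) -> dict[frozenset, float]:
    out = {}

    def walk(node: TreeNode):
        if not node.children:
            below = frozenset([node.name])
        else:
            below = frozenset()
            for c in node.children:
                below = below | walk(c)
        key = canonical_split(below, all_taxa)
        if 0 < len(key) < len(all_taxa):
            out[key] = out.get(key, 0.0) + node.length
        return below

    for c in tree.root.children:
        walk(c)
    return out


def dm_from_tree(tree, taxa: list[str]) -> DistanceMatrix:
    dist = leaf_distances(tree)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist[frozenset((taxa[i], taxa[j]))]
    return DistanceMatrix(taxa, d)


def assert_nj_recovers(tree, taxa):
    all_taxa = frozenset(taxa)
    dm = dm_from_tree(tree, list(taxa))
    result = neighbor_joining(dm)
    want = tree_splits(tree, all_taxa)
    got = nj_splits(result, all_taxa)
    # identical unrooted split sets with identical edge lengths
    assert set(got) == set(want)
    for key in want:
        assert got[key] == pytest.approx(want[key], abs=1e-9)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        dm = distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"}, "p_distance")
        assert dm.d[0, 1] == 0.0

    def test_p_distance_definition(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        dm = distance_matrix({"a": a, "b": b}, "p_distance")
        assert dm.d[0, 1] == pytest.approx(0.10)

    def test_jc_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        dm = distance_matrix({"a": a, "b": b}, "jukes_cantor")
        assert dm.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))

    def test_gap_positions_excluded_pairwise(self):
        dm = distance_matrix({"a": "AC-TA", "b": "ACG-A"}, "p_distance")
        assert dm.d[0, 1] == 0.0  # only 3 comparable, all equal

    def test_jc_saturation_error_names_pair(self):
        with pytest.raises(ValueError, match="a/b"):
            distance_matrix({"a": "AAAA", "b": "CCCC"}, "jukes_cantor")

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="equal-length"):
            distance_matrix({"a": "ACGT", "b": "ACG"})


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = [c.length for c in tree.root.children]
        assert sum(lengths) == pytest.approx(0.6)

    def test_three_equidistant_taxa_star(self):
        d = np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        assert [c.length for c in tree.root.children] == pytest.approx([0.5] * 3)

    def test_four_taxon_additive_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            tree = random_additive_tree(4, rng)
            assert_nj_recovers(tree, [f"t{i}" for i in range(4)])

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_random_additive_trees_recovered(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            tree = random_additive_tree(n_taxa, rng)
            assert_nj_recovers(tree, [f"t{i}" for i in range(n_taxa)])

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(55)
        tree = random_additive_tree(6, rng)
        taxa = [f"t{i}" for i in range(6)]
        dm = dm_from_tree(tree, taxa)
        base = nj_splits(neighbor_joining(dm), frozenset(taxa))
        perm = [3, 0, 5, 1, 4, 2]
        taxa_p = [taxa[i] for i in perm]
        d_p = dm.d[np.ix_(perm, perm)]
        other = nj_splits(neighbor_joining(DistanceMatrix(taxa_p, d_p)),
                          frozenset(taxa))
        assert set(base) == set(other)
        for k in base:
            assert base[k] == pytest.approx(other[k], abs=1e-9)

    def test_invalid_matrix(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a"], np.zeros((1, 1))))


# ---------------------------------------------------------------------------
# overlay
# ---------------------------------------------------------------------------

def _call(gid, arrangement):
    return ArrangementCall(gid, arrangement)


def _caterpillar(labels: list[str]) -> PhyloTree:
    root = TreeNode(children=[TreeNode(name=labels[0], length=1.0)])
    cur = root
    for name in labels[1:-1]:
        nxt = TreeNode(length=1.0, children=[TreeNode(name=name, length=1.0)])
        cur.children.append(nxt)
        cur = nxt
    cur.children.append(TreeNode(name=labels[-1], length=1.0))
    return PhyloTree(root)


class TestOverlay:
    def test_all_absent_is_one_group(self):
        tree = _caterpillar([f"g{i}" for i in range(5)])
        calls = [_call(f"g{i}", Arrangement.ABSENT) for i in range(5)]
        ann = overlay_presence(tree, calls)
        assert ann.absent_group_count == 1

    def test_absent_clade_counts_once(self):
        tree = _caterpillar(["g0", "g1", "g2", "g3", "g4", "g5"])
        arr = {"g0": Arrangement.TANDEM_PAIR, "g1": Arrangement.TANDEM_PAIR,
               "g2": Arrangement.SPLIT, "g3": Arrangement.ABSENT,
               "g4": Arrangement.ABSENT, "g5": Arrangement.ABSENT}
        ann = overlay_presence(tree, [_call(g, a) for g, a in arr.items()])
        assert ann.absent_group_count == 1

    def test_alternating_caterpillar_counts_each_absent_leaf(self):
        labels = [f"g{i}" for i in range(6)]
        tree = _caterpillar(labels)
        calls = [_call(g, Arrangement.ABSENT if i % 2 == 0
                       else Arrangement.TANDEM_PAIR)
                 for i, g in enumerate(labels)]
        ann = overlay_presence(tree, calls)
        assert ann.absent_group_count == 3

    def test_missing_call_listed(self):
        tree = _caterpillar(["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            overlay_presence(tree, [_call("g0", Arrangement.ABSENT),
                                    _call("g1", Arrangement.ABSENT)])

    def test_annotated_newick_contains_labels(self):
        tree = _caterpillar(["g0", "g1", "g2"])
        calls = [_call(g, Arrangement.TANDEM_PAIR) for g in ["g0", "g1", "g2"]]
        ann = overlay_presence(tree, calls)
        assert "g0|TANDEM_PAIR" in ann.newick()
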