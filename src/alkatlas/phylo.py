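"""Distance-based phylogenetics: pairwise distances, neighbor joining, and
presence/absence overlay onto the tree.

The survey's phylum-level picture is a 16S rRNA neighbor-joining tree with
each strain's alkane-locus arrangement painted onto the leaves. Distances
use pairwise deletion (sites gapped in either sequence of a pair are
skipped) under either the raw p-distance or the Jukes-Cantor correction
d = -(3/4) ln(1 - 4p/3). The NJ agglomeration follows the Saitou-Nei
Q-criterion with lexicographic tie-breaking so results are deterministic;
negative branch-length estimates are clamped to zero and the deficit logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)

_GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    taxon_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxon_ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def distance_matrix(
    aligned: Mapping[str, str],
    model: str = "jukes_cantor",
) -> DistanceMatrix:
    """Pairwise distances from an alignment with pairwise gap deletion.

    ``model`` is ``p_distance`` or ``jukes_cantor``. Under Jukes-Cantor a
    pairwise p >= 0.75 leaves the distance undefined and raises an error
    naming the pair.
    """
    if model not in ("p_distance", "jukes_cantor"):
        raise ValueError(f"unknown model {model!r}")
    taxa = list(aligned)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    length = {len(s) for s in aligned.values()}
    if len(length) != 1:
        raise ValueError("sequences are not equal-length (not aligned?)")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned[taxa[i]], aligned[taxa[j]]
            used = diffs = 0
            for x, y in zip(a, b):
                if x in _GAP_CHARS or y in _GAP_CHARS:
                    continue
                used += 1
                if x != y:
                    diffs += 1
            if used == 0:
                raise ValueError(f"no comparable sites for {taxa[i]}/{taxa[j]}")
            p = diffs / used
            if model == "p_distance":
                dist = p
            else:
                if p >= 0.75:
                    raise ValueError(
                        f"Jukes-Cantor undefined for {taxa[i]}/{taxa[j]}: p={p:.3f} >= 0.75"
                    )
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d)


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, digits: int = 6) -> str:
        return self._nwk(digits) + ";"

    def _nwk(self, digits: int) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{digits}g}"
        if not self.children:
            return f"{self.name}:{fmt(self.length)}"
        inner = ",".join(c._nwk(digits) for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{fmt(self.length)}"


@dataclass
class PhyloTree:
    root: TreeNode

    def newick(self, digits: int = 6) -> str:
        return self.root.newick(digits)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    For >= 3 taxa the result is the standard unrooted binary topology,
    returned rooted at the final three-way join. Ties in the Q-criterion are
    broken by the lexicographically smallest joined taxon-pair (internal
    nodes inherit the smallest leaf label beneath them), which makes the
    output independent of input order up to relabeling.
    """
    n = len(dm.taxon_ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxon_ids}
    # sort key per active node: smallest leaf label beneath it
    sortkey: dict[str, str] = {t: t for t in dm.taxon_ids}
    d: dict[tuple[str, str], float] = {}
    active = list(dm.taxon_ids)
    for i, a in enumerate(active):
        for j, b in enumerate(active):
            d[(a, b)] = float(dm.d[i, j])

    if n == 2:
        a, b = active
        half = d[(a, b)] / 2.0
        nodes[a].length = half
        nodes[b].length = d[(a, b)] - half
        return PhyloTree(TreeNode(children=[nodes[a], nodes[b]]))

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best_pair = None
        best_q = math.inf
        for a in active:
            for b in active:
                if a >= b:
                    continue
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                pair_key = tuple(sorted((sortkey[a], sortkey[b])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best_pair is not None
                    and pair_key < best_pair[2]
                ):
                    best_q = q
                    best_pair = (a, b, pair_key)
        a, b, _ = best_pair
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[(a, b)] - la
        la, lb = _clamp(la, a), _clamp(lb, b)
        new_name = f"_nj{counter}"
        counter += 1
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        parent = TreeNode(children=[na, nb])
        nodes[new_name] = parent
        sortkey[new_name] = min(sortkey[a], sortkey[b])
        for c in active:
            if c in (a, b):
                continue
            nd = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new_name, c)] = d[(c, new_name)] = max(0.0, nd)
        active = [c for c in active if c not in (a, b)] + [new_name]

    # final three-way join
    a, b, c = sorted(active, key=lambda x: sortkey[x])
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    for name, ln in ((a, la), (b, lb), (c, lc)):
        nodes[name].length = _clamp(ln, name)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


def _clamp(length: float, label: str) -> float:
    if length < 0:
        logger.info("clamped negative branch length %.6g at %s", length, label)
        return 0.0
    return length


@dataclass
class AnnotatedTree:
    tree: PhyloTree
    labels: dict[str, str]          # leaf -> arrangement label
    absent_group_count: int

    def newick(self, digits: int = 6) -> str:
        """Newick with an arrangement suffix appended to each leaf label."""
        def walk(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}|{self.labels[node.name]}:{node.length:.{digits}g}"
            inner = ",".join(walk(c) for c in node.children)
            return f"({inner}):{node.length:.{digits}g}"
        return walk(self.tree.root) + ";"


def overlay_presence(tree: PhyloTree, arrangement_calls) -> AnnotatedTree:
    """Annotate each leaf with its arrangement call and summarise clustering.

    ``absent_group_count`` counts maximal subtrees whose leaves are all
    ABSENT (with the NJ rooting): 1 when all absent strains form a single
    clade — the pattern seen at phylum scale, where most alkane-negative
    strains (the picocyanobacteria) sit on one branch.
    """
    calls = {c.genome_id: c.arrangement.value for c in arrangement_calls}
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in calls]
    if missing:
        raise ValueError(f"no arrangement call for leaves: {missing}")
    labels = {l: calls[l] for l in leaves}

    count = 0

    def pure_absent(node: TreeNode) -> bool:
        nonlocal count
        if not node.children:
            return labels[node.name] == "ABSENT"
        child_pure = [pure_absent(c) for c in node.children]
        if all(child_pure):
            return True
        for c, p in zip(node.children, child_pure):
            if p:
                count += 1
        return False

    if pure_absent(tree.root):
        count = 1
    return AnnotatedTree(tree, labels, count)
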