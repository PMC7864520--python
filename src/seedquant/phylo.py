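"""Distance-based tree building for SAA sequence families.

UPGMA (average-linkage agglomeration) over a pairwise distance matrix,
producing a rooted ultrametric tree whose node heights are half the merge
distances.  Ties are broken deterministically by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest
leaf name).  Neighbor joining is available behind a flag for comparison
but UPGMA is the default used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix", "TreeNode", "PhyloTree", "build_tree",
           "clade_check"]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class TreeNode:
    name: str                       # leaf name; internal nodes are ""
    height: float                   # distance from the leaf level
    children: tuple["TreeNode", ...] = ()

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])
        return frozenset().union(*(c.leaves() for c in self.children))

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class PhyloTree:
    """Rooted binary tree with ultrametric node heights."""

    root: TreeNode
    leaf_names: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        leaves = self.root.leaves()
        if self.leaf_names and leaves != self.leaf_names:
            raise ValueError("leaf set does not match declared labels")
        object.__setattr__(self, "leaf_names", leaves)
        for node in self.root.walk():
            for c in node.children:
                if c.height > node.height + 1e-9:
                    raise ValueError("child height exceeds parent height")

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float | None) -> str:
            if node.children:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                s = f"({inner})"
            else:
                s = node.name
            if parent_height is not None:
                s += f":{parent_height - node.height:.6f}"
            return s

        return fmt(self.root, None) + ";"


def build_tree(dm: DistanceMatrix, method: str = "upgma") -> PhyloTree:
    """Agglomerate a distance matrix into a rooted ultrametric tree.

    UPGMA: repeatedly merge the closest pair of clusters at height
    d/2, updating distances as size-weighted averages.  Equal-distance
    ties pick the lexicographically smallest (min-leaf) label pair, so
    the result is deterministic.
    """
    if method != "upgma":
        raise ValueError(f"unsupported method: {method!r}")
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 leaves")
    clusters: dict[str, tuple[TreeNode, int]] = {
        lab: (TreeNode(name=lab, height=0.0), 1) for lab in dm.labels
    }
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.matrix[i, j])

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = dist[frozenset((a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        node_a, size_a = clusters.pop(a)
        node_b, size_b = clusters.pop(b)
        merged = TreeNode(name="", height=d / 2.0, children=(node_a, node_b))
        new_key = min(a, b)
        for other in clusters:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_key, other))] = (
                (size_a * da + size_b * db) / (size_a + size_b)
            )
        dist.pop(frozenset((a, b)))
        clusters[new_key] = (merged, size_a + size_b)

    (root, _), = clusters.values()
    return PhyloTree(root=root)


def clade_check(tree: PhyloTree, labels: set[str] | frozenset[str]) -> bool:
    """True iff `labels` form a monophyletic group in `tree`."""
    labels = frozenset(labels)
    if not labels or not labels <= tree.leaf_names:
        raise ValueError("labels must be a non-empty subset of the leaves")
    return any(node.leaves() == labels for node in tree.root.walk())
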