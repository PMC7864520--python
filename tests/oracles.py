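"""Independent oracles shared by the unit and acceptance suites.

Each function here recomputes a quantity by a route independent of the
implementation it checks: straight-from-definition statistics,
fixed-step integration, exhaustive enumeration, or construction from a
known ground-truth object.
"""

import math

import numpy as np

from seedquant.phylo import DistanceMatrix, PhyloTree, TreeNode


def brute_force_sd(grid) -> float:
    """Two-pass population SD, straight from the definition."""
    vals = [float(v) for row in grid for v in row]
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    return math.sqrt(var)


def rk4_fixed_step(p, times, step):
    """Fixed-step RK4 integration of dF/dt = (kn + k+ F)(T - F)."""

    def rhs(f):
        m = p.total_monomer - f
        return p.nucleation_rate * m + p.elongation_rate * m * f

    f = p.seed_fraction * p.total_monomer
    out = [f]
    t = times[0]
    for t_next in times[1:]:
        n = max(1, int(math.ceil((t_next - t) / step)))
        h = (t_next - t) / n
        for _ in range(n):
            k1 = rhs(f)
            k2 = rhs(f + h / 2 * k1)
            k3 = rhs(f + h / 2 * k2)
            k4 = rhs(f + h * k3)
            f += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t_next
        out.append(f)
    return np.array(out) / p.total_monomer


def enumerate_best_score(a: str, b: str, score_fn, gap_open, gap_extend):
    """Exhaustive enumeration of every global alignment, affine-scored.

    A gap run of length L costs gap_open + (L-1)*gap_extend; recursion
    over (i, j, previous move) with no memoisation.
    """

    def gap_cost(prev, this):
        return gap_extend if prev == this else gap_open

    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, score_fn(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, gap_cost(prev, "U") + rec(i + 1, j, "U"))
        if j < len(b):
            best = max(best, gap_cost(prev, "L") + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, None)


def random_ultrametric_tree(rng, n_leaves) -> PhyloTree:
    """Random topology with strictly increasing merge heights."""
    nodes = [TreeNode(name=f"L{i}", height=0.0) for i in range(n_leaves)]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(name="", height=height, children=(a, b)))
    return PhyloTree(root=nodes[0])


def tree_clades(tree: PhyloTree):
    return {node.leaves() for node in tree.root.walk() if node.children}


def ultrametric_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Patristic distances of an ultrametric tree (2 x MRCA height)."""
    labels = sorted(tree.leaf_names)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    m = np.zeros((n, n))

    def fill(node):
        if not node.children:
            return
        left, right = node.children
        for a in left.leaves():
            for b in right.leaves():
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = 2 * node.height
        fill(left)
        fill(right)

    fill(tree.root)
    return DistanceMatrix(labels=tuple(labels), matrix=m)
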