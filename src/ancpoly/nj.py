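"""Neighbor joining (Saitou & Nei) with a deterministic tie rule.

Standard agglomerative NJ: at each step join the pair minimizing the
Q-criterion Q(i,j) = (n-2) d(i,j) - r_i - r_j, with branch lengths from the
usual three-point formulas.  Exact Q ties are broken by joining the pair
whose (lexicographically smallest member leaf names) sort first, so the
output is identical across platforms.  Negative branch lengths -- which NJ
can produce on non-additive input -- are clamped to zero and counted on the
returned tree.  On exactly additive matrices the generating topology and
branch lengths are recovered.

Also provides a random additive-tree generator used as the NJ consistency
oracle: leaf-to-leaf path lengths on a known random binary tree form an
additive matrix whose NJ reconstruction must match the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .tree import PhyloTree


@dataclass
class _Subtree:
    """An active NJ node: newick fragment plus its smallest leaf name."""

    newick: str
    min_leaf: str


def _fragment(sub: _Subtree, length: float) -> str:
    return f"{sub.newick}:{length:.17g}"


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Build the unrooted NJ tree for a distance matrix (n >= 3)."""
    n = len(matrix.strains)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 strains")
    d = np.array(matrix.values, dtype=float)
    if np.any(np.isnan(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")

    nodes = [_Subtree(name, name) for name in matrix.strains]
    clamped = 0

    def clamp(value: float) -> float:
        nonlocal clamped
        if value < 0.0:
            clamped += 1
            return 0.0
        return value

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, tuple[str, str], int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                names = tuple(sorted((nodes[i].min_leaf, nodes[j].min_leaf)))
                key = (q, names)
                if best is None or key < (best[0], best[1]):
                    best = (q, names, i, j)
        assert best is not None
        _, _, i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        joined = _Subtree(
            f"({_fragment(nodes[i], li)},{_fragment(nodes[j], lj)})",
            min(nodes[i].min_leaf, nodes[j].min_leaf),
        )
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [joined]

    a, b, c = nodes
    la = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    newick = f"({_fragment(a, la)},{_fragment(b, lb)},{_fragment(c, lc)});"
    tree = PhyloTree.from_newick(newick)
    tree.clamped_branches = clamped
    return tree


# ---------------------------------------------------------------------------
# additive-matrix oracle helpers


def random_binary_tree(
    names: list[str],
    rng: np.random.Generator,
    length_range: tuple[float, float] = (0.1, 2.0),
) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths.

    Grown by repeatedly attaching the next leaf to a uniformly chosen
    existing edge; every unrooted binary topology has positive probability.
    """
    if len(names) < 3:
        raise ValueError("need at least 3 leaf names")
    lo, hi = length_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    # adjacency map node_id -> list of (neighbor_id, length); leaves carry names
    next_id = [0]

    def fresh() -> int:
        next_id[0] += 1
        return next_id[0] - 1

    labels: dict[int, str] = {}
    adj: dict[int, dict[int, float]] = {}

    def add_edge(u: int, v: int, w: float) -> None:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    center = fresh()
    for name in names[:3]:
        leaf = fresh()
        labels[leaf] = name
        add_edge(center, leaf, blen())
    for name in names[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        split_at = fresh()
        del adj[u][v]
        del adj[v][u]
        frac = float(rng.uniform(0.2, 0.8))
        add_edge(u, split_at, w * frac)
        add_edge(split_at, v, w * (1 - frac))
        leaf = fresh()
        labels[leaf] = name
        add_edge(split_at, leaf, blen())

    def newick(node: int, parent: int | None) -> str:
        if node in labels:
            return labels[node]
        parts = [
            f"{newick(nb, node)}:{w:.17g}"
            for nb, w in sorted(adj[node].items())
            if nb != parent
        ]
        return "(" + ",".join(parts) + ")"

    return PhyloTree.from_newick(newick(center, None) + ";")


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) matrix of a tree.

    Computed through dendropy's phylogenetic distance matrix, keeping this
    oracle independent of the NJ code it is used to check.
    """
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    names = tree.leaf_names
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(
                taxa[names[i]], taxa[names[j]]
            )
    return DistanceMatrix(names, values)
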