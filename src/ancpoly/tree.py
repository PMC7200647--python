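"""Unrooted phylogenetic trees: bipartitions, branch support, small parsimony.

Trees are stored as dendropy trees (newick I/O, taxon handling) behind a thin
:class:`PhyloTree` wrapper that adds the operations this pipeline needs:

* the bipartition (split) set induced by internal edges, used both for
  Robinson--Foulds comparison and for chromosome-level branch support;
* clade membership queries for substrain clusters;
* minimum-mutation counts per site (Fitch small parsimony, computed with
  Hartigan's generalization so that the degree-3 seed node of an unrooted
  binary tree -- or any multifurcation -- is scored exactly).

A bipartition is represented rooting-free as a frozenset of the two frozen
leaf-name sets it induces; only non-trivial splits (both sides >= 2 leaves)
are enumerated, so a fully resolved unrooted binary tree with n leaves yields
exactly n - 3 of them.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

Bipartition = frozenset  # frozenset({frozenset(side_a), frozenset(side_b)})


def _format_length(value: float, digits: int = 10) -> str:
    return f"{value:.{digits}g}"


class PhyloTree:
    """An unrooted tree with named leaves and branch lengths."""

    def __init__(self, tree: dendropy.Tree, clamped_branches: int = 0):
        tree.is_rooted = False
        self._tree = tree
        self._suppress_root_bifurcation()
        #: number of negative NJ branch lengths clamped to zero (0 if built
        #: from newick or from an additive matrix)
        self.clamped_branches = clamped_branches
        self._bipartitions: set[Bipartition] | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read_newick(cls, path: str | os.PathLike) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic queries -----------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_names(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def _suppress_root_bifurcation(self) -> None:
        """Collapse a degree-2 seed node left over from a rooted newick."""
        seed = self._tree.seed_node
        children = seed.child_nodes()
        if len(children) != 2 or len(self) < 3:
            return
        internal = next((c for c in children if not c.is_leaf()), None)
        if internal is None:
            return
        other = children[0] if internal is children[1] else children[1]
        extra = internal.edge.length or 0.0
        seed.remove_child(internal)
        for grandchild in list(internal.child_nodes()):
            internal.remove_child(grandchild)
            seed.add_child(grandchild)
        if other.edge.length is not None or extra:
            other.edge.length = (other.edge.length or 0.0) + extra

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[Bipartition]:
        """Non-trivial splits induced by the internal edges."""
        if self._bipartitions is not None:
            return self._bipartitions
        all_leaves = frozenset(self.leaf_names)
        n = len(all_leaves)
        splits: set[Bipartition] = set()
        below: dict[dendropy.Node, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset({node.taxon.label})
            else:
                below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            if node is not self._tree.seed_node:
                side = below[node]
                if 2 <= len(side) <= n - 2:
                    splits.add(frozenset({side, all_leaves - side}))
        self._bipartitions = splits
        return splits

    def is_clade(self, names: Iterable[str]) -> bool:
        """True if `names` is one side of an edge of the tree.

        Trivial sides (single leaves and the full leaf set) count as clades.
        """
        side = frozenset(names)
        leaves = frozenset(self.leaf_names)
        if not side <= leaves:
            return False
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            return len(side) >= 1
        return any(side in split for split in self.bipartitions())

    def robinson_foulds(self, other: "PhyloTree") -> int:
        """Symmetric-difference (Robinson--Foulds) distance on split sets."""
        if set(self.leaf_names) != set(other.leaf_names):
            raise ValueError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    # -- newick output -----------------------------------------------------
    def write_newick(
        self,
        path: str | os.PathLike | None = None,
        support: "BranchSupport | None" = None,
        digits: int = 10,
    ) -> str:
        """Serialize to newick with branch lengths to `digits` significant
        figures; optional internal-node labels carry branch support values."""
        all_leaves = frozenset(self.leaf_names)
        n = len(all_leaves)

        def label_for(side: frozenset) -> str:
            if support is None or not (2 <= len(side) <= n - 2):
                return ""
            split = frozenset({side, all_leaves - side})
            pct = support.percent.get(split)
            return "" if pct is None else _format_length(pct, 4)

        below: dict[dendropy.Node, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            below[node] = (
                frozenset({node.taxon.label})
                if node.is_leaf()
                else frozenset().union(*(below[c] for c in node.child_nodes()))
            )

        out = io.StringIO()

        def write_node(node: dendropy.Node) -> None:
            if node.is_leaf():
                out.write(node.taxon.label)
            else:
                out.write("(")
                for i, child in enumerate(node.child_nodes()):
                    if i:
                        out.write(",")
                    write_node(child)
                    if child.edge.length is not None:
                        out.write(":" + _format_length(child.edge.length, digits))
                out.write(")")
                if node is not self._tree.seed_node:
                    out.write(label_for(below[node]))
                elif node.label:
                    out.write(str(node.label))

        write_node(self._tree.seed_node)
        out.write(";")
        text = out.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def support_labels(self) -> dict[Bipartition, float]:
        """Internal-node labels parsed back as split -> support percent."""
        all_leaves = frozenset(self.leaf_names)
        n = len(all_leaves)
        labels: dict[Bipartition, float] = {}
        below: dict[dendropy.Node, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset({node.taxon.label})
                continue
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            side = below[node]
            if node is self._tree.seed_node or not (2 <= len(side) <= n - 2):
                continue
            if node.label not in (None, ""):
                labels[frozenset({side, all_leaves - side})] = float(node.label)
        return labels


@dataclass
class BranchSupport:
    """Per-internal-edge agreement of a reference tree with comparison trees.

    `percent` maps each non-trivial split of the reference tree to
    100 * supporting / total, where a comparison tree supports a split when
    its own split set contains it (splits compared as unordered leaf-set
    pairs, i.e. rooting-free).
    """

    total: int
    counts: dict[Bipartition, int] = field(default_factory=dict)

    @property
    def percent(self) -> dict[Bipartition, float]:
        return {s: 100.0 * c / self.total for s, c in self.counts.items()}


def branch_support(
    reference_tree: PhyloTree, comparison_trees: Sequence[PhyloTree]
) -> BranchSupport:
    """Score each internal edge of `reference_tree` across comparison trees."""
    ref_leaves = set(reference_tree.leaf_names)
    for i, tree in enumerate(comparison_trees):
        if set(tree.leaf_names) != ref_leaves:
            raise ValueError(f"comparison tree {i} has a different leaf set")
    if not comparison_trees:
        raise ValueError("at least one comparison tree is required")
    counts = {split: 0 for split in reference_tree.bipartitions()}
    for tree in comparison_trees:
        other = tree.bipartitions()
        for split in counts:
            if split in other:
                counts[split] += 1
    return BranchSupport(total=len(comparison_trees), counts=counts)


def fitch_min_mutations(tree: PhyloTree, character: Mapping[str, str]) -> int:
    """Minimum number of state changes explaining a per-leaf character.

    Leaves absent from `character` carry no information and are ignored
    (pruned on the fly).  Implemented as Hartigan's bottom-up pass, which is
    exact for arbitrary node degrees and therefore rooting-invariant on the
    unrooted trees used here; on binary trees it coincides with Fitch's
    algorithm.
    """
    cost = 0

    def visit(node: dendropy.Node) -> frozenset | None:
        nonlocal cost
        if node.is_leaf():
            state = character.get(node.taxon.label)
            return None if state is None else frozenset({state})
        child_sets = [s for s in (visit(c) for c in node.child_nodes()) if s is not None]
        if not child_sets:
            return None
        tally: dict[str, int] = {}
        for s in child_sets:
            for state in s:
                tally[state] = tally.get(state, 0) + 1
        best = max(tally.values())
        cost += len(child_sets) - best
        return frozenset(s for s, c in tally.items() if c == best)

    visit(tree.dendropy_tree.seed_node)
    return cost
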