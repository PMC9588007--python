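"""Rooted phylogenies with branch lengths in expected substitutions per site.

Thin wrapper over a dendropy tree: Newick I/O (FastTree-style internal
support labels are tolerated and ignored), deterministic leaf ordering, and
re-rooting helpers used by the root-placement-invariance property of the
along-tree sequence simulator.
"""

from __future__ import annotations

import dendropy


class Phylogeny:
    """A single-rooted tree with non-negative, finite branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read_newick(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- basic structure ---------------------------------------------------

    def _validate(self) -> None:
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise ValueError("leaf names must be unique")
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            b = edge.length
            if b is not None and (b < 0 or b != b):
                raise ValueError(f"invalid branch length {b}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def branch_lengths(self) -> list[float]:
        """Lengths of all non-root edges (missing lengths count as 0)."""
        return [
            edge.length or 0.0
            for edge in self._tree.preorder_edge_iter()
            if edge.tail_node is not None
        ]

    def total_length(self) -> float:
        return sum(self.branch_lengths())

    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        return max(self._tree.calc_node_root_distances(return_leaf_distances_only=True))

    def scale(self, factor: float) -> "Phylogeny":
        """Return a copy with every branch length multiplied by ``factor``."""
        t = self._tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Phylogeny(t)

    def reroot_at(self, node_index: int) -> "Phylogeny":
        """Return a copy rooted at the ``node_index``-th internal node (preorder).

        Branch lengths are preserved, so path lengths between leaves are
        unchanged; only the direction of traversal differs.
        """
        t = self._tree.clone(depth=1)
        internal = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
        if not 0 <= node_index < len(internal):
            raise IndexError(f"no internal node {node_index}")
        t.reroot_at_node(internal[node_index], update_bipartitions=False)
        return Phylogeny(t)


def parse_newick(text: str) -> Phylogeny:
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()
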