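"""Phylogenetic tree container with lossless Newick round-tripping.

Support values are stored per internal node (conventionally bootstrap
percentages in [0, 100]) and serialized as internal node labels, the format
used by the classic parsimony/NJ programs.  Parsing is delegated to dendropy;
serialization is done here so that round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy

from .errors import NewickParseError, ValidationError


@dataclass
class Clade:
    """A node in a rooted tree view.  Leaves carry ``label``; internal nodes
    may carry ``support`` (or a free-text label) and a ``length`` to parent."""

    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Clade"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.postorder() if n.is_leaf]


class Tree:
    """A rooted view of a (possibly unrooted) tree with labelled leaves."""

    def __init__(self, root: Clade):
        self.root = root
        labels = root.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("tree leaf labels must be unique")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string.  Numeric internal-node labels are read as
        support values; non-numeric ones are kept as labels."""
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"invalid Newick: {exc}") from exc

        def convert(node: "dendropy.Node") -> Clade:
            if node.is_leaf():
                if node.taxon is None:
                    raise NewickParseError("leaf without a label")
                return Clade(label=node.taxon.label, length=node.edge.length)
            c = Clade(length=node.edge.length,
                      children=[convert(ch) for ch in node.child_nodes()])
            if node.label is not None:
                try:
                    c.support = float(node.label)
                except ValueError:
                    c.label = node.label
            return c

        return cls(convert(dt.seed_node))

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def fmt_num(x: float) -> str:
            return f"{int(x)}" if float(x).is_integer() else f"{x:g}"

        def fmt(node: Clade) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.support is not None:
                    s += fmt_num(node.support)
                elif node.label:
                    s += node.label
            if node.length is not None:
                s += f":{fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"

    def __str__(self) -> str:
        return self.to_newick()

    # -- queries ------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def postorder(self) -> Iterator[Clade]:
        return self.root.postorder()

    def copy(self) -> "Tree":
        def cp(n: Clade) -> Clade:
            return Clade(n.label, n.length, n.support, [cp(c) for c in n.children])
        return Tree(cp(self.root))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits as canonical frozensets: for each internal edge
        the leaf side *not* containing the lexicographically first leaf."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_labels())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def clade_sets(self) -> list[tuple[frozenset[str], Clade]]:
        """(leafset, node) for every node, postorder."""
        out = []
        for node in self.postorder():
            out.append((frozenset(node.leaf_labels()), node))
        return out

    def map_supports(self, support_of: Callable[[frozenset[str]], float | None]) -> None:
        """Attach supports to internal nodes keyed by their canonical split."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        for node in self.postorder():
            if node.is_leaf or node is self.root:
                continue
            side = frozenset(node.leaf_labels())
            if ref in side:
                side = all_leaves - side
            sup = support_of(side)
            if sup is not None:
                node.support = sup


def read_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`."""
    return Tree.from_newick(text)


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` to a Newick string."""
    return tree.to_newick()
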