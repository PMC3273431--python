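"""Phylogenetic tree container with newick input/output.

The tree is a rooted node structure; unrooted trees are represented with a
trifurcating root and ``rooted=False``.  Parsing delegates to dendropy; the
serializer is local so branch lengths round-trip at 10 significant digits.
"""
from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = ["Node", "PhyloTree", "NewickError", "parse_newick", "format_newick"]


class NewickError(ValueError):
    """Raised for malformed newick input."""


class Node:
    __slots__ = ("label", "length", "children", "parent", "support")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, length={self.length})"


class PhyloTree:
    """A tree with optional branch lengths and per-node bootstrap support."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dup}")

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def n_branches(self) -> int:
        return sum(1 for n in self.postorder() if n.parent is not None)

    # -- structure -------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            for child in node.children:
                new.add(_copy(child))
            return new

        return PhyloTree(_copy(self.root), rooted=self.rooted)

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions as canonical frozensets of leaf labels.

        The side not containing the lexicographically smallest leaf is used,
        so splits compare across differently rooted representations.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.postorder():
            if node.parent is None or node.is_leaf():
                continue
            side = frozenset(l.label for l in node.leaves())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def split_lengths(self) -> dict[frozenset, float]:
        """Branch lengths keyed by the (canonical) split each edge induces.

        Leaf edges are keyed by a singleton frozenset of the leaf label.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out: dict[frozenset, float] = {}
        for node in self.postorder():
            if node.parent is None or node.length is None:
                continue
            side = frozenset(l.label for l in node.leaves())
            if node.is_leaf():
                key = frozenset([node.label])
            else:
                key = all_leaves - side if ref in side else side
                if not (1 < len(key) < len(all_leaves) - 1):
                    continue
            out[key] = out.get(key, 0.0) + node.length
        return out

    # -- serialization ---------------------------------------------------
    def newick(self, support_as_label: bool = False) -> str:
        return _serialize(self.root, support_as_label) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.newick()})"


def _escape_label(label: str) -> str:
    if any(c in label for c in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _serialize(node: Node, support_as_label: bool) -> str:
    if node.is_leaf():
        out = _escape_label(node.label or "")
    else:
        inner = ",".join(_serialize(c, support_as_label) for c in node.children)
        if support_as_label and node.support is not None:
            tag = f"{node.support:g}"
        else:
            tag = _escape_label(node.label) if node.label else ""
        out = f"({inner}){tag}"
    if node.length is not None:
        out += f":{node.length:.10g}"
    return out


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree (rooted or unrooted, lengths optional)."""
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses in newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {exc}") from exc

    def _convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    root.length = None  # a root edge has no meaning here
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def format_newick(tree: PhyloTree) -> str:
    return tree.newick()
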