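"""Shared fixtures: reference sequences and small phylogenetic oracles."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from kunitzkit.io_formats import SequenceRecord
from kunitzkit.phylo import DistanceMatrix
from kunitzkit.tree import Node, PhyloTree

# Mature bovine pancreatic trypsin inhibitor (BPTI), 58 residues
# (UniProt P00974, mature chain).  Cysteines at mature positions
# 5/14/30/38/51/55 give the canonical spacing (8,15,7,12,3); the P1 site is
# Lys15.
BPTI_MATURE = (
    "RPDFCLEPPYTGPCKARIIRYFYNAKAGLCQTFVYGGCRAKRNNFKSAEDCMRTCGGA"
)


@pytest.fixture(scope="session")
def bpti_record() -> SequenceRecord:
    return SequenceRecord(id="BPTI", residues=BPTI_MATURE)


def build_domain_sequence(spacing, fill="A", subs=None, n_flank=3) -> str:
    """A sequence holding one six-cysteine domain with the given spacing.

    ``subs`` maps 0-based positions (within the returned string) to residues.
    """
    chars = list(fill * n_flank)
    for gap in spacing:
        chars.append("C")
        chars.extend(fill * gap)
    chars.append("C")
    chars.extend(fill * n_flank)
    if subs:
        for pos, aa in subs.items():
            chars[pos] = aa
    return "".join(chars)


def tree_path_distances(tree: PhyloTree):
    """(labels, matrix) of leaf-to-leaf path lengths."""
    labels = tree.leaf_labels()
    paths: dict[str, list] = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf():
            paths[node.label] = acc
        for child in node.children:
            walk(child, acc)

    walk(tree.root, [])
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            d = sum(nd.length for nd in pa[shared:]) + sum(
                nd.length for nd in pb[shared:]
            )
            D[i, j] = D[j, i] = d
    return labels, D


def enumerate_unrooted_topologies(labels):
    """All distinct unrooted binary topologies (3 for n=4, 15 for n=5)."""
    first = Node()
    for lbl in labels[:3]:
        first.add(Node(label=lbl))
    trees = [first]
    for lbl in labels[3:]:
        grown = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n.parent is not None]
            for k in range(len(edges)):
                clone_root = _clone(tree)
                clone_edges = [
                    n for n in clone_root.postorder() if n.parent is not None
                ]
                edge = clone_edges[k]
                parent = edge.parent
                idx = parent.children.index(edge)
                mid = Node()
                mid.add(edge)
                mid.add(Node(label=lbl))
                mid.parent = parent
                parent.children[idx] = mid
                grown.append(clone_root)
        trees = grown
    return [PhyloTree(t, rooted=False) for t in trees]


def _clone(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add(_clone(child))
    return new


def least_squares_topology(dm: DistanceMatrix):
    """Exhaustive least-squares oracle: best topology's split set.

    Fits branch lengths by ordinary least squares on the path-indicator
    system for every unrooted topology and returns the split set of the
    topology with minimal residual sum of squares.
    """
    labels = dm.labels
    best = None
    for tree in enumerate_unrooted_topologies(labels):
        edges = [n for n in tree.postorder() if n.parent is not None]
        pairs = list(itertools.combinations(range(len(labels)), 2))
        A = np.zeros((len(pairs), len(edges)))
        # mark edges on the path between each leaf pair
        leaf_nodes = {n.label: n for n in tree.leaves()}
        for row, (i, j) in enumerate(pairs):
            pa = _path_to_root(leaf_nodes[labels[i]])
            pb = _path_to_root(leaf_nodes[labels[j]])
            on_path = set(map(id, pa)) ^ set(map(id, pb))
            for col, e in enumerate(edges):
                if id(e) in on_path:
                    A[row, col] = 1.0
        y = np.array([dm.d[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ x - y) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, tree.splits())
    return best[1], best[0]


def _path_to_root(node: Node):
    out = []
    while node.parent is not None:
        out.append(node)
        node = node.parent
    return out
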