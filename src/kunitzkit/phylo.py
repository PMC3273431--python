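"""Protein distances and neighbor-joining tree construction.

Distances are p-distances over pairwise-shared ungapped columns (optionally
Poisson-corrected, d = -ln(1-p)).  Neighbor joining follows Saitou & Nei's
rate-corrected criterion with two determinism/robustness conventions: the
minimal-Q pair is chosen as the lowest (i, j) in row-major order, and a
negative pendant branch is clamped to zero with the deficit transferred to
its sibling.  Bootstrap support is the Felsenstein column bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord
from .tree import Node, PhyloTree, format_newick, parse_newick  # noqa: F401

__all__ = [
    "DistanceMatrix",
    "protein_distance",
    "neighbor_joining",
    "bootstrap_support",
    "PhyloTree",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(self.d).all():
            raise ValueError("distances must be finite")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def protein_distance(
    alignment: list[SequenceRecord], model: str = "p"
) -> DistanceMatrix:
    """Pairwise distances over shared ungapped columns.

    ``model="p"`` is the raw proportion of differing residues; ``"poisson"``
    applies d = -ln(1-p).  Columns where either sequence has a gap or an X
    are excluded pairwise.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    length = len(alignment[0].residues)
    if any(len(r.residues) != length for r in alignment):
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(r.residues) for r in alignment])
    valid = (arr != "-") & (arr != "X")
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"no shared ungapped columns between "
                    f"{alignment[i].id!r} and {alignment[j].id!r}"
                )
            p = float((arr[i, shared] != arr[j, shared]).mean())
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1 between {alignment[i].id!r} and "
                        f"{alignment[j].id!r}: Poisson correction undefined"
                    )
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=[r.id for r in alignment], d=d)


def _clamped_pair(dij: float, vi: float) -> tuple[float, float]:
    """Clamp a negative pendant length to 0, giving the deficit to its sibling."""
    vj = dij - vi
    if vi < 0:
        return 0.0, dij
    if vj < 0:
        return dij, 0.0
    return vi, vj


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration; returns an unrooted (trifurcating) tree."""
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    nodes: dict[int, Node] = {i: Node(label=lbl) for i, lbl in enumerate(dm.labels)}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: lowest (i, j) wins ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        vi, vj = _clamped_pair(dij, vi)
        parent = Node()
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length = vi
        child_j.length = vj
        parent.add(child_i)
        parent.add(child_j)
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[next_id, k] = D[k, next_id] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(idx)
        child.length = max(0.0, length)
        root.add(child)
    return PhyloTree(root, rooted=False)


def bootstrap_support(
    alignment: list[SequenceRecord],
    n_reps: int,
    seed: int = 0,
    model: str = "poisson",
) -> PhyloTree:
    """NJ tree from the full alignment, internal splits annotated with
    their frequency (x100) across column-bootstrap replicates.

    Replicates whose resampled distances are undefined (no shared columns or
    a saturated pair under the Poisson correction) are dropped; support is
    relative to the replicates that produced a tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = len(alignment[0].residues)
    if length < 1:
        raise ValueError("alignment must have at least one column")
    base = neighbor_joining(protein_distance(alignment, model=model))
    counts: dict[frozenset, int] = {s: 0 for s in base.splits()}
    rng = np.random.default_rng(seed)
    done = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(
                id=r.id,
                residues="".join(r.residues[c] for c in cols),
                description=r.description,
            )
            for r in alignment
        ]
        try:
            rep_tree = neighbor_joining(protein_distance(resampled, model=model))
        except ValueError:
            continue
        done += 1
        rep_splits = rep_tree.splits()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if done == 0:
        raise ValueError("all bootstrap replicates failed to produce a tree")
    all_leaves = frozenset(base.leaf_labels())
    ref = min(all_leaves)
    for node in base.postorder():
        if node.parent is None or node.is_leaf():
            continue
        side = frozenset(l.label for l in node.leaves())
        key = all_leaves - side if ref in side else side
        if key in counts:
            node.support = 100.0 * counts[key] / done
    return base
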