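"""Generators for every input the pipeline consumes.

The generators invert the analysis assumptions so each stage is testable
offline: proteins are built with exact group cysteine spacings (plus optional
functional motifs, signal-peptide-like prefixes and multi-domain
concatenations); codon alignments are evolved under a GY94 site-class
mixture along a tree; EST count matrices are drawn multinomially from
library sizes and per-stage expression profiles.

All randomness flows from one integer seed through named substreams, so
adding a generator never perturbs existing fixtures.
"""
from __future__ import annotations

import zlib

import numpy as np

from .codon import CodonAlignment, ReversibleGenerator, SENSE_CODONS, gy94_matrix
from .io_formats import CountMatrix, ESTLibrary, SequenceRecord
from .kunitz_domains import GROUP_PATTERNS
from .selection import SiteModel
from .tree import PhyloTree

__all__ = [
    "substream",
    "make_kunitz_proteins",
    "simulate_codon_alignment",
    "simulate_est_counts",
    "random_tree",
]

#: amino acids available for non-cysteine positions (C excluded so the only
#: cysteines are the six pattern-defining ones)
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"
_SIGNAL_CORE = "AFILMV"  # hydrophobic core letters of the fake signal peptide


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, deterministic child stream of the global seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def _random_domain(
    rng: np.random.Generator,
    group: str,
    p1_motif: str | None,
    channel_elements: bool | None,
) -> str:
    refs = GROUP_PATTERNS[group]
    spacing = refs[int(rng.integers(len(refs)))] if len(refs) > 1 else refs[0]
    chars: list[str] = []
    cys_positions: list[int] = []
    for gap_i, gap in enumerate([*spacing, None]):
        cys_positions.append(len(chars))
        chars.append("C")
        if gap is None:
            break
        chars.extend(rng.choice(list(_NON_CYS), size=gap))
    seq = chars

    if p1_motif == "trypsin":
        seq[cys_positions[1] + 1] = "KR"[int(rng.integers(2))]
        seq[cys_positions[1] + 2] = "A"
    elif p1_motif == "chymotrypsin":
        seq[cys_positions[1] + 1] = "FLNY"[int(rng.integers(4))]
        seq[cys_positions[1] + 2] = "G"
    elif p1_motif is not None:
        raise ValueError(f"unknown P1 motif {p1_motif!r}")

    base_start = cys_positions[3] - 3
    base_end = cys_positions[5]
    if channel_elements is True:
        # hydrophobic partner and basic residue 4 apart inside the base region
        h = cys_positions[3] + 2
        b = cys_positions[3] + 6
        seq[h] = "LYF"[int(rng.integers(3))]
        seq[b] = "KR"[int(rng.integers(2))]
    elif channel_elements is False:
        # known negative variants carry Q in place of the basic residue
        for i in range(max(0, base_start), base_end + 1):
            if seq[i] in "KR":
                seq[i] = "Q"
    return "".join(seq)


def make_kunitz_proteins(
    n: int,
    group: str = "I",
    n_domains: int = 1,
    seed: int = 0,
    *,
    signal_peptide: bool = False,
    p1_motif: str | None = None,
    channel_elements: bool | None = None,
    linker_range: tuple[int, int] = (8, 15),
    flank: tuple[int, int] = (3, 3),
    id_prefix: str | None = None,
) -> list[SequenceRecord]:
    """Proteins with exact group cysteine spacings (1-7 domains each)."""
    if group not in GROUP_PATTERNS:
        raise ValueError(f"unknown group {group!r}; expected one of I, II, III")
    if not 1 <= n_domains <= 7:
        raise ValueError("domains per protein must be between 1 and 7")
    rng = substream(seed, f"proteins/{group}/{n_domains}")
    prefix = id_prefix or f"syn{group}"
    records = []
    for i in range(n):
        parts: list[str] = []
        if signal_peptide:
            parts.append("M" + "".join(rng.choice(list(_SIGNAL_CORE), size=17)))
        parts.append("".join(rng.choice(list(_NON_CYS), size=flank[0])))
        for d in range(n_domains):
            if d:
                linker = int(rng.integers(linker_range[0], linker_range[1] + 1))
                parts.append("".join(rng.choice(list(_NON_CYS), size=linker)))
            parts.append(_random_domain(rng, group, p1_motif, channel_elements))
        parts.append("".join(rng.choice(list(_NON_CYS), size=flank[1])))
        records.append(
            SequenceRecord(
                id=f"{prefix}_{i + 1:04d}",
                residues="".join(parts),
                description=f"synthetic group {group} {n_domains}-domain protein",
            )
        )
    return records


def random_tree(
    n_taxa: int,
    seed: int = 0,
    length_range: tuple[float, float] = (0.05, 0.5),
    labels: list[str] | None = None,
) -> PhyloTree:
    """A random unrooted binary topology with uniform branch lengths."""
    from .tree import Node

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = substream(seed, f"tree/{n_taxa}")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    lo, hi = length_range

    def rlen() -> float:
        return float(rng.uniform(lo, hi))

    nodes = [Node(label=l, length=rlen()) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=rlen())
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return PhyloTree(root, rooted=False)


def simulate_codon_alignment(
    tree: PhyloTree,
    model: SiteModel,
    n_sites: int,
    seed: int = 0,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons along *tree* under the site-class mixture of *model*.

    Per site a class is drawn from the mixture, the root codon from pi, and
    each branch applies the exact matrix exponential P(t) of the class
    generator.  Returns the alignment and the true class index per site.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    rng = substream(seed, "codon_alignment")
    probs = model.class_probs()
    omegas = model.class_omegas()
    pi = np.asarray(model.pi, dtype=float)
    classes = rng.choice(len(probs), size=n_sites, p=probs)
    root_states = rng.choice(len(pi), size=n_sites, p=pi / pi.sum())

    gens = [
        ReversibleGenerator.from_q(gy94_matrix(model.kappa, float(w), pi), pi)
        for w in omegas
    ]
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            cur = root_states
        else:
            parent_states = states[id(node.parent)]
            cur = np.empty(n_sites, dtype=np.int64)
            for k in range(len(probs)):
                mask = classes == k
                if not mask.any():
                    continue
                P = gens[k].transition_stochastic(node.length or 0.0)
                cum = np.cumsum(P[parent_states[mask]], axis=1)
                u = rng.random(int(mask.sum()))
                cur[mask] = (u[:, None] > cum).sum(axis=1)
            states[id(node)] = cur
        if node.is_leaf():
            leaf_states[node.label] = states[id(node)]
    ids = tree.leaf_labels()
    rows = [[SENSE_CODONS[s] for s in leaf_states[l]] for l in ids]
    return CodonAlignment(ids=ids, codons=rows), classes


def simulate_est_counts(
    library_sizes,
    n_genes: int,
    seed: int = 0,
    *,
    library_names: list[str] | None = None,
    total_range: tuple[int, int] = (5, 50),
    diff_fraction: float = 0.0,
    diff_profile=(0.0, 0.06, 0.93, 0.01),
    diff_total: int | None = None,
) -> tuple[CountMatrix, list[bool]]:
    """EST counts: null genes follow library sizes, flagged genes a profile.

    Null genes redistribute their total multinomially with probabilities
    N_j / sum(N); differential genes use *diff_profile* (default: the
    mid-feeding burst shape of Isc.218, 0/17/259/2 normalized).  Returns the
    matrix plus per-gene truth flags (True = differential).
    """
    sizes = np.asarray(library_sizes, dtype=np.int64)
    if (sizes < 1).any():
        raise ValueError("library sizes must be positive")
    profile = np.asarray(diff_profile, dtype=float)
    if len(profile) != len(sizes):
        raise ValueError("profile length must match the number of libraries")
    if profile.min() < 0 or not np.isclose(profile.sum(), 1.0):
        raise ValueError("diff_profile must lie on the simplex")
    if not 0.0 <= diff_fraction <= 1.0:
        raise ValueError("diff_fraction must be in [0, 1]")
    rng = substream(seed, "est_counts")
    if library_names is None:
        library_names = [f"L{j + 1}" for j in range(len(sizes))]
    null_probs = sizes / sizes.sum()
    n_diff = int(round(diff_fraction * n_genes))
    flags = [i < n_diff for i in range(n_genes)]
    counts = np.zeros((n_genes, len(sizes)), dtype=np.int64)
    for i in range(n_genes):
        if flags[i] and diff_total is not None:
            total = diff_total
        else:
            total = int(rng.integers(total_range[0], total_range[1] + 1))
        counts[i] = rng.multinomial(total, profile if flags[i] else null_probs)
    libraries = [
        ESTLibrary(name=name, total_size=int(sz), stage=j)
        for j, (name, sz) in enumerate(zip(library_names, sizes))
    ]
    matrix = CountMatrix(
        gene_ids=[f"gene{i + 1:04d}" for i in range(n_genes)],
        libraries=libraries,
        counts=counts,
    )
    return matrix, flags
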