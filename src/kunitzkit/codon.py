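"""Universal genetic code tables, codon alignments and the GY94 generator.

The Goldman-Yang codon model parameterizes substitution between the 61 sense
codons: single-nucleotide changes occur at rate proportional to the target
codon frequency pi_j, multiplied by kappa for transitions and by omega
(= dN/dS) for nonsynonymous changes; multi-nucleotide changes are forbidden.
The generator is scaled to one expected substitution per codon per unit
branch length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "CODON_AA",
    "STOP_CODONS",
    "GAP_CODON",
    "CodonAlignment",
    "codon_frequencies",
    "thread_codon_alignment",
    "gy94_matrix",
    "ReversibleGenerator",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {codon: i for i, codon in enumerate(SENSE_CODONS)}
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)
GAP_CODON = "---"

_PURINES = frozenset("AG")


def is_transition(x: str, y: str) -> bool:
    return x != y and (x in _PURINES) == (y in _PURINES)


def _pair_structure():
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) == 1:
                single[i, j] = True
                k = diffs[0]
                transition[i, j] = is_transition(ci[k], cj[k])
                synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


SINGLE_CHANGE, TRANSITION, SYNONYMOUS = _pair_structure()


@dataclass
class CodonAlignment:
    """Equal-length codon sequences over the 61 sense codons ('---' = gap)."""

    ids: list[str]
    codons: list[list[str]]

    def __post_init__(self):
        if len(self.ids) != len(self.codons):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.codons:
            n = len(self.codons[0])
            for sid, row in zip(self.ids, self.codons):
                if len(row) != n:
                    raise ValueError(f"{sid}: codon length differs")
                for k, codon in enumerate(row, start=1):
                    if codon == GAP_CODON:
                        continue
                    if codon in STOP_CODONS:
                        raise ValueError(f"{sid}: stop codon {codon} at site {k}")
                    if codon not in CODON_INDEX:
                        raise ValueError(f"{sid}: malformed codon {codon!r} at site {k}")

    @classmethod
    def from_sequences(cls, ids: list[str], sequences: list[str]) -> "CodonAlignment":
        rows = []
        for sid, seq in zip(ids, sequences):
            seq = seq.upper()
            if len(seq) % 3:
                raise ValueError(f"{sid}: length {len(seq)} not a multiple of 3")
            rows.append([seq[i : i + 3] for i in range(0, len(seq), 3)])
        return cls(ids=list(ids), codons=rows)

    @property
    def n_sites(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def to_indices(self) -> np.ndarray:
        """(n_seq, n_sites) codon indices; -1 marks gap codons."""
        out = np.full((len(self.ids), self.n_sites), -1, dtype=np.int64)
        for i, row in enumerate(self.codons):
            for j, codon in enumerate(row):
                if codon != GAP_CODON:
                    out[i, j] = CODON_INDEX[codon]
        return out

    def sequences(self) -> dict[str, str]:
        return {sid: "".join(row) for sid, row in zip(self.ids, self.codons)}


def codon_frequencies(alignment: CodonAlignment, scheme: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies: equal, F1x4 or F3x4 (positional)."""
    if not alignment.ids:
        raise ValueError("empty alignment")
    if scheme == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for row in alignment.codons:
        for codon in row:
            if codon == GAP_CODON:
                continue
            for pos, nt in enumerate(codon):
                counts[pos, base_idx[nt]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no codons")
    if scheme == "F1x4":
        f = counts.sum(axis=0)
        f = f / f.sum()
        freq_by_pos = np.stack([f, f, f])
    elif scheme == "F3x4":
        freq_by_pos = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown frequency scheme {scheme!r}")
    pi = np.array(
        [
            freq_by_pos[0, base_idx[c[0]]]
            * freq_by_pos[1, base_idx[c[1]]]
            * freq_by_pos[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide composition: all sense codons have zero frequency")
    return pi / total


def thread_codon_alignment(
    protein_alignment: list, cds_by_id: dict[str, str]
) -> CodonAlignment:
    """Back-translate a protein alignment onto in-frame CDSs (PAL2NAL style).

    Each aligned residue is replaced by its codon; gap columns become '---'.
    The CDS must translate to the ungapped protein (X matches anything).
    """
    from .io_formats import translate_cds  # local import avoids cycle at import time

    ids, rows = [], []
    for rec in protein_alignment:
        if rec.id not in cds_by_id:
            raise KeyError(f"no CDS for {rec.id!r}")
        cds = cds_by_id[rec.id].upper()
        core = rec.residues.replace("-", "")
        if len(cds) != 3 * len(core):
            raise ValueError(
                f"{rec.id}: CDS length {len(cds)} != 3 x {len(core)} residues"
            )
        protein = translate_cds(cds)
        for k, (aa, expected) in enumerate(zip(protein, core), start=1):
            if expected != "X" and aa != expected:
                raise ValueError(
                    f"{rec.id}: CDS translates to {aa!r} at residue {k}, "
                    f"expected {expected!r}"
                )
        row = []
        cursor = 0
        for aa in rec.residues:
            if aa == "-":
                row.append(GAP_CODON)
            else:
                row.append(cds[3 * cursor : 3 * cursor + 3])
                cursor += 1
        ids.append(rec.id)
        rows.append(row)
    return CodonAlignment(ids=ids, codons=rows)


def gy94_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator Q (61x61), scaled to unit mean substitution rate."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a 61-simplex vector")
    rates = np.where(TRANSITION, kappa, 1.0) * np.where(SYNONYMOUS, 1.0, omega)
    Q = np.where(SINGLE_CHANGE, rates * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate model: zero mean substitution rate")
    return Q / mean_rate


@dataclass
class ReversibleGenerator:
    """Eigendecomposition of a reversible generator for cheap P(t) = exp(Qt).

    Uses the similarity transform B = D^{1/2} Q D^{-1/2} (symmetric for a
    time-reversible Q with stationary distribution pi), so a single `eigh`
    serves every branch length.
    """

    evals: np.ndarray
    right: np.ndarray  # D^{-1/2} U
    left: np.ndarray  # U^T D^{1/2}

    @classmethod
    def from_q(cls, Q: np.ndarray, pi: np.ndarray) -> "ReversibleGenerator":
        pi = np.asarray(pi, dtype=float)
        if (pi <= 0).any():
            raise ValueError("spectral decomposition needs strictly positive pi")
        s = np.sqrt(pi)
        B = Q * (s[:, None] / s[None, :])
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        evals, U = np.linalg.eigh(B)
        return cls(evals=evals, right=U / s[:, None], left=U.T * s[None, :])

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self.right * np.exp(self.evals * t)) @ self.left
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_stochastic(self, t: float) -> np.ndarray:
        """Row-renormalized P(t) for simulation sampling."""
        P = self.transition(t)
        return P / P.sum(axis=1, keepdims=True)
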