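"""Readers and writers for the formats the pipeline touches.

Protein/nucleotide FASTA, tab-separated EST count tables (with a mandatory
TOTAL row carrying library sizes) and newick trees.  All coordinates are
0-based half-open internally; user-facing reports add 1-based positions.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .tree import NewickError, PhyloTree, format_newick, parse_newick  # noqa: F401

__all__ = [
    "SequenceRecord",
    "ESTLibrary",
    "CountMatrix",
    "FastaParseError",
    "read_fasta",
    "read_nucleotide_fasta",
    "write_fasta",
    "attach_cds",
    "read_est_counts",
    "write_est_counts",
    "parse_newick",
    "format_newick",
    "PhyloTree",
    "NewickError",
]

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_PROTEIN = "X"
GAP = "-"
NUCLEOTIDES = frozenset("ACGT")


class FastaParseError(ValueError):
    """Malformed FASTA; carries the 1-based line number of the offence."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS under the universal genetic code."""
    return str(Seq(cds).translate())


@dataclass
class SequenceRecord:
    """A protein sequence, optionally aligned (gaps) and with its CDS."""

    id: str
    residues: str
    description: str = ""
    cds: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - PROTEIN_LETTERS - {AMBIGUOUS_PROTEIN, GAP}
        if bad:
            raise ValueError(f"{self.id}: illegal residue(s) {sorted(bad)}")
        if self.cds is not None:
            self.cds = self.cds.upper()
            self._check_cds()

    def _check_cds(self) -> None:
        bad = set(self.cds) - NUCLEOTIDES
        if bad:
            raise ValueError(f"{self.id}: illegal CDS character(s) {sorted(bad)}")
        core = self.ungapped()
        if len(self.cds) != 3 * len(core):
            raise ValueError(
                f"{self.id}: CDS length {len(self.cds)} != 3 x {len(core)} residues"
            )
        protein = translate_cds(self.cds)
        for i, (aa, expected) in enumerate(zip(protein, core), start=1):
            if expected != AMBIGUOUS_PROTEIN and aa != expected:
                raise ValueError(
                    f"{self.id}: CDS translates to {aa!r} at residue {i}, "
                    f"expected {expected!r}"
                )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ESTLibrary:
    """A cDNA library: name, total EST count N_j and its feeding-stage rank."""

    name: str
    total_size: int
    stage: int

    def __post_init__(self):
        if self.total_size < 1:
            raise ValueError(f"library {self.name}: total_size must be >= 1")


@dataclass
class CountMatrix:
    """Per-gene EST counts (x_ij) across an ordered set of libraries."""

    gene_ids: list[str]
    libraries: list[ESTLibrary]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.libraries)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.libraries)} libraries"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        sizes = np.array([lib.total_size for lib in self.libraries])
        if self.counts.size and (self.counts > sizes[None, :]).any():
            g, j = np.argwhere(self.counts > sizes[None, :])[0]
            raise ValueError(
                f"gene {self.gene_ids[g]} has {self.counts[g, j]} ESTs in "
                f"{self.libraries[j].name} but the library holds only {sizes[j]}"
            )
        stages = [lib.stage for lib in self.libraries]
        if stages != sorted(stages) or len(set(stages)) != len(stages):
            raise ValueError("library stages must be strictly increasing")

    @property
    def library_sizes(self) -> np.ndarray:
        return np.array([lib.total_size for lib in self.libraries], dtype=np.int64)

    @property
    def library_names(self) -> list[str]:
        return [lib.name for lib in self.libraries]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(source):
    """Accept a path, an open text handle, or raw FASTA content."""
    if hasattr(source, "read"):
        return source, False
    if isinstance(source, (str, os.PathLike)):
        text = str(source)
        if text.lstrip().startswith(">"):
            return io.StringIO(text), False
        return open(source, "r", encoding="utf-8"), True
    raise TypeError(f"cannot read FASTA from {type(source)!r}")


def _read_fasta_generic(source, allowed: frozenset, kind: str):
    handle, should_close = _open_text(source)
    records: list[tuple[str, str, str]] = []
    try:
        header: tuple[str, str] | None = None
        header_line = 0
        chunks: list[str] = []

        def _finish(end_line):
            assert header is not None
            seq = "".join(chunks)
            if not seq:
                raise FastaParseError(f"record {header[0]!r} has no sequence", header_line)
            records.append((header[0], header[1], seq))

        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    _finish(line_no)
                name = line[1:].strip()
                if not name:
                    raise FastaParseError("empty FASTA header", line_no)
                parts = name.split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else "")
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise FastaParseError("sequence data before first '>' header", line_no)
                seg = line.upper()
                bad = set(seg) - allowed
                if bad:
                    raise FastaParseError(
                        f"illegal {kind} character(s) {sorted(bad)}", line_no
                    )
                chunks.append(seg)
        if header is not None:
            _finish(None)
    finally:
        if should_close:
            handle.close()
    return records


def read_fasta(source) -> list[SequenceRecord]:
    """Read protein FASTA (20 amino acids + X; '-' allowed for alignments)."""
    allowed = PROTEIN_LETTERS | {AMBIGUOUS_PROTEIN, GAP}
    return [
        SequenceRecord(id=i, residues=seq, description=desc)
        for i, desc, seq in _read_fasta_generic(source, allowed, "amino-acid")
    ]


def read_nucleotide_fasta(source) -> dict[str, str]:
    """Read nucleotide FASTA (strict ACGT) into an ordered id -> sequence map."""
    out: dict[str, str] = {}
    for i, _desc, seq in _read_fasta_generic(source, NUCLEOTIDES | {GAP}, "nucleotide"):
        if i in out:
            raise ValueError(f"duplicate sequence id {i!r}")
        out[i] = seq
    return out


def attach_cds(records: list[SequenceRecord], cds_by_id: dict[str, str]) -> list[SequenceRecord]:
    """Return copies of *records* with their coding sequences attached."""
    out = []
    for rec in records:
        if rec.id not in cds_by_id:
            raise KeyError(f"no CDS provided for {rec.id!r}")
        out.append(
            SequenceRecord(
                id=rec.id,
                residues=rec.residues,
                description=rec.description,
                cds=cds_by_id[rec.id],
            )
        )
    return out


def write_fasta(records: list[SequenceRecord], wrap: int = 60) -> str:
    """Serialize records to FASTA with sequence lines of *wrap* characters."""
    if wrap < 1:
        raise ValueError(f"wrap must be >= 1, got {wrap}")
    lines: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        lines.append(header)
        for i in range(0, len(rec.residues), wrap):
            lines.append(rec.residues[i : i + wrap])
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# EST count tables
# ---------------------------------------------------------------------------

TOTAL_ROW = "TOTAL"


def read_est_counts(source) -> CountMatrix:
    """Read a TSV count table: header of library names, gene rows, a TOTAL row.

    Library stage order is the column order of the table.
    """
    handle, should_close = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", index_col=0, dtype=str)
    finally:
        if should_close:
            handle.close()
    if df.index.name is None and df.empty and not len(df.columns):
        raise ValueError("empty count table")
    values = df.map(lambda v: str(v).strip())
    for gene, row in values.iterrows():
        for lib, v in row.items():
            if not v.lstrip("-").isdigit():
                raise ValueError(f"non-integer entry {v!r} for {gene}/{lib}")
            if int(v) < 0:
                raise ValueError(f"negative entry {v} for {gene}/{lib}")
    table = values.astype(np.int64)
    if TOTAL_ROW not in table.index:
        raise ValueError(f"count table is missing the {TOTAL_ROW!r} row of library sizes")
    totals = table.loc[TOTAL_ROW]
    genes = table.drop(index=TOTAL_ROW)
    libraries = [
        ESTLibrary(name=str(name), total_size=int(totals[name]), stage=j)
        for j, name in enumerate(table.columns)
    ]
    return CountMatrix(
        gene_ids=[str(g) for g in genes.index],
        libraries=libraries,
        counts=genes.to_numpy(dtype=np.int64).reshape(len(genes.index), len(libraries)),
    )


def write_est_counts(matrix: CountMatrix) -> str:
    """Inverse of :func:`read_est_counts`."""
    header = "\t".join(["gene"] + matrix.library_names)
    lines = [header]
    for gene, row in zip(matrix.gene_ids, matrix.counts):
        lines.append("\t".join([gene] + [str(int(v)) for v in row]))
    lines.append("\t".join([TOTAL_ROW] + [str(lib.total_size) for lib in matrix.libraries]))
    return "\n".join(lines) + "\n"
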