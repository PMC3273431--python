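"""Kunitz/BPTI domain detection by cysteine spacing.

A Kunitz/BPTI domain is defined here by its six conserved cysteines (C1-C6,
disulfide-bonded 1-6, 2-4, 3-5) and the residue counts between consecutive
cysteines.  The three single-domain groups found in Ixodes ticks follow the
spacings

    group I   C X(8)   C X(15) C X(7) C X(12) C X(3) C   (canonical, BPTI-like)
    group II  C X(8)   C X(18) C X(5) C X(12) C X(3) C
    group III C X(5,6) C X(15) C X(8) C X(11) C X(3) C

Detection scans six-cysteine windows left to right with a per-gap tolerance;
classification assigns the nearest group in L1 distance over spacings.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io_formats import SequenceRecord

__all__ = [
    "KunitzDomain",
    "DomainArchitecture",
    "GROUP_PATTERNS",
    "find_kunitz_domains",
    "classify_group",
    "scan_record",
    "split_multidomain",
    "architecture",
    "domain_coding_length",
]

#: Reference spacing vectors (residues strictly between consecutive cysteines).
GROUP_PATTERNS: dict[str, tuple[tuple[int, ...], ...]] = {
    "I": ((8, 15, 7, 12, 3),),
    "II": ((8, 18, 5, 12, 3),),
    "III": ((5, 15, 8, 11, 3), (6, 15, 8, 11, 3)),
}

UNCLASSIFIED = "unclassified"

#: Padding kept around the cysteine core when extracting a domain segment.
SEGMENT_MARGIN_BEFORE_C1 = 5
SEGMENT_MARGIN_AFTER_C6 = 2


@dataclass
class KunitzDomain:
    """One detected domain: six cysteine positions (0-based) in the parent."""

    parent_id: str
    cys_positions: tuple[int, ...]
    spacing: tuple[int, ...]
    segment_start: int
    segment_end: int
    group: str = UNCLASSIFIED
    exact_match: bool = False

    def __post_init__(self):
        if len(self.cys_positions) != 6:
            raise ValueError("a Kunitz domain needs exactly six cysteines")
        expected = tuple(
            self.cys_positions[i + 1] - self.cys_positions[i] - 1 for i in range(5)
        )
        if tuple(self.spacing) != expected:
            raise ValueError(f"spacing {self.spacing} inconsistent with cysteine positions")
        if not (self.segment_start <= self.cys_positions[0] and self.cys_positions[-1] < self.segment_end):
            raise ValueError("segment does not cover all six cysteines")


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping domains of one protein with a count label."""

    parent_id: str
    domains: list[KunitzDomain]
    label: str
    has_signal_peptide: bool | None = None

    def __post_init__(self):
        starts = [d.segment_start for d in self.domains]
        if starts != sorted(starts):
            raise ValueError("domains must be sorted by segment start")
        for a, b in zip(self.domains, self.domains[1:]):
            if b.cys_positions[0] <= a.cys_positions[-1]:
                raise ValueError("overlapping domains")


_NUMBER_WORDS = {
    0: "Zero", 1: "One", 2: "Two", 3: "Three", 4: "Four",
    5: "Five", 6: "Six", 7: "Seven",
}


def _spacing_of(window: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(window[i + 1] - window[i] - 1 for i in range(5))


def _within_tolerance(spacing, reference, tolerance) -> bool:
    return all(abs(s - r) <= tolerance for s, r in zip(spacing, reference))


def _exact(spacing) -> bool:
    return any(
        tuple(spacing) == ref for refs in GROUP_PATTERNS.values() for ref in refs
    )


def find_kunitz_domains(record: SequenceRecord, tolerance: int = 2) -> list[KunitzDomain]:
    """All non-overlapping six-cysteine windows near a reference pattern.

    The sequence is scanned left to right over consecutive cysteines; the
    earliest matching window wins and its six cysteines are consumed.
    Returned domains carry ``group="unclassified"``; use
    :func:`classify_group` (or :func:`scan_record`) to label them.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    seq = record.residues
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    domains: list[KunitzDomain] = []
    i = 0
    while i + 6 <= len(cys):
        window = tuple(cys[i : i + 6])
        spacing = _spacing_of(window)
        match = any(
            _within_tolerance(spacing, ref, tolerance)
            for refs in GROUP_PATTERNS.values()
            for ref in refs
        )
        if match:
            domains.append(
                KunitzDomain(
                    parent_id=record.id,
                    cys_positions=window,
                    spacing=spacing,
                    segment_start=max(0, window[0] - SEGMENT_MARGIN_BEFORE_C1),
                    segment_end=min(len(seq), window[-1] + SEGMENT_MARGIN_AFTER_C6 + 1),
                    exact_match=_exact(spacing),
                )
            )
            i += 6
        else:
            i += 1
    return domains


def classify_group(domain: KunitzDomain, max_l1: int = 3) -> str:
    """Assign a group label by spacing; sets ``group`` and ``exact_match``.

    Exact spacing matches map directly; otherwise the group minimizing the L1
    distance between spacing vectors wins when that distance is at most
    *max_l1* (group III takes the minimum over its two references).  Ties and
    larger distances yield ``unclassified``.
    """
    spacing = tuple(domain.spacing)
    distances: dict[str, int] = {}
    for group, refs in GROUP_PATTERNS.items():
        distances[group] = min(
            sum(abs(s - r) for s, r in zip(spacing, ref)) for ref in refs
        )
    best = min(distances.values())
    winners = [g for g, d in distances.items() if d == best]
    if best == 0:
        domain.group = winners[0]
        domain.exact_match = True
    elif best <= max_l1 and len(winners) == 1:
        domain.group = winners[0]
        domain.exact_match = False
    else:
        domain.group = UNCLASSIFIED
        domain.exact_match = False
    return domain.group


def scan_record(
    record: SequenceRecord, tolerance: int = 2, max_l1: int = 3
) -> list[KunitzDomain]:
    """Detect and classify all domains of one protein."""
    domains = find_kunitz_domains(record, tolerance=tolerance)
    for d in domains:
        classify_group(d, max_l1=max_l1)
    return domains


def split_multidomain(
    record: SequenceRecord, domains: list[KunitzDomain]
) -> list[SequenceRecord]:
    """Cut a protein into one record per domain (ids suffixed ``_d1``...).

    Each segment runs from 5 residues before C1 (clamped to the start) through
    2 residues after C6 (clamped to the end), keeping enough context for the
    P1-motif checks downstream.
    """
    ordered = sorted(domains, key=lambda d: d.segment_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.cys_positions[0] <= a.cys_positions[-1]:
            raise ValueError(
                f"{record.id}: overlapping domains at cysteines "
                f"{a.cys_positions[-1]} / {b.cys_positions[0]}"
            )
    out = []
    for k, dom in enumerate(ordered, start=1):
        out.append(
            SequenceRecord(
                id=f"{record.id}_d{k}",
                residues=record.residues[dom.segment_start : dom.segment_end],
                description=f"domain {k} of {record.id}",
            )
        )
    return out


def architecture(
    record: SequenceRecord,
    domains: list[KunitzDomain],
    has_signal_peptide: bool | None = None,
) -> DomainArchitecture:
    """Label a protein by its domain count (One-KU ... Seven-KU)."""
    ordered = sorted(domains, key=lambda d: d.segment_start)
    n = len(ordered)
    if n > 7:
        warnings.warn(
            f"{record.id}: {n} Kunitz domains exceeds the largest architecture "
            "observed in ticks (Seven-KU)",
            stacklevel=2,
        )
    word = _NUMBER_WORDS.get(n, str(n))
    return DomainArchitecture(
        parent_id=record.id,
        domains=ordered,
        label=f"{word}-KU",
        has_signal_peptide=has_signal_peptide,
    )


def domain_coding_length(domain_aa_length: int) -> int:
    """Nucleotides encoding a domain of the given residue count (3 per aa).

    The canonical ~60-aa Kunitz domain is encoded by a single ~180-bp exon.
    """
    if domain_aa_length < 1:
        raise ValueError("domain length must be a positive residue count")
    return 3 * int(domain_aa_length)
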