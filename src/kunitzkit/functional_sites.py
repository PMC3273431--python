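"""Functional annotation of Kunitz/BPTI domains.

Three annotations per domain:

* the P1 site — the residue immediately after the second cysteine, which is
  inserted into a serine protease's catalytic cleft (Lys15 in BPTI);
* the inhibitor motif class — trypsin inhibitors carry a basic P1 (K/R)
  followed by a small residue (C2-[K/R]-s), chymotrypsin inhibitors a bulky
  P1 (F/L/N/Y) followed by a small residue;
* channel-modulating structural elements — a basic residue (R/K) close to a
  hydrophobic partner (L/Y/F) in the "base" of the fold (the C-terminal
  third holding the 3-10 helix and beta-turn).
"""
from __future__ import annotations

from dataclasses import dataclass

from .io_formats import SequenceRecord
from .kunitz_domains import KunitzDomain

__all__ = [
    "FunctionalAnnotation",
    "SMALL_RESIDUES",
    "locate_p1",
    "classify_inhibitor",
    "detect_channel_elements",
    "annotate_domain",
]

SMALL_RESIDUES = frozenset("GASCT")
LARGE_P1 = frozenset("FLNY")
BASIC = frozenset("KR")
HYDROPHOBIC_PARTNER = frozenset("LYF")

#: How far before C4 the structural "base" region starts.
BASE_OFFSET_BEFORE_C4 = 3
DEFAULT_CHANNEL_WINDOW = 6


@dataclass
class FunctionalAnnotation:
    parent_id: str
    p1_position: int  # 0-based index into the parent residues
    p1_residue: str
    inhibitor_class: str  # trypsin | chymotrypsin | none
    channel_modulator: bool
    channel_evidence: tuple[int, int] | None = None  # (basic, hydrophobic), 0-based

    def __post_init__(self):
        if self.inhibitor_class == "trypsin" and self.p1_residue not in BASIC:
            raise ValueError("trypsin call requires a basic P1 residue")
        if self.channel_modulator and self.channel_evidence is None:
            raise ValueError("channel-modulator call requires an evidence pair")


def locate_p1(domain: KunitzDomain, record: SequenceRecord) -> tuple[int, str]:
    """Position (0-based) and identity of the residue right after C2."""
    pos = domain.cys_positions[1] + 1
    if pos >= len(record.residues):
        raise ValueError(
            f"{record.id}: C2 is the last residue; no P1 site exists"
        )
    return pos, record.residues[pos]


def classify_inhibitor(
    domain: KunitzDomain,
    record: SequenceRecord,
    small: frozenset = SMALL_RESIDUES,
) -> str:
    """Serine-protease inhibitor class from the P1/P1' dipeptide."""
    pos, p1 = locate_p1(domain, record)
    if pos + 1 >= len(record.residues):
        raise ValueError(f"{record.id}: no residue after the P1 site (P1' missing)")
    p1_prime = record.residues[pos + 1]
    if p1 in BASIC and p1_prime in small:
        return "trypsin"
    if p1 in LARGE_P1 and p1_prime in small:
        return "chymotrypsin"
    return "none"


def detect_channel_elements(
    domain: KunitzDomain,
    record: SequenceRecord,
    window: int = DEFAULT_CHANNEL_WINDOW,
) -> tuple[bool, tuple[int, int] | None]:
    """Look for an R/K within *window* residues of an L/Y/F in the base region.

    The base region spans from 3 residues before C4 through C6.  Returns the
    closest qualifying (basic, hydrophobic) position pair, ties broken toward
    the N-terminus.
    """
    if window < 1:
        raise ValueError("window must be positive")
    start = max(0, domain.cys_positions[3] - BASE_OFFSET_BEFORE_C4)
    end = domain.cys_positions[5]  # inclusive
    region = record.residues[start : end + 1]
    basics = [start + i for i, aa in enumerate(region) if aa in BASIC]
    hydros = [start + i for i, aa in enumerate(region) if aa in HYDROPHOBIC_PARTNER]
    best: tuple[int, int, int] | None = None
    for b in basics:
        for h in hydros:
            dist = abs(b - h)
            if dist <= window:
                key = (dist, b, h)
                if best is None or key < best:
                    best = key
    if best is None:
        return False, None
    return True, (best[1], best[2])


def annotate_domain(
    domain: KunitzDomain,
    record: SequenceRecord,
    small: frozenset = SMALL_RESIDUES,
    window: int = DEFAULT_CHANNEL_WINDOW,
) -> FunctionalAnnotation:
    pos, p1 = locate_p1(domain, record)
    modulator, evidence = detect_channel_elements(domain, record, window=window)
    return FunctionalAnnotation(
        parent_id=record.id,
        p1_position=pos,
        p1_residue=p1,
        inhibitor_class=classify_inhibitor(domain, record, small=small),
        channel_modulator=modulator,
        channel_evidence=evidence,
    )
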