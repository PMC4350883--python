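"""Mapping introns into protein coordinates and typing them against domain anchors.

Two conserved intron positions discriminate the deep WRKY lineages: the PR
intron interrupts the linker between the signature block and the zinc finger
(hallmark of the Group I-derived lineage: I, IIc, IId, IIe, III), while the
VQR/QVQR intron falls inside the finger region itself (hallmark of Groups IIa
and IIb).  An intron near neither anchor but inside a domain (plus a small
flank) is OTHER; an intron wholly outside any domain is NONE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import PreconditionError
from .io_formats import GeneModel
from .domain_scanner import WrkyDomainHit

#: Half-width, in codons, of the window around an anchor residue within which
#: an intron still counts as that anchor's type.
ANCHOR_HALF_WIDTH = 2

#: Residue flank around a domain span inside which an intron is OTHER
#: rather than NONE.
DOMAIN_FLANK = 10


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    genomic_span: tuple[int, int]  # 1-based inclusive intron coordinates
    protein_position: int  # 1-based residue after which the intron falls
    phase: int  # 0, 1 or 2: bases of the interrupted codon already emitted
    domain_relative: Optional[int] = None


@dataclass(frozen=True)
class IntronTypeCall:
    intron: IntronRecord
    type: str  # PR | VQR | OTHER | NONE
    anchor: Optional[tuple[str, int]] = None  # (motif, 1-based anchor residue)


def protein_coordinates_of_introns(model: GeneModel) -> list[IntronRecord]:
    """Locate each intron of a gene model in protein coordinates.

    Walking the CDS segments in transcription order, an intron after
    ``c`` coding bases falls after protein residue ``c // 3`` with phase
    ``c % 3``.  Single-segment models have no introns.
    """
    segments = model.segments_in_transcription_order()
    if len(segments) < 2:
        return []
    records = []
    cumulative = 0
    for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
        cumulative += e1 - s1
        if model.strand == "+":
            gspan = (e1 + 1, s2)  # 1-based inclusive gap between the exons
        else:
            gspan = (e2 + 1, s1)
        records.append(
            IntronRecord(
                gene_id=model.gene_id,
                genomic_span=gspan,
                protein_position=cumulative // 3,
                phase=cumulative % 3,
            )
        )
    return records


def _pr_anchor(domain: WrkyDomainHit, residues: str) -> Optional[int]:
    """1-based residue position of the R of the P-R dipeptide nearest the
    first chelator, searched between signature end and the first chelator."""
    lo = domain.signature.offset + 7
    hi = domain.finger.chelator_positions[0]
    best = None
    for i in range(lo, hi - 1):
        if residues[i] == "P" and residues[i + 1] == "R":
            best = i + 1  # 0-based position of the R
    return None if best is None else best + 1


def _vqr_anchors(domain: WrkyDomainHit, residues: str) -> list[int]:
    """1-based positions of the final R of each V-Q-R match inside the finger
    region (first to last chelator).  A Q-V-Q-R match ends in V-Q-R, so the
    tripattern covers both spellings."""
    lo = domain.finger.chelator_positions[0]
    hi = domain.finger.chelator_positions[-1]
    out = []
    for i in range(lo, hi - 1):
        if residues[i : i + 3] == "VQR":
            out.append(i + 2 + 1)
    return out


def type_intron(
    intron: IntronRecord, domain: WrkyDomainHit, residues: str
) -> IntronTypeCall:
    """Classify one intron relative to one WRKY domain.

    ``residues`` is the full protein sequence the domain was called on.  The
    intron position is compared, within +/-2 codons, against the PR anchor
    (linker region) and the VQR anchors (finger region); the two search
    regions are disjoint, so PR and VQR are mutually exclusive.
    """
    if domain.span[1] > len(residues):
        raise PreconditionError(
            f"domain span {domain.span} exceeds protein length {len(residues)}"
        )
    if intron.protein_position > len(residues):
        raise PreconditionError("intron position beyond protein end")
    pos = intron.protein_position  # 1-based residue after which the intron falls

    pr = _pr_anchor(domain, residues)
    if pr is not None and abs(pos - pr) <= ANCHOR_HALF_WIDTH:
        return IntronTypeCall(intron, "PR", ("PR", pr))
    for vqr in _vqr_anchors(domain, residues):
        if abs(pos - vqr) <= ANCHOR_HALF_WIDTH:
            return IntronTypeCall(intron, "VQR", ("VQR", vqr))
    lo = domain.span[0] + 1 - DOMAIN_FLANK  # 1-based residue bounds
    hi = domain.span[1] + DOMAIN_FLANK
    if lo <= pos <= hi:
        return IntronTypeCall(intron, "OTHER", None)
    return IntronTypeCall(intron, "NONE", None)


def type_introns_for_protein(
    introns: Sequence[IntronRecord],
    domains: Sequence[WrkyDomainHit],
    residues: str,
) -> list[IntronTypeCall]:
    """Type each intron against the nearest domain of its protein.

    With no domains at all, every intron is NONE.
    """
    calls = []
    for intron in introns:
        if not domains:
            calls.append(IntronTypeCall(intron, "NONE", None))
            continue
        nearest = min(
            domains,
            key=lambda d: min(
                abs(intron.protein_position - (d.span[0] + 1)),
                abs(intron.protein_position - d.span[1]),
            )
            if not (d.span[0] + 1 <= intron.protein_position <= d.span[1])
            else 0,
        )
        calls.append(type_intron(intron, nearest, residues))
    return calls
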