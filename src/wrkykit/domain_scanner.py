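"""Detection of WRKY domains in protein sequences.

A WRKY domain is called where a signature heptapeptide (WRKYGQK or one of its
divergent variants) is followed, within a bounded search window, by at least
part of a zinc-finger motif.  Signatures with no downstream finger are kept as
rejected candidates for auditing but are not domains — incomplete hits may be
pseudogenes, assembly artefacts or mispredictions.

Zinc-finger classes are spacing envelopes over the chelating residues:

==========  =============================  ======================================
class       envelope                       typical carriers
==========  =============================  ======================================
C2H2_X4     C-x(4)-C-x(20,28)-H-x(1)-H     Groups I, IIc, IId, IIe
C2H2_X5     C-x(5)-C-x(20,28)-H-x(1)-H     Groups IIa, IIb
C2HC        C-x(4,7)-C-x(20,28)-H-x(1,3)-C Group III
FUNGAL      C-x(6)-C-x(5,30)-H-x(3)-C      fungal-type single-domain proteins
==========  =============================  ======================================

The envelopes are configurable; the literature prints exemplar spacings, not
ranges, so the defaults are deliberately permissive around them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import PreconditionError
from .io_formats import SequenceRecord

#: Signature heptapeptide library, canonical variant first.  All variants
#: begin with W; fuzzy matching is anchored on that tryptophan.
DEFAULT_VARIANTS = ("WRKYGQK", "WKNNGNT", "WKKYGNK", "WKKYGHK")

#: Class precedence used to break ties between equally placed finger hits.
FINGER_CLASSES = ("C2H2_X4", "C2H2_X5", "C2HC", "FUNGAL")

#: Spacing envelopes: list of (chelator_residue, min_gap, max_gap) steps.
#: Each step means "chelator, then between min and max arbitrary residues".
DEFAULT_ENVELOPES: dict[str, tuple[tuple[str, int, int], ...]] = {
    "C2H2_X4": (("C", 4, 4), ("C", 20, 28), ("H", 1, 1), ("H", 0, 0)),
    "C2H2_X5": (("C", 5, 5), ("C", 20, 28), ("H", 1, 1), ("H", 0, 0)),
    "C2HC": (("C", 4, 7), ("C", 20, 28), ("H", 1, 3), ("C", 0, 0)),
    "FUNGAL": (("C", 6, 6), ("C", 5, 30), ("H", 3, 3), ("C", 0, 0)),
}


@dataclass(frozen=True)
class SignatureHit:
    protein_id: str
    offset: int  # 0-based index of the heptapeptide start
    heptapeptide: str
    matched_variant: str
    mismatches: int


@dataclass(frozen=True)
class ZincFingerHit:
    pattern_class: str
    chelator_positions: tuple[int, ...]  # 0-based, strictly increasing
    completeness: str  # "full" | "partial"

    @property
    def start(self) -> int:
        return self.chelator_positions[0]

    @property
    def end(self) -> int:
        """One past the last chelator."""
        return self.chelator_positions[-1] + 1


@dataclass(frozen=True)
class WrkyDomainHit:
    protein_id: str
    signature: SignatureHit
    finger: ZincFingerHit
    span: tuple[int, int]  # 0-based half-open: signature start .. last chelator+1
    index_in_protein: int
    residues: str = ""  # the spanned subsequence, kept for classification


@dataclass
class ScanConfig:
    """Tunables of the domain caller."""

    max_mismatches: int = 1
    finger_window: int = 60  # residues after signature end where a finger may start
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    envelopes: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_ENVELOPES))


def _check_unaligned(record: SequenceRecord):
    if "-" in record.residues:
        raise PreconditionError(
            f"{record.id}: gapped sequence passed to a scanner operation"
        )


def scan_signatures(
    record: SequenceRecord,
    max_mismatches: int = 0,
    variants: Sequence[str] = DEFAULT_VARIANTS,
) -> list[SignatureHit]:
    """Find all heptapeptide windows within ``max_mismatches`` of the library.

    Matching is anchored: a window is only considered if it starts with W.
    Each window reports its closest variant (ties resolved in library order);
    overlapping windows are deduplicated to the best-scoring (then leftmost)
    hit.
    """
    _check_unaligned(record)
    if not 0 <= max_mismatches <= 3:
        raise PreconditionError("max_mismatches must be in [0, 3]")
    seq = record.residues
    candidates: list[SignatureHit] = []
    for off in range(len(seq) - 6):
        if seq[off] != "W":
            continue
        window = seq[off : off + 7]
        best_variant, best_mm = None, max_mismatches + 1
        for variant in variants:
            mm = sum(a != b for a, b in zip(window, variant))
            if mm < best_mm:
                best_variant, best_mm = variant, mm
        if best_variant is not None and best_mm <= max_mismatches:
            candidates.append(
                SignatureHit(record.id, off, window, best_variant, best_mm)
            )
    # Greedy dedup of overlapping windows: fewest mismatches wins, then leftmost.
    chosen: list[SignatureHit] = []
    for hit in sorted(candidates, key=lambda h: (h.mismatches, h.offset)):
        if all(abs(hit.offset - kept.offset) >= 7 for kept in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.offset)
    return chosen


def _envelope_matches(seq: str, start: int, steps, limit: int) -> Optional[tuple[int, ...]]:
    """Match a chelator envelope starting at ``start``, backtracking over the
    allowed gap ranges (shortest-gap solution returned).

    ``steps[i]`` is ``(chelator, min_gap, max_gap)``: the chelator residue,
    then between min and max arbitrary residues before the next chelator.
    Returns the chelator positions, or None.  ``limit`` bounds all positions.
    """
    if start >= limit or seq[start] != steps[0][0]:
        return None

    def extend(pos: int, step_idx: int) -> Optional[list[int]]:
        if step_idx == len(steps) - 1:
            return [pos]
        _, lo, hi = steps[step_idx]
        nxt_res = steps[step_idx + 1][0]
        for gap in range(lo, hi + 1):
            cand = pos + 1 + gap
            if cand >= limit:
                break
            if seq[cand] == nxt_res:
                rest = extend(cand, step_idx + 1)
                if rest is not None:
                    return [pos] + rest
        return None

    result = extend(start, 0)
    return tuple(result) if result is not None else None


def detect_zinc_finger(
    record: SequenceRecord,
    search_from: int = 0,
    window: int = 60,
    envelopes: Optional[dict] = None,
) -> list[ZincFingerHit]:
    """Report zinc-finger motifs whose first chelator lies in
    ``[search_from, search_from + window)``.

    Full hits (all four chelators at class-consistent spacing) are preferred
    over partial hits (>= 2 chelators) at the same start; hits are ordered by
    start, then class precedence.
    """
    _check_unaligned(record)
    if not 0 <= search_from <= len(record.residues):
        raise PreconditionError(f"search_from {search_from} outside protein")
    if window < 30:
        raise PreconditionError("window must be >= 30")
    if envelopes is None:
        envelopes = DEFAULT_ENVELOPES
    seq = record.residues
    limit = len(seq)
    start_limit = min(limit, search_from + window)
    hits: list[ZincFingerHit] = []
    for cls in FINGER_CLASSES:
        if cls not in envelopes:
            continue
        steps = envelopes[cls]
        for start in range(search_from, start_limit):
            full = _envelope_matches(seq, start, steps, limit)
            if full is not None:
                hits.append(ZincFingerHit(cls, full, "full"))
                continue
            # partial: longest proper prefix of the envelope with >= 2 chelators
            for k in range(len(steps) - 1, 1, -1):
                part = _envelope_matches(seq, start, steps[:k], limit)
                if part is not None:
                    hits.append(ZincFingerHit(cls, part, "partial"))
                    break
    order = {c: i for i, c in enumerate(FINGER_CLASSES)}
    hits.sort(key=lambda h: (h.start, h.completeness != "full", order[h.pattern_class]))
    return hits


def call_wrky_domains(
    record: SequenceRecord, config: Optional[ScanConfig] = None
) -> tuple[list[WrkyDomainHit], list[SignatureHit]]:
    """Apply the curation rule: signature + at least part of a downstream finger.

    Returns ``(domains, rejected)`` where ``rejected`` holds signature hits
    with no finger in their search window.  Domains are ordered N->C, indexed,
    and never overlap: once a domain is called, later signatures falling
    inside it are ignored.
    """
    if config is None:
        config = ScanConfig()
    signatures = scan_signatures(record, config.max_mismatches, config.variants)
    domains: list[WrkyDomainHit] = []
    rejected: list[SignatureHit] = []
    occupied_until = -1
    for sig in signatures:
        if sig.offset <= occupied_until:
            continue
        sig_end = sig.offset + 7
        fingers = detect_zinc_finger(
            record, search_from=sig_end, window=config.finger_window,
            envelopes=config.envelopes,
        )
        if not fingers:
            rejected.append(sig)
            continue
        finger = fingers[0]  # leftmost, full-preferred at same start
        span = (sig.offset, finger.end)
        domains.append(
            WrkyDomainHit(
                protein_id=record.id,
                signature=sig,
                finger=finger,
                span=span,
                index_in_protein=len(domains),
                residues=record.residues[span[0] : span[1]],
            )
        )
        occupied_until = finger.end - 1
    return domains, rejected
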