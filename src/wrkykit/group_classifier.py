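"""Assignment of curated WRKY domains to evolutionary groups.

Flowering-plant WRKY proteins fall into seven groups: Group I proteins carry
two domains (N- and C-terminal), Group II proteins one domain with a
C2H2-type finger (subgroups IIa-IIe), and Group III proteins one domain with
a C2HC finger.  Sequence-level diagnostics separate only part of this space:

* two C2H2-class domains  -> I (first domain I_NT, second I_CT);
* a C2HC finger           -> III (moss-variant signatures flagged);
* a fungal-type finger    -> FUNGAL_TYPE;
* a C-x5-C finger with QVQR inside the finger and/or DGC just before the
  signature -> the IIa+IIb lineage (reported IIb, refinable to IIa);
* a C-x4-C finger         -> the I/IIc lineage (reported IIc, refinable).

IIa vs IIb, and IIc vs IId vs IIe, are separated only phylogenetically, so
the rule cascade emits a coarse lineage label and :func:`refine_by_reference`
resolves it by nearest packaged reference under the Poisson-corrected
distance — a nearest-neighbour stand-in for full tree placement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from math import log
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FormatError, PreconditionError
from .io_formats import SequenceRecord
from .domain_scanner import WrkyDomainHit

GROUPS = (
    "I_NT", "I_CT", "IIa", "IIb", "IIc", "IId", "IIe", "III",
    "III_MOSS_VARIANT", "FUNGAL_TYPE", "ALGAL_SINGLE", "DIPLOMONAD_TYPE",
    "UNCLASSIFIED",
)

#: Signature variants treated as the moss/fungal divergent set.
MOSS_FUNGAL_SIGNATURES = frozenset({"WKKYGNK", "WKNNGNT"})
DIPLOMONAD_SIGNATURE = "WKKYGHK"

#: Which reference labels a coarse rule label may be refined into.
REFINABLE = {
    "IIb": ("IIa", "IIb"),
    "IIc": ("IIc", "IId", "IIe", "ALGAL_SINGLE"),
    "UNCLASSIFIED": GROUPS[:-1],
}

#: Window (residues) before the signature inside which DGC counts as the
#: "immediately N-terminal" IIb diagnostic.
DGC_WINDOW = 5

TIE_TOLERANCE = 1e-9


@dataclass
class GroupCall:
    domain: WrkyDomainHit
    group: str
    evidence: list[str] = field(default_factory=list)
    nearest_reference: Optional[tuple[str, float]] = None
    tie_candidates: Optional[tuple[str, str]] = None


@dataclass(frozen=True)
class ReferenceEntry:
    ref_id: str
    group: str
    residues: str  # ungapped


@dataclass
class ReferenceSet:
    entries: list[ReferenceEntry]

    def __post_init__(self):
        if not self.entries:
            raise PreconditionError("empty reference set")

    def subset(self, groups: Sequence[str]) -> list[ReferenceEntry]:
        wanted = set(groups)
        return [e for e in self.entries if e.group in wanted]


def load_reference_set() -> ReferenceSet:
    """Load the packaged reference domains.

    The packaged set is synthetic: one designed exemplar per group satisfying
    the documented diagnostics (see the synthetic-data module), shipped as an
    aligned FASTA plus a label sidecar.
    """
    data = resources.files("wrkykit.data")
    labels = {}
    for line in data.joinpath("reference_labels.synthetic.tsv").read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("ref_id\t"):
            continue
        ref_id, group = line.split("\t")
        labels[ref_id] = group
    entries = []
    current_id, chunks = None, []
    for line in data.joinpath("reference_domains.synthetic.afa").read_text().splitlines():
        if line.startswith(">"):
            if current_id is not None:
                entries.append(ReferenceEntry(current_id, labels[current_id],
                                              "".join(chunks).replace("-", "")))
            current_id, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if current_id is not None:
        entries.append(ReferenceEntry(current_id, labels[current_id],
                                      "".join(chunks).replace("-", "")))
    return ReferenceSet(entries)


# ---------------------------------------------------------------------------
# Rule cascade


def _single_domain_rules(protein_residues: str, d: WrkyDomainHit) -> tuple[str, list[str]]:
    cls = d.finger.pattern_class
    if cls == "FUNGAL":
        return "FUNGAL_TYPE", ["R3"]
    if cls == "C2HC":
        if d.signature.matched_variant in MOSS_FUNGAL_SIGNATURES:
            return "III_MOSS_VARIANT", ["R2", "R2_moss_signature"]
        return "III", ["R2"]
    if cls == "C2H2_X5":
        evidence = []
        finger_region = protein_residues[d.finger.start : d.finger.end]
        if "QVQR" in finger_region:
            evidence.append("R4a")
        pre = protein_residues[max(0, d.signature.offset - DGC_WINDOW) : d.signature.offset]
        if "DGC" in pre:
            evidence.append("R4b")
        if evidence:
            return "IIb", evidence
        return "UNCLASSIFIED", ["no_rule:C2H2_X5_without_IIb_diagnostics"]
    if cls == "C2H2_X4":
        return "IIc", ["R5"]
    return "UNCLASSIFIED", [f"no_rule:finger_class_{cls}"]


def classify_domain_rules(
    domains_of_protein: Sequence[WrkyDomainHit],
    protein_residues: Optional[str] = None,
) -> list[GroupCall]:
    """Run the diagnostic rule cascade on all domains of one protein.

    ``protein_residues`` supplies context for the DGC look-behind; when
    omitted, each domain's own spanned residues are used (the DGC motif then
    cannot be seen, since it lies just before the span).
    """
    if not domains_of_protein:
        raise PreconditionError("no domains supplied")
    ids = {d.protein_id for d in domains_of_protein}
    if len(ids) > 1:
        raise PreconditionError(f"domains from multiple proteins: {sorted(ids)}")
    domains = sorted(domains_of_protein, key=lambda d: d.span[0])

    def ctx(d: WrkyDomainHit) -> str:
        if protein_residues is not None:
            return protein_residues
        return d.residues

    def region(d: WrkyDomainHit, start: int, end: int) -> str:
        seq = ctx(d)
        if protein_residues is not None:
            return seq[start:end]
        return seq[start - d.span[0] : end - d.span[0]]

    if len(domains) == 2:
        c1, c2 = (d.finger.pattern_class for d in domains)
        if c1 in ("C2H2_X4", "C2H2_X5") and c2 in ("C2H2_X4", "C2H2_X5"):
            if domains[1].signature.matched_variant == DIPLOMONAD_SIGNATURE:
                ev = ["R1", "diplomonad_ct_signature"]
                return [GroupCall(d, "UNCLASSIFIED", list(ev)) for d in domains]
            return [
                GroupCall(domains[0], "I_NT", ["R1"]),
                GroupCall(domains[1], "I_CT", ["R1"]),
            ]
        return [
            GroupCall(d, "UNCLASSIFIED", ["conflict:two_domains_non_C2H2"])
            for d in domains
        ]
    if len(domains) == 1:
        d = domains[0]
        seq = ctx(d)
        if protein_residues is not None:
            group, ev = _single_domain_rules(seq, d)
        else:
            # re-base coordinates onto the span-local sequence
            shifted = _shift_domain(d)
            group, ev = _single_domain_rules(seq, shifted)
        return [GroupCall(d, group, ev)]
    return [
        GroupCall(d, "UNCLASSIFIED", [f"conflict:{len(domains)}_domains"])
        for d in domains
    ]


def _shift_domain(d: WrkyDomainHit) -> WrkyDomainHit:
    from dataclasses import replace
    off = d.span[0]
    sig = replace(d.signature, offset=d.signature.offset - off)
    finger = replace(
        d.finger,
        chelator_positions=tuple(p - off for p in d.finger.chelator_positions),
    )
    return replace(d, signature=sig, finger=finger, span=(0, d.span[1] - off))


# ---------------------------------------------------------------------------
# Pairwise alignment (affine-gap Needleman-Wunsch over the shipped BLOSUM62)


def load_substitution_table() -> dict[tuple[str, str], float]:
    text = resources.files("wrkykit.data").joinpath("blosum62.tsv").read_text()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    letters = lines[0].strip().split("\t")
    table = {}
    for line in lines[1:]:
        cols = line.split("\t")
        row = cols[0]
        for letter, val in zip(letters, cols[1:]):
            table[(row, letter)] = float(val)
    return table


_DEFAULT_TABLE: Optional[dict] = None


def _default_table() -> dict:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_substitution_table()
    return _DEFAULT_TABLE


def _aligner_for(table: dict, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    letters = sorted({a for a, _ in table})
    mat = substitution_matrices.Array(alphabet="".join(letters), dims=2)
    for (a, b), v in table.items():
        mat[a, b] = v
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    a: str,
    b: str,
    substitution_table: Optional[dict] = None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped protein sequences.

    Affine gap scoring: a gap of length L costs ``gap_open + (L-1)*gap_extend``.
    Returns the two gapped rows and the optimal score.
    """
    if not a or not b:
        raise PreconditionError("align_global requires non-empty sequences")
    if "-" in a or "-" in b:
        raise PreconditionError("align_global requires ungapped input")
    table = substitution_table if substitution_table is not None else _default_table()
    known = {x for x, _ in table}
    unknown = (set(a) | set(b)) - known
    if unknown:
        raise PreconditionError(f"residues not in substitution table: {sorted(unknown)}")
    aligner = _aligner_for(table, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    best = alignments[0]
    return str(best[0]), str(best[1]), best.score


# ---------------------------------------------------------------------------
# Reference refinement


def _corrected_distance(a: str, b: str, table: Optional[dict] = None) -> float:
    """Poisson-corrected distance between two sequences after global alignment,
    computed over aligned non-gap columns."""
    row_a, row_b, _ = align_global(a, b, table)
    comparable = 0
    diffs = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-" or x == "X" or y == "X":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        return float("inf")
    p = diffs / comparable
    if p >= 1.0:
        return float("inf")
    return -log(1.0 - p) + 0.0  # avoid -0.0 at p == 0


def refine_by_reference(call: GroupCall, refs: ReferenceSet) -> GroupCall:
    """Replace a coarse lineage label with the group of the nearest reference.

    The domain is globally aligned to every eligible reference and the
    Poisson-corrected distance taken over aligned non-gap columns; the nearest
    reference's group wins.  When the two best references from different
    groups are within the tie tolerance, the coarse label is kept and both
    candidates recorded.
    """
    if call.group not in REFINABLE:
        raise PreconditionError(
            f"group {call.group!r} is not refinable (expected one of {sorted(REFINABLE)})"
        )
    candidates = refs.subset(REFINABLE[call.group])
    if not candidates:
        raise PreconditionError("no references for the refinable lineage")
    scored = sorted(
        ((_corrected_distance(call.domain.residues, e.residues), e) for e in candidates),
        key=lambda t: (t[0], t[1].ref_id),
    )
    best_d, best = scored[0]
    rival = next(((d, e) for d, e in scored[1:] if e.group != best.group), None)
    out = GroupCall(
        domain=call.domain,
        group=best.group,
        evidence=call.evidence + [f"nearest:{best.ref_id}"],
        nearest_reference=(best.ref_id, best_d),
    )
    if rival is not None and abs(rival[0] - best_d) <= TIE_TOLERANCE:
        out.group = call.group
        out.tie_candidates = (best.group, rival[1].group)
        out.evidence.append(f"tie:{best.group}|{rival[1].group}")
    return out


# ---------------------------------------------------------------------------
# Consensus


def consensus_sequence(alignment: Sequence[SequenceRecord], threshold: float = 0.5) -> str:
    """Column-wise consensus of an alignment.

    A column emits its most frequent residue when that residue's frequency
    (gaps excluded from the numerator, included in the denominator) reaches
    the threshold; ties between top residues emit 'x'; all-gap columns '-'.
    """
    if len(alignment) < 2:
        raise PreconditionError("consensus requires >= 2 rows")
    if not 0.5 <= threshold <= 1.0:
        raise PreconditionError("threshold must be in [0.5, 1]")
    lengths = {len(r) for r in alignment}
    if len(lengths) > 1:
        raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
    n = len(alignment)
    out = []
    for col in zip(*(r.residues for r in alignment)):
        counts = Counter(c for c in col if c != "-")
        if not counts:
            out.append("-")
            continue
        top = counts.most_common()
        best_res, best_n = top[0]
        if len(top) > 1 and top[1][1] == best_n:
            out.append("x")
        elif best_n / n >= threshold:
            out.append(best_res)
        else:
            out.append("x")
    return "".join(out)
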