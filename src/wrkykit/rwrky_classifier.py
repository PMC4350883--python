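"""Classification of chimeric R-protein/WRKY genes (families RW1-RW8).

Flowering plants repeatedly fused resistance-protein (NLR) domains — TIR,
NB-ARC, LRR — with one or more WRKY domains into single chimeric genes.
Eight architecture families are recognised, each a fixed ordered domain
pattern (e.g. RW1 = TIR / NB-ARC / LRR / WRKY(IIe)); the grammar ships as an
editable TSV so new families can be registered without code changes.

A protein qualifies as a candidate at all only when its architecture carries
at least one WRKY token and at least one of TIR / NB-ARC / LRR; candidates
matching no family are RW_NOVEL.  RW2 and RW4 share the single-WRKY(III)
TIR architecture and are separated in the source literature only by lineage,
so that case reports both candidates unless a lineage hint resolves it.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

from .errors import PreconditionError
from .io_formats import DomainAnnotationRow
from .group_classifier import GroupCall

R_DOMAINS = frozenset({"TIR", "NB-ARC", "LRR"})

#: Lineage hints resolving the RW2/RW4 architecture ambiguity.
LINEAGE_HINTS = {"strawberry": "RW2", "soybean": "RW4"}

#: Adjacent LRR rows separated by at most this many residues merge into one token.
LRR_MERGE_GAP = 30

#: Mutual-overlap fraction above which two rows compete (higher score wins).
OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class ArchToken:
    label: str  # controlled vocabulary label, e.g. "NB-ARC" or "WRKY"
    wrky_group: Optional[str] = None  # for WRKY tokens

    def __str__(self):
        if self.label == "WRKY":
            return f"WRKY({self.wrky_group})"
        return self.label


@dataclass
class ArchitectureString:
    protein_id: str
    tokens: list[ArchToken]
    provenance: list[list[DomainAnnotationRow]] = field(default_factory=list)

    def __str__(self):
        return "-".join(str(t) for t in self.tokens)


@dataclass(frozen=True)
class RWCall:
    protein_id: str
    family: str  # RW1..RW8, "RW2|RW4", RW_NOVEL, NOT_RW
    matched_rule: Optional[str] = None
    candidates: Optional[frozenset] = None
    lineage_hint_used: bool = False


# ---------------------------------------------------------------------------
# Architecture construction


def _mutual_overlap(a: DomainAnnotationRow, b: DomainAnnotationRow) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start, b.end - b.start)


def build_architecture(
    rows: Sequence[DomainAnnotationRow],
    wrky_calls: Sequence[Union[GroupCall, str]] = (),
) -> ArchitectureString:
    """Order domain rows into an architecture string.

    Rows are sorted by start; of two rows overlapping by more than half of the
    shorter one, only the higher-scoring survives; runs of LRR rows separated
    by small gaps collapse into one LRR token.  WRKY tokens are annotated with
    their group calls, paired off N-to-C (plain strings are accepted in place
    of :class:`GroupCall` objects); WRKY rows beyond the supplied calls are
    UNCLASSIFIED.
    """
    if not rows:
        raise PreconditionError("no domain rows supplied")
    ids = {r.protein_id for r in rows}
    if len(ids) > 1:
        raise PreconditionError(f"rows from multiple proteins: {sorted(ids)}")
    ordered = sorted(rows, key=lambda r: (r.start, r.end, -r.score))
    kept: list[DomainAnnotationRow] = []
    for row in ordered:
        rival = next((k for k in kept if _mutual_overlap(k, row) > OVERLAP_FRACTION), None)
        if rival is None:
            kept.append(row)
        elif row.score > rival.score:
            kept[kept.index(rival)] = row
    kept.sort(key=lambda r: r.start)

    groups = [c if isinstance(c, str) else c.group for c in wrky_calls]
    g_iter = iter(groups)
    tokens: list[ArchToken] = []
    provenance: list[list[DomainAnnotationRow]] = []
    for row in kept:
        if (
            row.domain_label == "LRR"
            and tokens
            and tokens[-1].label == "LRR"
            and row.start - provenance[-1][-1].end <= LRR_MERGE_GAP
        ):
            provenance[-1].append(row)
            continue
        if row.domain_label == "WRKY":
            tokens.append(ArchToken("WRKY", next(g_iter, "UNCLASSIFIED")))
        else:
            tokens.append(ArchToken(row.domain_label))
        provenance.append([row])
    return ArchitectureString(next(iter(ids)), tokens, provenance)


# ---------------------------------------------------------------------------
# Grammar


@dataclass(frozen=True)
class PatternToken:
    label: str
    wrky_group: Optional[str]
    optional: bool


@dataclass(frozen=True)
class GrammarRule:
    family: str
    pattern: tuple[PatternToken, ...]

    def expansions(self):
        """All optional-token on/off combinations, as token tuples."""
        opts = [t for t in self.pattern if t.optional]
        for bits in itertools.product((True, False), repeat=len(opts)):
            onoff = dict(zip(opts, bits))
            yield tuple(t for t in self.pattern if not t.optional or onoff[t])


_TOKEN_RE = re.compile(r"^(\[)?([A-Za-z0-9_\-]+)(?:\(([A-Za-z_*]+)\))?(\])?$")


def _parse_pattern(text: str) -> tuple[PatternToken, ...]:
    tokens = []
    for word in text.split():
        m = _TOKEN_RE.match(word)
        if not m:
            raise ValueError(f"bad grammar token {word!r}")
        optional = bool(m.group(1))
        tokens.append(PatternToken(m.group(2), m.group(3), optional))
    return tuple(tokens)


def load_grammar(path=None) -> list[GrammarRule]:
    if path is None:
        text = resources.files("wrkykit.data").joinpath("rw_grammar.tsv").read_text()
    else:
        text = open(path).read()
    rules = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("family\t"):
            continue
        family, pattern = line.split("\t")
        rules.append(GrammarRule(family, _parse_pattern(pattern)))
    return rules


def _token_matches(arch_token: ArchToken, pat: PatternToken, rule_family: str) -> bool:
    if arch_token.label != pat.label:
        return False
    if pat.label != "WRKY":
        return True
    if pat.wrky_group in (None, "*"):
        return True
    if arch_token.wrky_group == pat.wrky_group:
        return True
    # Truncated, unclassifiable WRKY domains wildcard-match in RW7 only.
    return rule_family == "RW7" and arch_token.wrky_group == "UNCLASSIFIED"


def _matches_rule(tokens: Sequence[ArchToken], rule: GrammarRule) -> bool:
    # Leading/trailing OTHER:* tokens are ignored; internal unmatched tokens fail.
    core = list(tokens)
    while core and core[0].label.startswith("OTHER:"):
        core.pop(0)
    while core and core[-1].label.startswith("OTHER:"):
        core.pop()
    for expansion in rule.expansions():
        if len(expansion) == len(core) and all(
            _token_matches(a, p, rule.family) for a, p in zip(core, expansion)
        ):
            return True
    return False


def classify_rw(
    arch: ArchitectureString,
    lineage_hint: Optional[str] = None,
    grammar: Optional[list[GrammarRule]] = None,
) -> RWCall:
    """Match an architecture against the family grammar.

    Rules are tried in RW1..RW8 order and all matches collected.  A unique
    match wins outright; the RW2/RW4 pair is resolved by ``lineage_hint``
    when one is supplied, and reported as the pair otherwise.  Architectures
    that are chimeric candidates (WRKY + R domain) but match nothing are
    RW_NOVEL; everything else is NOT_RW.
    """
    if grammar is None:
        grammar = load_grammar()
    labels = {t.label for t in arch.tokens}
    is_candidate = "WRKY" in labels and labels & R_DOMAINS
    if not is_candidate:
        return RWCall(arch.protein_id, "NOT_RW")
    matches = [r.family for r in grammar if _matches_rule(arch.tokens, r)]
    if not matches:
        return RWCall(arch.protein_id, "RW_NOVEL")
    if len(matches) == 1:
        return RWCall(arch.protein_id, matches[0], matched_rule=matches[0])
    if set(matches) == {"RW2", "RW4"}:
        if lineage_hint is not None and lineage_hint.lower() in LINEAGE_HINTS:
            return RWCall(
                arch.protein_id,
                LINEAGE_HINTS[lineage_hint.lower()],
                matched_rule="RW2|RW4",
                candidates=frozenset(matches),
                lineage_hint_used=True,
            )
        return RWCall(
            arch.protein_id, "RW2|RW4", matched_rule="RW2|RW4",
            candidates=frozenset(matches),
        )
    # Multiple unrelated rules matching indicates grammar overlap; first wins,
    # with all candidates recorded.
    return RWCall(
        arch.protein_id, matches[0], matched_rule=matches[0],
        candidates=frozenset(matches),
    )
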