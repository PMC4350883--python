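"""Seeded generators for synthetic proteomes, gene models and domain tables.

Everything the pipeline consumes can be fabricated here with a known ground
truth: proteins carrying 0-2 WRKY domains built from per-group templates
(signature variant, finger spacing, DGC/QVQR diagnostics), gene models with
introns planted at the PR or VQR anchor residues, and domain-annotation rows
realising each chimeric RW1-RW8 architecture plus decoys.

The templates are designed sequences, not transcriptions of any published
alignment: each satisfies the documented group diagnostics, all are 75
residues long with the signature at offset 8, and related groups share filler
ancestry so template distances mirror the published lineage structure.
Point mutations only ever touch non-diagnostic positions (the shipped mask),
and the mutation alphabet excludes W, C and H so that no mutation can create
a spurious signature anchor or chelator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .io_formats import GeneModel, DomainAnnotationRow, SequenceRecord, write_fasta, write_gff3
from .errors import PreconditionError

FILLER_ALPHABET = "ADEFGIKLMNPQRSTVY"  # 20 standard minus W, C, H

#: Fixed reverse-translation codon per amino acid (affects only DNA fixtures).
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC", "L": "CTT", "K": "AAG",
    "M": "ATG", "F": "TTC", "P": "CCA", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAC", "V": "GTT",
}
STOP = "TAA"


@dataclass(frozen=True)
class Template:
    template_id: str
    group: str
    signature_variant: str
    finger_class: str
    residues: str
    mask: str  # '1' = diagnostic position, never mutated
    sig_offset: int
    chelators: tuple[int, ...]
    pr_anchor: int  # 1-based residue of the PR anchor R, or -1
    vqr_anchor: int  # 1-based residue of the VQR anchor R, or -1

    @property
    def span(self) -> tuple[int, int]:
        """Domain span within the template: signature start .. last chelator+1."""
        return (self.sig_offset, self.chelators[-1] + 1)


def load_templates() -> dict[str, Template]:
    text = resources.files("wrkykit.data").joinpath(
        "group_templates.synthetic.tsv"
    ).read_text()
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("template_id\t"):
            continue
        (tid, group, sig, cls, tpl, mask, sig_off, chel, pr_a, vqr_a) = line.split("\t")
        out[tid] = Template(
            tid, group, sig, cls, tpl, mask, int(sig_off),
            tuple(int(x) for x in chel.split(",")), int(pr_a), int(vqr_a),
        )
    return out


#: Protein composition per group: which templates, N to C.
GROUP_COMPOSITION = {
    "I": ("I_NT", "I_CT"),
    "IIa": ("IIa",),
    "IIb": ("IIb",),
    "IIc": ("IIc",),
    "IId": ("IId",),
    "IIe": ("IIe",),
    "III": ("III",),
    "III_MOSS_VARIANT": ("III_MOSS",),
    "FUNGAL_TYPE": ("FUNGAL",),
    "ALGAL_SINGLE": ("ALGAL",),
    "DIPLOMONAD_TYPE": ("DIPLO_NT", "DIPLO_CT"),
}

DEFAULT_GROUP_COUNTS = {g: 5 for g in GROUP_COMPOSITION}

RW_FAMILIES = tuple(f"RW{i}" for i in range(1, 9))

#: One grammar witness per family; optional tokens listed with an ``opt:``
#: prefix are toggled by a seeded coin.  WRKY groups in parentheses.
RW_WITNESSES = {
    "RW1": ("TIR", "NB-ARC", "LRR", "WRKY(IIe)"),
    "RW2": ("TIR", "NB-ARC", "LRR", "WRKY(III)", "opt:WRKY(III)"),
    "RW3": ("PAH", "WRKY(I_NT)", "WRKY(I_CT)", "NB-ARC", "opt:MAPKKK"),
    "RW4": ("TIR", "NB-ARC", "LRR", "WRKY(III)"),
    "RW5": ("opt:B3", "LRR", "NB-ARC", "LRR", "WRKY(IIe)"),
    "RW6": ("NB-ARC", "LRR", "WRKY(III)", "opt:WRKY(III)"),
    "RW7": ("LRR", "WRKY(III)", "WRKY(IId)", "CAMB", "WRKY(IIc)"),
    "RW8": ("WRKY(III)", "NB-ARC", "LRR"),
}

#: Lineage hints that disambiguate the shared RW2/RW4 architecture.
RW_HINTS = {"RW2": "strawberry", "RW4": "soybean"}


@dataclass
class SynthSpec:
    """Study conditions for one synthetic data set."""

    group_counts: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    decoy_proteins: int = 5
    mutation_rate: float = 0.0
    linker_length_range: tuple[int, int] = (20, 60)
    intron_plan: dict = field(
        default_factory=lambda: {"PR": 50, "VQR": 50, "OTHER": 20, "NONE": 10}
    )
    rw_plan: dict = field(
        default_factory=lambda: dict(
            {f: 1 for f in RW_FAMILIES}, decoy_NLR=2, decoy_WRKY=2
        )
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 0.2:
            raise PreconditionError("mutation_rate must be in [0, 0.2]")
        if any(c < 0 for c in self.group_counts.values()):
            raise PreconditionError("negative group count")


@dataclass
class DomainTruth:
    template_id: str
    group: str
    span: tuple[int, int]  # 0-based half-open within the protein
    sig_offset: int  # 0-based signature start within the protein
    chelators: tuple[int, ...]
    pr_anchor: int  # 1-based protein residue, or -1
    vqr_anchor: int


@dataclass
class ProteinTruth:
    protein_id: str
    group: str  # planted group label, or "decoy"
    domains: list[DomainTruth] = field(default_factory=list)
    intron_type: Optional[str] = None
    intron_protein_position: Optional[int] = None
    intron_phase: Optional[int] = None
    rw_family: Optional[str] = None
    lineage_hint: Optional[str] = None
    wrky_groups: list[str] = field(default_factory=list)


@dataclass
class TruthTable:
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)

    def by_group(self, group: str) -> list[ProteinTruth]:
        return [p for p in self.proteins.values() if p.group == group]


def _random_linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(FILLER_ALPHABET), size=n))


def _mutate(rng: np.random.Generator, tpl: Template, rate: float) -> str:
    if rate == 0.0:
        return tpl.residues
    out = list(tpl.residues)
    for i, flag in enumerate(tpl.mask):
        if flag == "1":
            continue
        if rng.random() < rate:
            choices = [c for c in FILLER_ALPHABET if c != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def generate_proteome(spec: SynthSpec) -> tuple[list[SequenceRecord], TruthTable]:
    """Emit one protein per planted group member plus signature-free decoys.

    Deterministic for a fixed spec (the seed is part of the spec); every
    truth-table span indexes the emitted sequence to the planted domain.
    """
    rng = np.random.default_rng(spec.seed)
    templates = load_templates()
    lo, hi = spec.linker_length_range
    records: list[SequenceRecord] = []
    truth = TruthTable()
    for group in sorted(spec.group_counts):
        if group not in GROUP_COMPOSITION:
            raise PreconditionError(f"unknown group {group!r}")
        for k in range(spec.group_counts[group]):
            pid = f"SYN_{group}_{k}"
            parts = [_random_linker(rng, lo, hi)]
            domains = []
            for tid in GROUP_COMPOSITION[group]:
                tpl = templates[tid]
                offset = sum(len(p) for p in parts)
                parts.append(_mutate(rng, tpl, spec.mutation_rate))
                domains.append(
                    DomainTruth(
                        template_id=tid,
                        group=tpl.group if len(GROUP_COMPOSITION[group]) == 1
                        else tpl.group,
                        span=(offset + tpl.span[0], offset + tpl.span[1]),
                        sig_offset=offset + tpl.sig_offset,
                        chelators=tuple(offset + c for c in tpl.chelators),
                        pr_anchor=-1 if tpl.pr_anchor < 0 else offset + tpl.pr_anchor,
                        vqr_anchor=-1 if tpl.vqr_anchor < 0 else offset + tpl.vqr_anchor,
                    )
                )
                parts.append(_random_linker(rng, lo, hi))
            residues = "".join(parts)
            records.append(SequenceRecord(pid, residues))
            truth.proteins[pid] = ProteinTruth(pid, group, domains)
    for k in range(spec.decoy_proteins):
        pid = f"SYN_decoy_{k}"
        records.append(SequenceRecord(pid, _random_linker(rng, 150, 250)))
        truth.proteins[pid] = ProteinTruth(pid, "decoy")
    return records, truth


# ---------------------------------------------------------------------------
# Gene models


def _plan_introns(spec: SynthSpec, truth: TruthTable, rng: np.random.Generator):
    """Assign an intron type to each eligible planted protein, honouring the
    per-type counts in ``spec.intron_plan`` up to the number of carriers."""
    pr_capable = [
        p for p in truth.proteins.values()
        if p.domains and p.domains[-1].pr_anchor > 0
    ]
    vqr_capable = [
        p for p in truth.proteins.values()
        if p.domains and p.domains[-1].vqr_anchor > 0
    ]
    any_domain = [p for p in truth.proteins.values() if p.domains]
    plan = spec.intron_plan
    assigned = set()

    def take(pool, count):
        out = [p for p in pool if p.protein_id not in assigned][:count]
        assigned.update(p.protein_id for p in out)
        return out

    for p in take(pr_capable, plan.get("PR", 0)):
        p.intron_type = "PR"
    for p in take(vqr_capable, plan.get("VQR", 0)):
        p.intron_type = "VQR"
    for p in take(any_domain, plan.get("OTHER", 0)):
        p.intron_type = "OTHER"
    for p in take(any_domain, plan.get("NONE", 0)):
        p.intron_type = "NONE"


def generate_gene_models(
    truth: TruthTable,
    proteome: list[SequenceRecord],
    spec: SynthSpec,
) -> tuple[list[SequenceRecord], list[GeneModel]]:
    """Reverse-translate planted proteins into gene models with planted introns.

    Each gene sits on its own contig with 50 bp of intergenic padding; intron
    bodies are GT...AG, length 60-300; the interruption point is placed
    exactly at the planned anchor residue (PR or VQR) or control position,
    with a random phase.  Every second emitted model goes on the minus strand
    with mirrored coordinates.
    """
    rng = np.random.default_rng(spec.seed + 1)
    _plan_introns(spec, truth, rng)
    by_id = {r.id: r for r in proteome}
    contigs: list[SequenceRecord] = []
    models: list[GeneModel] = []
    emitted = 0
    for pid in sorted(truth.proteins):
        p = truth.proteins[pid]
        if p.intron_type is None:
            continue
        protein = by_id[pid]
        cds = "".join(CODON[aa] for aa in protein.residues) + STOP
        domain = p.domains[-1]
        if p.intron_type == "PR":
            anchor = domain.pr_anchor
        elif p.intron_type == "VQR":
            anchor = domain.vqr_anchor
        elif p.intron_type == "OTHER":
            anchor = domain.sig_offset + 3  # inside the signature: near no anchor
        else:  # NONE: well upstream of the domain, outside the flank
            anchor = max(1, domain.span[0] + 1 - 15)
        phase = int(rng.integers(0, 3))
        cut = 3 * anchor + phase  # coding bases before the intron
        if cut >= len(cds):
            cut = len(cds) - 3
            phase = cut % 3
        intron_len = int(rng.integers(60, 301))
        body = "GT" + "".join(rng.choice(list("ACGT"), size=intron_len - 4)) + "AG"
        pad5 = "".join(rng.choice(list("ACGT"), size=50))
        pad3 = "".join(rng.choice(list("ACGT"), size=50))
        contig_seq = pad5 + cds[:cut] + body + cds[cut:] + pad3
        exon1 = (50, 50 + cut)  # 0-based half-open
        exon2 = (50 + cut + intron_len, 50 + len(cds) + intron_len)
        strand = "+" if emitted % 2 == 0 else "-"
        if strand == "-":
            contig_seq = _revcomp(contig_seq)
            L = len(contig_seq)
            exon1, exon2 = (L - exon2[1], L - exon2[0]), (L - exon1[1], L - exon1[0])
        contig_id = f"ctg_{pid}"
        contigs.append(SequenceRecord(contig_id, contig_seq))
        models.append(
            GeneModel(
                gene_id=pid, seq_id=contig_id, strand=strand,
                cds_segments=sorted([exon1, exon2]), protein_id=pid,
            )
        )
        p.intron_protein_position = anchor
        p.intron_phase = phase
        emitted += 1
    return contigs, models


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def splice_and_translate(contig: str, model: GeneModel) -> str:
    """Independent check helper: splice a model's CDS out of its contig and
    translate it with the fixed codon table (stop trimmed)."""
    parts = [contig[s:e] for s, e in model.cds_segments]
    cds = "".join(parts)
    if model.strand == "-":
        cds = _revcomp(cds)
    inverse = {v: k for k, v in CODON.items()}
    aas = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon == STOP:
            break
        aas.append(inverse[codon])
    return "".join(aas)


# ---------------------------------------------------------------------------
# Chimeric architecture tables


def generate_rw_table(spec: SynthSpec) -> tuple[list[DomainAnnotationRow], TruthTable]:
    """Emit domain-annotation rows realising one grammar witness per requested
    family, plus NLR-only and WRKY-only decoys."""
    rng = np.random.default_rng(spec.seed + 2)
    rows: list[DomainAnnotationRow] = []
    truth = TruthTable()

    def emit(pid: str, tokens: list[str]):
        pos = 1
        wrky_groups = []
        for tok in tokens:
            width = int(rng.integers(60, 200))
            label = tok
            if tok.startswith("WRKY"):
                label = "WRKY"
                wrky_groups.append(tok[5:-1])
                width = int(rng.integers(60, 80))
            rows.append(
                DomainAnnotationRow(
                    protein_id=pid, domain_label=label,
                    start=pos - 1, end=pos - 1 + width,
                    score=float(np.round(rng.uniform(20, 300), 1)),
                )
            )
            pos += width + int(rng.integers(10, 40))
        return wrky_groups

    for family in RW_FAMILIES:
        for k in range(spec.rw_plan.get(family, 0)):
            pid = f"RWSYN_{family}_{k}"
            tokens = []
            for tok in RW_WITNESSES[family]:
                if tok.startswith("opt:"):
                    if rng.random() < 0.5:
                        tokens.append(tok[4:])
                else:
                    tokens.append(tok)
            groups = emit(pid, tokens)
            truth.proteins[pid] = ProteinTruth(
                pid, "rw", rw_family=family,
                lineage_hint=RW_HINTS.get(family), wrky_groups=groups,
            )
    for k in range(spec.rw_plan.get("decoy_NLR", 0)):
        pid = f"RWSYN_decoyNLR_{k}"
        emit(pid, ["TIR", "NB-ARC", "LRR"])
        truth.proteins[pid] = ProteinTruth(pid, "decoy", rw_family="NOT_RW")
    for k in range(spec.rw_plan.get("decoy_WRKY", 0)):
        pid = f"RWSYN_decoyWRKY_{k}"
        groups = emit(pid, ["WRKY(IIc)"])
        truth.proteins[pid] = ProteinTruth(
            pid, "decoy", rw_family="NOT_RW", wrky_groups=groups
        )
    rows.sort(key=lambda r: (r.protein_id, r.start))
    return rows, truth


def domain_alignment(
    records: list[SequenceRecord],
    truth: TruthTable,
    template_ids: Optional[set] = None,
) -> list[SequenceRecord]:
    """Extract planted domains as an implicit alignment.

    All templates are 75 residues with identical signature offset, so the
    extracted domain regions line up column-for-column without an explicit
    alignment step.  Rows are named ``<template_id>|<protein_id>``.
    """
    by_id = {r.id: r for r in records}
    rows = []
    for pid, p in sorted(truth.proteins.items()):
        for d in p.domains:
            if template_ids is not None and d.template_id not in template_ids:
                continue
            rec = by_id[pid]
            lo = d.span[0] - 8  # template starts 8 residues before the signature
            hi = d.span[1] + 1
            rows.append(SequenceRecord(f"{d.template_id}|{pid}", rec.residues[lo:hi]))
    return rows


# ---------------------------------------------------------------------------
# Bundle writer (used by the CLI `simulate` subcommand)


def write_bundle(outdir, spec: SynthSpec) -> dict:
    """Generate and write proteins.faa, genome.fna, genes.gff3, domains.tsv
    and truth.tsv under ``outdir``; returns summary counts."""
    from pathlib import Path
    from .io_formats import write_domain_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    proteome, truth = generate_proteome(spec)
    contigs, models = generate_gene_models(truth, proteome, spec)
    rw_rows, rw_truth = generate_rw_table(spec)
    write_fasta(proteome, out / "proteins.faa")
    write_fasta(contigs, out / "genome.fna")
    write_gff3(models, out / "genes.gff3")
    write_domain_table(rw_rows, out / "domains.tsv")
    with open(out / "rw_groups.tsv", "w", newline="\n") as fh:
        fh.write("protein_id\twrky_groups\tlineage_hint\n")
        for pid in sorted(rw_truth.proteins):
            p = rw_truth.proteins[pid]
            fh.write(f"{pid}\t{','.join(p.wrky_groups)}\t{p.lineage_hint or ''}\n")
    with open(out / "truth.tsv", "w", newline="\n") as fh:
        fh.write(
            "protein_id\tgroup\tn_domains\tintron_type\tintron_position\t"
            "rw_family\twrky_groups\n"
        )
        for pid in sorted({**truth.proteins, **rw_truth.proteins}):
            p = truth.proteins.get(pid) or rw_truth.proteins[pid]
            fh.write(
                f"{pid}\t{p.group}\t{len(p.domains)}\t{p.intron_type or ''}\t"
                f"{p.intron_protein_position or ''}\t{p.rw_family or ''}\t"
                f"{','.join(p.wrky_groups)}\n"
            )
    return {
        "proteins": len(proteome),
        "contigs": len(contigs),
        "gene_models": len(models),
        "rw_rows": len(rw_rows),
    }
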