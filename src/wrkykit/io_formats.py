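"""Readers and writers for every on-disk format the pipeline touches.

Formats: protein FASTA (optionally gapped), GFF3 gene models, hmmscan
``--domtblout`` tables, plain TSV domain tables, the packaged chimeric-gene
catalogue, and Newick trees.

Coordinate convention: every file format speaks 1-based inclusive coordinates
(the GFF3 convention); every in-memory span in this package is 0-based
half-open.  The conversion happens here, at the I/O boundary, and nowhere
else.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import skbio

from .errors import EmptyInput, FormatError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
_VALID_RESIDUES = AMINO_ACIDS | {"X"}
_VALID_ALIGNED = _VALID_RESIDUES | {"-"}

#: Controlled vocabulary for domain annotation labels.
DOMAIN_VOCABULARY = (
    "TIR", "NB-ARC", "LRR", "WRKY", "B3", "NAC", "CAMB", "MAPKKK", "PAH",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence; ``id`` is the first whitespace-delimited header word."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace("-", ""), self.description)


@dataclass
class GeneModel:
    """CDS structure of one mRNA.

    ``cds_segments`` are 0-based half-open genomic intervals, stored in
    ascending genomic order regardless of strand; transcription order on the
    minus strand is the reverse.  ``incomplete`` flags models whose total CDS
    length is not a codon multiple.
    """

    gene_id: str
    seq_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    protein_id: str
    incomplete: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = sorted(self.cds_segments)
        for (s, e) in segs:
            if s >= e:
                raise FormatError(f"{self.gene_id}: empty/inverted CDS segment {s}:{e}")
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise FormatError(f"{self.gene_id}: overlapping CDS segments")
        self.cds_segments = segs
        if self.coding_length % 3 != 0:
            self.incomplete = True

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def segments_in_transcription_order(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return list(self.cds_segments)
        return list(reversed(self.cds_segments))


@dataclass(frozen=True)
class DomainAnnotationRow:
    """One externally produced domain call on a protein (0-based half-open span)."""

    protein_id: str
    domain_label: str
    start: int
    end: int
    score: float

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"{self.protein_id}: domain row span {self.start}:{self.end} is empty"
            )


@dataclass(frozen=True)
class CatalogueEntry:
    """One row of the packaged chimeric R-protein/WRKY gene catalogue."""

    name: str
    species: str
    gene_model: str
    seq_id: str
    span: Optional[tuple[int, int]]  # 1-based inclusive, as printed
    rw_family: str  # RW1..RW8 or "unassigned"
    notes: str = ""

    @property
    def length(self) -> Optional[int]:
        if self.span is None:
            return None
        return self.span[1] - self.span[0] + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a protein FASTA file.

    With ``aligned=True`` gap characters are retained and all rows must have
    equal length; otherwise a gap character is a format error.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        alphabet = _VALID_ALIGNED if aligned else _VALID_RESIDUES
        bad = set(residues) - alphabet
        if bad:
            kind = "alignment" if aligned else "sequence"
            raise FormatError(
                f"{rec.id}: invalid {kind} characters {sorted(bad)} in {path}"
            )
        records.append(SequenceRecord(rec.id, residues, rec.description))
    if not records:
        raise EmptyInput(f"no FASTA records in {path}")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment in {path}: row lengths {sorted(lengths)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def read_gff3(path) -> list[GeneModel]:
    """Extract one :class:`GeneModel` per mRNA from the CDS features of a GFF3 file.

    Only ``CDS`` rows are consulted; each must carry a ``Parent`` (or
    ``protein_id``) attribute naming its transcript.  UTR/exon/gene rows are
    ignored, so intron inference downstream is insensitive to their presence.
    """
    per_parent: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seq_id, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attr.get("Parent") or attr.get("protein_id")
            if not parent:
                raise FormatError(f"{path}:{lineno}: CDS feature without Parent")
            try:
                s1, e1 = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
            entry = per_parent.setdefault(
                parent,
                {"seq_id": seq_id, "strand": strand, "segments": [],
                 "protein_id": attr.get("protein_id", parent)},
            )
            if entry["strand"] != strand:
                raise FormatError(f"{path}:{lineno}: mixed strands in model {parent!r}")
            if entry["seq_id"] != seq_id:
                raise FormatError(f"{path}:{lineno}: mixed seq_ids in model {parent!r}")
            entry["segments"].append((s1 - 1, e1))  # to 0-based half-open
    models = []
    for parent, entry in per_parent.items():
        models.append(
            GeneModel(
                gene_id=parent,
                seq_id=entry["seq_id"],
                strand=entry["strand"],
                cds_segments=sorted(entry["segments"]),
                protein_id=entry["protein_id"],
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for s, e in m.cds_segments:
                fh.write(
                    "\t".join(
                        [
                            m.seq_id, "wrkykit", "CDS", str(s + 1), str(e), ".",
                            m.strand, ".",
                            f"Parent={m.gene_id};protein_id={m.protein_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Domain tables


def _load_label_map(extra_path=None) -> dict[str, str]:
    mapping = {}
    text = resources.files("wrkykit.data").joinpath("domain_label_map.tsv").read_text()
    sources = [io.StringIO(text)]
    if extra_path is not None:
        sources.append(open(extra_path))
    for src in sources:
        with src:
            for line in src:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                raw, mapped = line.split("\t")
                mapping[raw] = mapped
    return mapping


def map_domain_label(raw: str, mapping: Optional[dict[str, str]] = None) -> str:
    """Map a raw Pfam-style domain name onto the controlled vocabulary.

    Unknown names become ``OTHER:<raw>`` rather than erroring, so novel
    domains survive into architecture strings.
    """
    if mapping is None:
        mapping = _load_label_map()
    if raw in mapping:
        return mapping[raw]
    # prefix families such as LRR_1..LRR_8, LRRNT_2
    for prefix, label in (("LRR", "LRR"), ("NB-ARC", "NB-ARC"), ("WRKY", "WRKY")):
        if raw.upper().startswith(prefix):
            return label
    return f"OTHER:{raw}"


def read_domain_table(path, dialect: str = "tsv", label_map_path=None) -> list[DomainAnnotationRow]:
    """Read external domain calls in either hmmscan ``domtblout`` or plain TSV form.

    TSV columns: protein_id, domain, start, end, score (1-based inclusive
    coordinates; a header line starting with ``protein_id`` is skipped).
    From domtblout only the target name, query name, envelope coordinates and
    full-sequence score are used.
    """
    if dialect not in ("tsv", "domtblout"):
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping = _load_label_map(label_map_path)
    rows: list[DomainAnnotationRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "domtblout":
                cols = line.split()
                if len(cols) < 22:
                    raise FormatError(f"{path}:{lineno}: short domtblout row")
                raw_name, protein_id = cols[0], cols[3]
                try:
                    score = float(cols[7])
                    start1, end1 = int(cols[19]), int(cols[20])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed domtblout row") from exc
            else:
                cols = line.split("\t")
                if cols[0] == "protein_id":
                    continue
                if len(cols) < 5:
                    raise FormatError(f"{path}:{lineno}: expected 5 TSV columns")
                protein_id, raw_name = cols[0], cols[1]
                try:
                    start1, end1 = int(cols[2]), int(cols[3])
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed TSV row") from exc
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: start > end")
            rows.append(
                DomainAnnotationRow(
                    protein_id=protein_id,
                    domain_label=map_domain_label(raw_name, mapping),
                    start=start1 - 1,
                    end=end1,
                    score=score,
                )
            )
    rows.sort(key=lambda r: (r.protein_id, r.start))
    return rows


def write_domain_table(rows: Iterable[DomainAnnotationRow], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tdomain\tstart\tend\tscore\n")
        for r in rows:
            fh.write(f"{r.protein_id}\t{r.domain_label}\t{r.start + 1}\t{r.end}\t{r.score}\n")


# ---------------------------------------------------------------------------
# Chimeric-gene catalogue

_SPAN_RE = re.compile(r"^(\d+)-(\d+)$")


def read_rw_catalogue(path=None) -> list[CatalogueEntry]:
    """Read the catalogue of chimeric R-protein/WRKY genes.

    With no argument, the packaged 29-entry catalogue is loaded.  Columns:
    name, species, gene_model, seq_id, span (``start-end`` 1-based inclusive,
    or empty when the source prints none), rw_family, notes.
    """
    if path is None:
        text = resources.files("wrkykit.data").joinpath("rw_catalogue.tsv").read_text()
    else:
        text = Path(path).read_text()
    entries: list[CatalogueEntry] = []
    seen = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        cols = line.split("\t")
        if len(cols) == 6:  # trailing notes column omitted
            cols.append("")
        if len(cols) != 7:
            raise FormatError(f"catalogue line {lineno}: expected 7 columns, got {len(cols)}")
        name, species, gene_model, seq_id, span_s, family, notes = cols
        if name in seen:
            raise FormatError(f"catalogue line {lineno}: duplicate name {name!r}")
        seen.add(name)
        span = None
        if span_s:
            m = _SPAN_RE.match(span_s)
            if not m:
                raise FormatError(f"catalogue line {lineno}: bad span {span_s!r}")
            span = (int(m.group(1)), int(m.group(2)))
            if span[0] > span[1]:
                raise FormatError(f"catalogue line {lineno}: span start > end")
        entries.append(CatalogueEntry(name, species, gene_model, seq_id, span, family, notes))
    return entries


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: skbio.TreeNode) -> str:
    """Serialise a tree to Newick with branch lengths.

    Every leaf must be named; support values, when present on internal nodes,
    are emitted as internal node labels.
    """
    for tip in tree.tips():
        if not tip.name:
            raise FormatError("tree contains an unnamed leaf")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text_or_path) -> skbio.TreeNode:
    text = str(text_or_path)
    if "(" in text:
        return skbio.TreeNode.read(io.StringIO(text), format="newick")
    return skbio.TreeNode.read(text, format="newick")
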