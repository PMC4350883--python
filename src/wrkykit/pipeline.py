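"""End-to-end pipeline: scan -> classify -> introns -> rw -> tree.

Each stage is a pure function over in-memory objects plus a TSV writer; the
orchestrator validates the configuration up front, executes the stages whose
inputs are configured, logs per-stage record counts, and writes a summary
with the effective configuration alongside the outputs so every run is
reproducible from its own directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats, domain_scanner, group_classifier, intron_typer, phylo
from . import rwrky_classifier
from .errors import ConfigError

log = logging.getLogger("wrkykit")


@dataclass
class RunConfig:
    fasta: Optional[str] = None
    gff3: Optional[str] = None
    domains: Optional[str] = None  # external domain-annotation table
    domains_dialect: str = "tsv"
    rw_groups: Optional[str] = None  # external WRKY group/hint table for rw stage
    alignment: Optional[str] = None  # aligned domain FASTA for the tree stage
    outdir: str = "wrky_run"
    max_mismatches: int = 1
    finger_window: int = 60
    refine: bool = True
    deletion: str = "pairwise"
    min_coverage: Optional[float] = None  # None: no coverage filtering before NJ
    bootstrap: int = 1000
    seed: int = 0

    def validate(self):
        if self.fasta is None and self.alignment is None and self.domains is None:
            raise ConfigError("nothing to do: no fasta, alignment or domain table")
        for label, path in (
            ("fasta", self.fasta), ("gff3", self.gff3),
            ("domains", self.domains), ("alignment", self.alignment),
            ("rw_groups", self.rw_groups),
        ):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} input not found: {path}")
        if not 0 <= self.max_mismatches <= 3:
            raise ConfigError("max_mismatches must be in [0, 3]")
        if self.min_coverage is not None and not 0 < self.min_coverage <= 1:
            raise ConfigError("min_coverage must be in (0, 1]")
        if self.deletion not in ("pairwise", "complete"):
            raise ConfigError(f"unknown deletion mode {self.deletion!r}")
        if self.bootstrap < 1:
            raise ConfigError("bootstrap must be >= 1")


def scan_stage(records, config: RunConfig):
    sc = domain_scanner.ScanConfig(
        max_mismatches=config.max_mismatches, finger_window=config.finger_window
    )
    results = {}
    for rec in records:
        domains, rejected = domain_scanner.call_wrky_domains(rec, sc)
        results[rec.id] = (domains, rejected)
    return results


def classify_stage(records, scan_results, refine: bool = True):
    by_id = {r.id: r for r in records}
    refs = group_classifier.load_reference_set() if refine else None
    calls = {}
    for pid, (domains, _) in scan_results.items():
        if not domains:
            continue
        protein_calls = group_classifier.classify_domain_rules(
            domains, by_id[pid].residues
        )
        if refine:
            protein_calls = [
                group_classifier.refine_by_reference(c, refs)
                if c.group in group_classifier.REFINABLE
                else c
                for c in protein_calls
            ]
        calls[pid] = protein_calls
    return calls


def intron_stage(models, records, scan_results):
    by_id = {r.id: r for r in records}
    calls = {}
    for model in models:
        if model.protein_id not in by_id:
            continue
        introns = intron_typer.protein_coordinates_of_introns(model)
        domains, _ = scan_results.get(model.protein_id, ([], []))
        calls[model.protein_id] = intron_typer.type_introns_for_protein(
            introns, domains, by_id[model.protein_id].residues
        )
    return calls


def rw_stage(rows, group_calls, aux_groups=None):
    """Classify architectures per protein.

    ``group_calls`` carries GroupCall lists from the classify stage;
    ``aux_groups`` optionally maps protein_id -> (wrky_group_list, lineage_hint)
    for proteins whose group calls come from an external table rather than
    from scanning (e.g. truncated transcripts annotated elsewhere).
    """
    from collections import defaultdict
    per_protein = defaultdict(list)
    for row in rows:
        per_protein[row.protein_id].append(row)
    out = {}
    for pid, protein_rows in sorted(per_protein.items()):
        wrky_calls = group_calls.get(pid, [])
        hint = None
        if not wrky_calls and aux_groups and pid in aux_groups:
            wrky_calls, hint = aux_groups[pid]
        arch = rwrky_classifier.build_architecture(protein_rows, wrky_calls)
        out[pid] = (arch, rwrky_classifier.classify_rw(arch, lineage_hint=hint))
    return out


def read_rw_groups(path) -> dict:
    """Read an external WRKY-group table for the rw stage.

    Columns: protein_id, comma-separated WRKY groups N-to-C, optional
    lineage hint.  Lines starting with '#' or a header row are skipped.
    """
    aux = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            cols = line.split("\t")
            groups = [g for g in cols[1].split(",") if g] if len(cols) > 1 else []
            hint = cols[2] or None if len(cols) > 2 else None
            aux[cols[0]] = (groups, hint)
    return aux


def tree_stage(alignment, config: RunConfig):
    if config.min_coverage is not None:
        alignment = phylo.site_coverage_filter(alignment, config.min_coverage)
    tree, support = phylo.bootstrap_support(
        alignment, n_replicates=config.bootstrap, seed=config.seed,
        deletion=config.deletion,
    )
    return alignment, tree, support


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write per-stage TSVs plus a summary.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: v for k, v in vars(config).items()}}

    records = []
    scan_results = {}
    group_calls = {}
    if config.fasta:
        records = io_formats.read_fasta(config.fasta)
        scan_results = scan_stage(records, config)
        n_domains = sum(len(d) for d, _ in scan_results.values())
        n_rejected = sum(len(r) for _, r in scan_results.values())
        log.info("scan: %d proteins, %d domains, %d rejected candidates",
                 len(records), n_domains, n_rejected)
        _write_hits(out / "hits.tsv", scan_results)
        summary["scan"] = {
            "proteins": len(records), "domains": n_domains, "rejected": n_rejected,
        }

        group_calls = classify_stage(records, scan_results, config.refine)
        counts: dict[str, int] = {}
        for calls in group_calls.values():
            for c in calls:
                counts[c.group] = counts.get(c.group, 0) + 1
        log.info("classify: %s", counts)
        _write_groups(out / "groups.tsv", group_calls)
        summary["groups"] = counts

    if config.gff3 and config.fasta:
        models = io_formats.read_gff3(config.gff3)
        intron_calls = intron_stage(models, records, scan_results)
        type_counts: dict[str, int] = {}
        for calls in intron_calls.values():
            for c in calls:
                type_counts[c.type] = type_counts.get(c.type, 0) + 1
        log.info("introns: %s", type_counts)
        _write_introns(out / "introns.tsv", intron_calls)
        summary["introns"] = type_counts

    if config.domains:
        rows = io_formats.read_domain_table(config.domains, config.domains_dialect)
        aux = read_rw_groups(config.rw_groups) if config.rw_groups else None
        rw_calls = rw_stage(rows, group_calls, aux)
        family_counts: dict[str, int] = {}
        for _, (arch, call) in rw_calls.items():
            family_counts[call.family] = family_counts.get(call.family, 0) + 1
        log.info("rw: %s", family_counts)
        _write_rw(out / "rw.tsv", rw_calls)
        summary["rw"] = family_counts

    if config.alignment:
        aln = io_formats.read_fasta(config.alignment, aligned=True)
        aln, tree, support = tree_stage(aln, config)
        newick = io_formats.write_newick(tree)
        (out / "tree.nwk").write_text(newick + "\n")
        with open(out / "support.tsv", "w", newline="\n") as fh:
            fh.write("bipartition\tsupport\n")
            for bp, s in sorted(support.items(), key=lambda kv: -kv[1]):
                fh.write(f"{','.join(sorted(bp))}\t{s:.4f}\n")
        summary["tree"] = {
            "taxa": len(aln), "columns": len(aln[0].residues),
            "bootstrap": config.bootstrap,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary


# ---------------------------------------------------------------------------
# TSV writers (all output coordinates 1-based inclusive)


def _write_hits(path, scan_results):
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "protein_id\tstatus\tindex\tsignature_start\tsignature\tvariant\t"
            "mismatches\tfinger_class\tcompleteness\tchelators\tspan_start\tspan_end\n"
        )
        for pid in sorted(scan_results):
            domains, rejected = scan_results[pid]
            for d in domains:
                fh.write(
                    f"{pid}\tdomain\t{d.index_in_protein}\t{d.signature.offset + 1}\t"
                    f"{d.signature.heptapeptide}\t{d.signature.matched_variant}\t"
                    f"{d.signature.mismatches}\t{d.finger.pattern_class}\t"
                    f"{d.finger.completeness}\t"
                    f"{','.join(str(c + 1) for c in d.finger.chelator_positions)}\t"
                    f"{d.span[0] + 1}\t{d.span[1]}\n"
                )
            for r in rejected:
                fh.write(
                    f"{pid}\trejected\t\t{r.offset + 1}\t{r.heptapeptide}\t"
                    f"{r.matched_variant}\t{r.mismatches}\t\t\t\t\t\n"
                )


def _write_groups(path, group_calls):
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tdomain_index\tgroup\tevidence\tnearest_reference\tdistance\n")
        for pid in sorted(group_calls):
            for c in group_calls[pid]:
                ref, dist = ("", "")
                if c.nearest_reference:
                    ref, dist = c.nearest_reference[0], f"{c.nearest_reference[1]:.6f}"
                fh.write(
                    f"{pid}\t{c.domain.index_in_protein}\t{c.group}\t"
                    f"{';'.join(c.evidence)}\t{ref}\t{dist}\n"
                )


def _write_introns(path, intron_calls):
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tprotein_position\tphase\ttype\tanchor\n")
        for pid in sorted(intron_calls):
            for c in intron_calls[pid]:
                anchor = f"{c.anchor[0]}@{c.anchor[1]}" if c.anchor else ""
                fh.write(
                    f"{pid}\t{c.intron.protein_position}\t{c.intron.phase}\t"
                    f"{c.type}\t{anchor}\n"
                )


def _write_rw(path, rw_calls):
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tarchitecture\tfamily\tmatched_rule\n")
        for pid, (arch, call) in sorted(rw_calls.items()):
            fh.write(f"{pid}\t{arch}\t{call.family}\t{call.matched_rule or ''}\n")
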