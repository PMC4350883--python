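# wrkykit

Annotation, classification and distance phylogenetics for the **WRKY
transcription-factor family** — the large plant family of DNA-binding
proteins whose ~60-residue WRKY domain (a WRKYGQK-like signature
heptapeptide followed by a zinc finger) binds the W-box promoter element.

`wrkykit` is for comparative genomicists who need to take a proteome (plus,
optionally, gene models and external domain annotations) and answer:

* which proteins carry WRKY domains, and where (`domain_scanner`);
* which evolutionary group each domain belongs to — I (two domains),
  IIa-IIe (single C2H2 finger), III (C2HC finger), or the divergent
  fungal/algal/diplomonad types (`group_classifier`);
* whether each gene carries the conserved **PR** intron (Group I-derived
  lineage) or the **VQR** intron (IIa + IIb lineage) (`intron_typer`);
* whether a protein is a chimeric **R protein-WRKY** gene — an NLR
  resistance-protein backbone (TIR/NB-ARC/LRR) fused with WRKY domains —
  and which of the eight architecture families RW1-RW8 it belongs to
  (`rwrky_classifier`, plus a packaged 29-gene catalogue);
* how the domains relate phylogenetically (`phylo`).

## The statistics at the core

Pairwise distances between aligned domains use the proportion of differing
sites *p* with **pairwise deletion** (gap/X columns dropped per pair) and
the **Poisson correction**

    d = -ln(1 - p)    [substitutions per site]

Trees are built by **neighbor joining** (Saitou-Nei) with deterministic
tie-breaking, support by **nonparametric bootstrap** over alignment columns
(seeded, reproducible), and gappy alignments can be pre-filtered by **site
coverage**: columns with less than 95% unambiguous rows are eliminated
(a column at exactly 95% is kept).

Everything is testable offline: the `synthetic_data` module generates
seeded proteomes, genomes/gene models and domain tables with planted
groups, introns and RW architectures plus a machine-readable truth table.

## Worked example

Simulate a data set and run the stages from the shell:

```sh
$ wrky simulate --seed 7 --outdir demo
{"proteins": 60, "contigs": 55, "gene_models": 55, "rw_rows": 42}

$ wrky scan --fasta demo/proteins.faa --max-mm 0 --out demo/hits.tsv
65 domains in 60 proteins -> demo/hits.tsv

$ wrky classify --fasta demo/proteins.faa --out demo/groups.tsv
group calls for 55 proteins -> demo/groups.tsv

$ wrky introns --fasta demo/proteins.faa --gff3 demo/genes.gff3 --out demo/introns.tsv
introns for 55 models -> demo/introns.tsv

$ wrky rw --domains demo/domains.tsv --groups demo/rw_groups.tsv --out demo/rw.tsv
12 architectures -> demo/rw.tsv
```

The 60 proteins carry 65 planted domains (Group I and diplomonad-type
proteins carry two each); all 65 are found, none invented — the truth table
written by `simulate` lets you verify this. `demo/groups.tsv` shows each
call with its evidence trail, e.g.

```
protein_id           domain_index  group          evidence           nearest_reference  distance
SYN_ALGAL_SINGLE_0   0             ALGAL_SINGLE   R5;nearest:ALGAL   ALGAL              0.000000
```

(rule R5 fired — single C-x4-C finger, coarse IIc lineage — and
nearest-reference refinement resolved it to the algal single-domain type at
corrected distance 0). `demo/rw.tsv` shows the architecture grammar at
work, including the one genuinely architecture-ambiguous case, RW2 vs RW4,
resolved by a lineage hint:

```
RWSYN_RW1_0   TIR-NB-ARC-LRR-WRKY(IIe)              RW1   RW1
RWSYN_RW4_0   TIR-NB-ARC-LRR-WRKY(III)              RW4   RW2|RW4
```

Trees, from any aligned FASTA of domains:

```sh
wrky tree --aln domains.afa --boot 1000 --seed 42 --deletion pairwise \
          --out tree.nwk --support-out support.tsv
```

The library surface mirrors the CLI (`wrkykit.call_wrky_domains`,
`classify_domain_rules`, `refine_by_reference`, `type_intron`,
`classify_rw`, `p_distance`, `nj_tree`, `bootstrap_support`, ...); see
`docs/methods.md` for the model, the parameter choices and their
rationale, and known limitations.

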