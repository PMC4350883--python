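# Methods

## Scope

`wrkykit` implements the annotation-and-inference chain used in comparative
studies of the WRKY transcription-factor family: domain detection and
curation, evolutionary group assignment, conserved-intron typing, chimeric
R-protein/WRKY (RW) architecture classification, and distance-based
phylogenetics. Every stage is testable without external downloads because
the package ships a seeded synthetic-data generator with machine-readable
ground truth.

## Domain detection and curation

A WRKY domain consists of a signature heptapeptide followed by a
zinc-finger motif. The scanner searches every 7-residue window anchored on
tryptophan (all known signature variants begin with W; anchoring keeps the
false-positive rate of fuzzy matching low) against the variant library
{WRKYGQK, WKNNGNT, WKKYGNK, WKKYGHK}, reporting the closest variant within
`max_mismatches` (default 1 in the pipeline, 0 in most tests). On uniformly
random sequence the expected number of exact hits is `L x 4 x 20^-7` per
window set — effectively zero, which the test suite confirms empirically.

Zinc fingers are matched as spacing envelopes over the chelating residues:

| class    | envelope                        | carriers            |
|----------|---------------------------------|---------------------|
| C2H2_X4  | C-x(4)-C-x(20,28)-H-x(1)-H      | groups I, IIc-IIe   |
| C2H2_X5  | C-x(5)-C-x(20,28)-H-x(1)-H      | groups IIa, IIb     |
| C2HC     | C-x(4,7)-C-x(20,28)-H-x(1,3)-C  | group III           |
| FUNGAL   | C-x(6)-C-x(5,30)-H-x(3)-C       | fungal-type domains |

The literature prints exemplar spacings, not ranges; the envelopes are a
deliberately permissive operationalisation and are configurable. The C2HC
and FUNGAL envelopes overlap where the fungal C...H gap falls in 20-28;
fixed class precedence (C2H2_X4 < C2H2_X5 < C2HC < FUNGAL) resolves the
ambiguity deterministically, and the synthetic fungal template uses a gap of
12 so the two classes remain separable end to end.

The curation rule is: a domain is called iff a signature hit is followed,
within a 60-residue window, by at least *part* of a zinc finger —
operationalised as >= 2 chelators in class-consistent spacing. The window
width is a package decision (the source material does not bound the
signature-finger distance). Signatures with no downstream finger are kept
as rejected candidates for audit, since incomplete hits may be pseudogenes
or mispredictions, but they are never domains.

## Group assignment

Sequence-level rules separate only part of the group space:

* two C2H2-class domains → I_NT + I_CT (rule R1);
* single C2HC finger → III, or III_MOSS_VARIANT when the signature is in
  the divergent set {WKKYGNK, WKNNGNT} (R2);
* single FUNGAL finger → FUNGAL_TYPE (R3);
* single C2H2_X5 finger with QVQR inside the finger region (R4a) and/or DGC
  within 5 residues before the signature (R4b) → IIb lineage;
* single C2H2_X4 finger → IIc lineage (R5).

IIa vs IIb and IIc vs IId vs IIe have no published motif diagnostics — they
are separated phylogenetically — so the cascade emits a coarse lineage label
and `refine_by_reference` resolves it by globally aligning the domain to
each packaged reference and assigning the nearest group under the
Poisson-corrected distance over aligned non-gap columns. This is a
nearest-neighbour stand-in for tree placement. The eligible reference sets
are IIb→{IIa, IIb} and IIc→{IIc, IId, IIe, ALGAL_SINGLE}; UNCLASSIFIED
calls may refine into any group (this is how two-domain proteins with the
diplomonad C-terminal signature WKKYGHK reach DIPLOMONAD_TYPE). A tie
within 1e-9 of corrected distance keeps the coarse label and records both
candidates.

The DGC window (5 residues) is a package decision: the "immediately before
the signature" phrasing in the literature does not fix an offset.

On the moss/fungal signature question the source statements conflict; the
package follows the two concordant ones (fungal = WKNNGNT, moss Group III
variant = WKKYGNK) and treats both variants as "moss/fungal set" evidence
in R2.

Pairwise alignment uses affine-gap Needleman-Wunsch (gap open -10, extend
-1; a gap of length L costs open + (L-1)·extend) over a BLOSUM62 table
shipped as a plain TSV. Consensus sequences use the conservative
convention: a column emits its majority residue only when its frequency
(gaps excluded from the numerator, included in the denominator) reaches the
threshold, ties emit `x`, all-gap columns emit `-`.

## Intron typing

Intron positions are projected into protein coordinates by walking CDS
segments in transcription order: after `c` coding bases the intron falls
after residue `c // 3` with phase `c % 3`. Minus-strand models are walked
in descending genomic order, so a gene and its reverse-complement mirror
give identical records.

Two conserved positions are diagnostic: the PR intron in the linker between
the signature and the finger (hallmark of the Group I-derived lineage) and
the VQR/QVQR intron inside the finger (hallmark of IIa + IIb). Typing uses
a ±2-codon window around the anchor residue — the published figures mark
single positions but are not machine-readable, and a small window absorbs
annotation jitter. The PR anchor is the R of the P-R dipeptide nearest the
first chelator, searched only between signature end and first chelator; the
VQR anchor is the final R of any V-Q-R inside the finger (Q-V-Q-R ends in
V-Q-R, so one tripattern covers both spellings). The two search regions are
disjoint by construction, so PR and VQR calls are mutually exclusive.
Phase is reported but never used to discriminate. An intron near neither
anchor is OTHER inside the domain ±10 residues, NONE outside.

## RW architecture grammar

A protein is a chimeric candidate when its architecture has at least one
WRKY token and at least one of TIR/NB-ARC/LRR. Architectures are built
from external domain-annotation rows: rows sorted by start, >50%
mutual-overlap conflicts resolved to the higher score, LRR runs separated
by <= 30 residues collapsed to one token, WRKY tokens annotated with their
group calls. The eight family patterns ship as an editable TSV; optional
tokens are 0/1 occurrences and matching is strict (unmatched internal
tokens fail; flanking OTHER:* tokens are ignored). RW2 and RW4 share the
single-WRKY(III) TIR pattern and are separated in the literature only by
lineage; the classifier reports the pair and a lineage hint
(strawberry→RW2, soybean→RW4) may resolve it, never overriding an
unambiguous match. Truncated, unclassifiable WRKY tokens wildcard-match
only inside the RW7 rule, mirroring the one reported truncated-domain case.
The RW6 pattern accepts a NAC token with either one or two WRKY(III)
domains, since the single published NAC-bearing member's WRKY count is
unstated.

## Phylogenetics

The distance chain is the classical amino-acid workflow: p-distance with
pairwise deletion (columns with a gap or X in either row of the pair are
excluded; "ambiguous" means gap or X, the only ambiguity classes in the
data model), the Poisson correction `d = -ln(1 - p)` in substitutions per
site, and Saitou-Nei neighbor joining. NJ ties on the Q criterion break to
the lowest index pair; negative branch lengths are clamped to zero with a
warning, preserving topology. The implementation is cross-checked in the
test suite against scikit-bio's NJ and against exact recovery on additive
matrices from random trees.

The site-coverage filter retains exactly the columns whose fraction of
unambiguous rows is >= the threshold (default 0.95): the rule *eliminates*
strictly-below-threshold columns, so a column at exactly 95% coverage
survives.

Bootstrap support resamples alignment columns with replacement, one seeded
generator per call; replicate r consumes draw r, so results are exact
replicas for fixed (alignment, n, seed) but not stream-stable across
different n. Support is the fraction of replicate trees containing each
non-trivial bipartition of the full-data tree, bipartitions canonicalised
to the side not containing the lexicographically smallest leaf. Supports of
*well-supported* bipartitions are invariant to taxon order; weakly
supported within-clade bipartitions are not, because identical within-clade
distances tie and the tie-break is index-based.

## Synthetic data: what it emulates and what it does not

Each group has a designed 75-residue domain template satisfying its
documented diagnostics, with the signature at offset 8 and the last
chelator at position 73. The templates are *not* transcriptions of any
published alignment (the published consensus figures are graphics);
filenames and docstrings mark them synthetic. Related groups share filler
ancestry — IIc/IId/IIe derive from the I_CT filler, IIa from IIb — so
template distances mirror the published lineage structure
({I + IIc} and {IIa + IIb} as distinct lineages), and the identical layout
means extracted domains align column-for-column without an MSA step.

Mutations are applied per residue at the requested rate to non-diagnostic
positions only (the shipped mask freezes signature, chelators, DGC, QVQR
and PR positions), drawing replacements from an alphabet without W, C or H
so no mutation can create a spurious signature anchor or chelator. Linkers
and decoys use the same W/C/H-free alphabet. Default study conditions:
5 proteins per group plus 5 decoys (60 proteins), mutation rate 0,
linkers 20-60 residues.

Gene models reverse-translate proteins with a fixed one-codon-per-residue
table, insert a GT...AG intron of 60-300 bp exactly at the planned anchor
residue with a random phase, pad 50 bp of intergenic sequence, and emit
every second model on the minus strand with mirrored coordinates.

Consequently, passing tests show that the *inference chain* is correct
under its own assumptions; they do not show robustness to real-data
phenomena the generator omits: indels within domains, alignment error,
splice-site ambiguity, compositional bias, domain-boundary erosion, or
homology between unrelated linkers.

## Numerical and degenerate-input choices

* p = 1 (no shared identical sites) raises rather than returning infinity.
* A pair with zero comparable columns raises `DegenerateDistance` naming
  the pair.
* A coverage filter that removes every column warns and returns
  single-gap rows rather than raising.
* All randomness flows through `numpy.random.default_rng` seeded from the
  spec or call arguments; regeneration is byte-identical.
* Problem sizes in the acceptance script (100 proteins/group for the
  refinement accuracy, 200 bootstrap replicates, 32-taxon four-lineage
  alignment) are desk-scale study conditions chosen so the whole chain
  exercises every stage in seconds.

## Known limitations

* Group assignment for IIc/IId/IIe and IIa/IIb depends entirely on the
  packaged reference set; with real proteomes users should supply their own
  curated references.
* The scanner does not model profile-HMM scores; it is a motif grammar, by
  design.
* The RW grammar is strict: biologically plausible but unlisted
  architectures are RW_NOVEL rather than force-fitted.
* Trees are distance-based only; no likelihood or parsimony search is
  provided.
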