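# Methods

## The segmentation model

The segmenter treats residue-wise order/disorder classification as a
deterministic decision procedure over precomputed evidence, not as a
predictor of its own. Its premise: order is established either by
detectable homology to a known structure or, where homology fails, by the
joint verdict of two complementary disorder callers — one
(predictor A, DISOPRED2-like) trained to flag disorder and silent
elsewhere, the other (predictor B, CLADIST-like) forced to call every
residue ID or SD from composition and conservation. Every stated rule
resolves disagreement toward disorder; ordered regions that no known
structure matches are *cryptic domains* (CD), and a candidate CD is only
believed when it is long enough (strictly more than 30 residues) to fold
independently.

Assumptions worth keeping in mind:

* Evidence tracks are taken at face value; the procedure has no
  confidence weighting. Upstream search/prediction quality bounds output
  quality.
* The subject-length deferral (< 50 residues) assumes short known-structure
  entries are mostly partner-bound fragments of functional ID regions.
  The cut is on the *subject sequence* length, not the alignment length;
  a fragment entry of a long chain is still judged by its own deposited
  length. Both thresholds are `SegmenterConfig` fields.
* Region annotations (transmembrane, signal/transit peptide, coiled coil)
  and qualifying homology hits are equal-rank KD evidence; KD always
  outranks disorder calls, and resolution is per residue (a residue keeps
  the best evidence covering it even when a short hit partially overlaps a
  qualifying one).
* Where predictor B says ID and predictor A is silent, the residue is ID:
  B is the system's primary binary classifier and no rule ever promotes a
  B-ID residue to order.
* Candidate-CD runs at or under the minimum length are relabeled ID rather
  than left unclassified, preserving the binary-partition contract (no
  "unknown" class exists in the output). `cd_strictly_longer=False`
  switches the boundary to inclusive if a user wants it.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `short_subject_threshold` | 50 residues | subject length below which a homology hit defers to disorder calling |
| `cd_min_length` | 30 residues | candidate CD runs must be strictly longer to become CD |
| `fibrous_pfam_ids` | {PF01391, PF00038} | Pfam families treated as known fibrous structure (collagen, α-keratin) |

Statistics defaults: per-localization fractions are residue-weighted
(stratum ID residues / stratum residues), matching the whole-proteome
convention; a protein-weighted mean is available via
`weighting="protein"`. ID-run survival uses a strict cutoff ("longer
than"). The 200–400 length filter is inclusive on both bounds. Site
classification merges KD and CD into SD; disulfides contribute both
cysteines (configurable) and splice events both variable-sequence ends.
Superfamily extrapolations round half up — with the published inputs
(943 superfamilies, 2450/1348 unique domains, 52%/13% shares) they give
519 and 236.

## Coordinates and file formats

Internal coordinates are 0-based half-open; every file format (evidence
and annotation TSV, segmentation GFF3) is 1-based inclusive, the
Swiss-Prot/GFF convention. The readers enforce the predictor-B
full-coverage invariant and in-bounds coordinates, naming protein and row
on failure. The TSV dialects deliberately replace full Swiss-Prot DAT
parsing: only a handful of line types feed the pipeline, and flat tables
keep the package testable offline; a DAT importer could be layered on
later. Nonstandard residue letters are accepted (segmentation logic never
reads composition). Proteins annotated to multiple compartments collapse
to `multiple` (excluded from stratified statistics) unless the pair is
nucleus + cytoplasm, which is a stratum of its own. Residues of signal
peptides that are later cleaved off still count toward residue totals —
the stored sequence is the unit of analysis.

## The synthetic-proteome generator

`dichot.simulate` generates the conditions the analysis modules are meant
to measure: proteins are runs of independent segments, each a disordered
linker or a domain (cryptic with probability `cd_share`, default 13/65 —
the CD share of ordered residues in the human proteome), with
shifted-exponential lengths (domains ≥ 32 so every true CD clears the
30-residue rule; means 110/90 for domains/linkers). Protein target
lengths are log-normal (median ≈ 365 residues, σ = 0.45), human-like in
scale. Localizations are drawn from a weight table and each stratum has a
target residue-wise ID fraction anchored at the two published extremes —
nucleus 0.47, mitochondrion 0.13 — with the remaining strata interpolated
once in the standard descending order (Nuc > Nuc/Cyt > Cyt > PlMem > Sec >
ER/Gol > MitMem > Mit); `multiple`/`other` sit at the proteome mean. Under
the default weights the implied proteome-wide mixture is ≈ 52.8 / 13.2 /
34.0 (KD/CD/ID).

The per-segment linker probability solves
p = f·L_d / (f·L_d + (1−f)·L_l) so pooled stratum fractions converge to
their targets; a proportional feedback controller (gain 5, configurable,
0 restores i.i.d. sampling) nudges that probability toward closing the
realized-vs-target gap, because at a few thousand proteins the smallest
strata would otherwise wander a few percent from their targets. Pfam
emission — one domain-shaped hit per true segment, per-class coverage
probabilities 0.606/0.266/0.085, disjoint per-class identifier pools —
uses the same controller for the same reason.

Evidence emission mirrors the decision rules: true KDs emit a homology
hit with adequate subject length (a small fraction, `region_kd_rate`,
emit a curated region annotation instead); true CDs emit B=SD /
A=unassigned; true IDs emit ID on both tracks. Noise is opt-in and
defaults to zero: `false_call_rate` flips each track call independently
per residue, `missed_hit_rate` drops KD hits, `short_subject_rate` turns
hits into short-subject artifacts. The central oracle of the module is
exact: **at zero noise the segmenter reconstructs every true label
vector bit-for-bit**, which the test suite asserts over 2,000 proteins.

Feature sites are placed per kind with enrichment odds: a site lands in
ID with probability q = odds·f / (odds·f + 1 − f) against the eligible
stratum's realized ID fraction f, then uniformly within the chosen
compartment (proteins weighted by compartment size). Kind eligibility
follows cell biology: phosphorylation intracellular; N-/O-glycosylation,
disulfides and cleavage extracellular; splice boundaries, exon boundaries
and translocation breakpoints everywhere. Default odds (e.g.
phosphorylation and O-glycosylation 3, disulfide 0.25, exon boundary 1)
reproduce the qualitative enrichment ordering the statistics modules are
designed to expose. Disulfides and splice events pick their protein
first, so their per-stratum fractions track q only approximately.

What the generator does **not** emulate: realistic amino-acid
compositions (letters are uniform noise — no pipeline stage reads them),
correlated prediction errors (noise is independent per residue/segment),
length-localization interactions, paralogy, and the long-tail run-length
structure of real disordered regions. Passing recovery tests therefore
demonstrates the correctness of the decision rules and statistics, not
the field accuracy of any upstream predictor.

## Numerical and scale choices

All tiling, masking and counting is exact integer arithmetic on numpy
masks; the only stochastic quantities are generator outputs, checked at
fixed seeds against binomial concentration bounds (3σ) or a ±0.02 band.
Problem sizes in the test suite and acceptance script — 2,000 synthetic
proteins (~1 M residues), 1,000–1,200 random small proteins for oracle
equivalence — were chosen as the smallest scales at which every stratum
is populated and Monte-Carlo bands are comfortably met; the whole suite
runs in a few seconds. Degenerate inputs fail loudly: empty segmentation
sets, empty cutoff lists, sites outside their protein, coverage gaps in
predictor B, coordinates beyond protein length.

## Known limitations

* The coverage/extrapolation arithmetic on published per-class counts is
  reproduced exactly; per-species absolute fractions for real proteomes
  require the external databases and search pipelines that produce the
  evidence tracks, which are out of scope here.
* The ID share of the published human counts is 34.4% unrounded (the
  headline figure is quoted as 35% elsewhere); tables here always carry
  unrounded values alongside counts.
* Whether per-class Pfam residue counts should double-count residues
  covered by two overlapping domains is undefined upstream;
  coverage here is a set union (single-counting), and unique-domain
  tallies do multi-count a domain into every class it touches.
* CLADIST/DISOPRED2 internals are not reimplemented; their outputs are
  inputs to this package.
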