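# Methods

`archaeoscan` re-implements, as a self-contained and tested pipeline, the
comparative-genomics analyses that characterize small methanogenic archaeal
genomes of the Methanomassiliicoccales type: genome feature statistics,
pyrrolysine (Pyl) amber-readthrough prediction, ORB-motif replication-origin
mapping, CRISPR array detection, best-hit core-genome orthology and
phyletic-pattern classification of methanogenesis markers.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## Annotation model and coordinates

All coordinates are 1-based inclusive (the GenBank/GFF3 convention), so
printed motif coordinates can be compared directly with reports.  BED output
alone is 0-based half-open, and every report header states its dialect.
Features that wrap the origin of a circular replicon are stored as two
segments sharing one feature id, listed in translation order.  Translation
uses NCBI genetic code table 11; the amber-suppression mode decodes TAG as
pyrrolysine ('O') and continues, while TAA and TGA always terminate.

## Homology engine

All homology calls (readthrough segments, pyl cassette, orthology, spacer
matching) run through one local-alignment engine: Smith-Waterman with
BLOSUM62 and affine gap penalties 11/1 for proteins, +2/−3 with gap open 5 /
extend 2 for nucleotides (Biopython's `PairwiseAligner`).  Two statistics are
defined explicitly rather than inherited from a search tool:

- **identity** = matches / alignment columns (in percent);
- **coverage** = aligned query positions / query length (in percent).

Ties in score break by lexicographic subject id, a deterministic stand-in
for e-value ordering, which makes every result independent of input order.
Pyrrolysine is scored as lysine, selenocysteine as cysteine.  The engine is
exact at the scale the package targets (reference sets of tens to hundreds
of proteins); for full nr-scale searches an external tool would be
substituted behind the same interface, and results there would additionally
depend on that tool's statistics.

## Readthrough (Pyl) detection

A candidate Pyl protein is a TAG-terminated CDS whose standard-code product
and whose virtual in-frame translation of the 3' flanking region (up to but
excluding the next stop codon, wrapping the origin on circular replicons)
share the same best reference hit.  Default thresholds: identity ≥ 30%,
coverage ≥ 50% of the query segment (segments are protein *fragments*, so
the orthology-style 80% is deliberately relaxed), extension ≥ 15 aa, and a
raw alignment score ≥ 50 per segment.  The score floor models the
significance filtering implicit in a database search: without it, short
random segments occasionally reach 30% identity over ~35 columns, which no
e-value-filtered search would report, and the detector's specificity
guarantee (zero candidates on genomes without readthrough structure) would
fail at a rate of roughly one locus per few hundred TAG-terminated genes.
Both parts are fused with 'O' at the amber; if the extension itself ends at
another TAG the fusion may iterate (default at most 2 ambers — known Pyl
proteins carry one).  A shared-hit mode (any qualifying alignment to the
upstream's best subject, rather than best-equals-best) is provided; best-hit
is the default.

The pyl cassette call is homology of annotated CDS against reference
pylS/pylB/pylC/pylD family sequences at 30%/50%, plus pylT as an annotated
tRNA whose product text marks tRNA-Pyl or the CUA anticodon — the annotation
model has no structured anticodon field, so the product string is the
signal.

## ORB scanning and origin calling

The scanner reports every position, on both strands, whose window lies
within a Hamming-distance budget of an IUPAC-aware consensus core; circular
genomes are scanned across the origin.  The default core is the 22-mer
Methanomassiliicoccales consensus `GTTCCAGTGGAAATGGAGGGGT` with
`max_mismatch = 4`, matching the divergence of the reported motifs from
their consensus; the reported consensus carries a 23rd trailing base that
the underlying motifs do not support, so it is omitted from the default
(the core is fully configurable).  Pair spacing is defined as
start(hit2) − end(hit1) for hits ordered by start — the definition that
reproduces the printed spacing of 39 for motifs at 78–99 and 138–159.
Defaults: `max_pair_spacing` 300 bp (reported spacings are 39–256 bp) and
`origin_window` 10 kb around an orc1/cdc6 gene (identified by product text).
Consensus derivation is per-column strict majority with ties emitting the
minimal covering IUPAC code.

## CRISPR detection

Seeds are exact 16-mers recurring with a period inside one repeat+spacer
unit (default DR 23–47 bp, spacer 20–60 bp, so periods 43–107 bp); seed
chains of ≥ `min_units` (default 3) are extended column-by-column while at
least 1 − `max_dr_mismatch_fraction` (default 0.8) of units agree on the
majority base, bounded so no spacer is squeezed below its minimum.  The DR
consensus is column majority; terminal units above the mismatch bound are
trimmed; overlapping candidate arrays deduplicate greedily, preferring more
units.  With ≥ ~6 identical repeats, the probability that a column beyond
the true repeat boundary agrees across all units is negligible, so planted
arrays are recovered base-exactly; 3-unit arrays can in principle overshoot
a boundary by a base.  Spacer matching reports the exact identity fraction
(matches / alignment columns) of the best local nucleotide alignment and
additionally requires the alignment to cover 80% of the spacer, so a
chance-perfect short local match does not count as a hit.

## Orthology and the core genome

Best-hit orthology at identity ≥ 30% and query coverage ≥ 80% (the
screening thresholds), best-hit rather than reciprocal-best-hit by default
(a reciprocal mode exists).  The three-way partition assigns each protein of
each proteome to exactly one of seven cells by which other proteomes hold a
qualifying best hit; cell counts therefore sum to proteome sizes.  The same
thresholds drive the outgroup screen (presence = any qualifying hit;
"absent from all" counted per target).

## Phyletic marker categories

Six categories over a boolean family × taxon matrix with taxa partitioned
into focal clade / other methanogens / other archaea; see the module
docstring for the exact predicates.  Numerical choices: ">90%" and "<5%"
are strict inequalities (configurable to inclusive); "not in other archaea"
means an outgroup fraction of exactly zero; categories 1–3 require presence
in every focal taxon, 4–6 absence from every focal taxon, so the ranges are
mutually exclusive; evaluation is in order 1→6 returning the first match,
the most specific label, since category 1 implies category 2's condition.
Fractions for "other methanogens" (categories 4–6) exclude the focal clade,
following the wording of the category definitions.  Category 3's ">90% of
methanogens" is computed over the whole ingroup including the focal taxa.

## Synthetic benchmark

The generator emulates the statistical envelope of the target genomes:
configurable length, GC (the real genomes span 41–61%), target coding
density (~88–90%), mean CDS length (~900 bp) and stop-codon usage, with
every detectable signal plantable at truth-recorded coordinates.  Details
that matter for the tests:

- Background intergenic sequence is order-0 at the configured GC; coding
  sequence is sampled codon-by-codon with GC-weighted codon probabilities
  (so GC3 tracks genomic GC), which is also how reference proteins are
  back-translated.
- Stop and start codons are apportioned by largest remainder, so realized
  stop usage matches the configuration to within 1/n — well inside the ±3
  point acceptance band, and tight enough to benchmark a 1.6% amber
  fraction at n ≥ 500 genes.
- Gene lengths are gamma-distributed (shape 2) and rescaled so realized
  coding density lands within a fraction of a point of target; intergenic
  gaps follow a symmetric Dirichlet-multinomial split of the non-coding
  budget.
- After assembly the background is screened: no window within Hamming
  distance 1 of a planted ORB core and no exact off-array copy of a planted
  DR survives (offending windows are re-rolled), which is what makes
  planted-recovery tests exact rather than statistical.
- One seeded RNG drives everything; identical configs give byte-identical
  FASTA/GFF3/truth output.

What the synthetic benchmark does **not** model: phylogenetic correlation
among proteomes (family members diverge by i.i.d. substitution, not along a
tree), indels, pseudogenes, mobile elements, real codon-usage bias beyond
GC, PYLIS-like structural context of readthrough sites, or degraded CRISPR
repeats.  Passing the planted-recovery suite therefore shows the detectors
implement their definitions correctly and are specific on featureless
background; it does not measure sensitivity on diverged real signals.

## Problem sizes and degenerate inputs

Tests and the acceptance script run on 25–300 kb genomes (a few hundred
genes), reference sets of ~6 proteins and 20-protein proteomes — sizes
chosen so the full suite completes in well under a minute of alignment time
while every statistical tolerance is still binding.  Degenerate inputs are
signalled, not guessed at: empty genomes, fewer than two features for
intergenic statistics, CDS lengths not divisible by 3 (skipped and
counted), missing rRNA kinds (undetermined classification with a warning),
missing orc1/cdc6 genes (no origin candidates, with a warning), and
infeasible planting footprints (PackingError).

## Known limitations

- The in-package aligner has no e-value model; the score floor is a proxy
  calibrated for small reference sets.
- CRISPR repeat orientation is reported as found; no leader prediction or
  strand canonicalization is attempted.
- Origin calling is motif-proximity only; no replication-timing or skew
  evidence is used.
- Deposited-genome reruns additionally depend on annotation conventions
  (whether deposited CDS include stop codons — the reader tolerates both)
  and on reference-database versions, so counts from such runs are
  directional rather than exact.
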