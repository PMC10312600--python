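# Methods

## Phasing and classification model

A transcript's combinatorial edit state over `k` editable adenosines can be
observed directly only when one sequencing read covers all `k` sites.
`editphase` therefore distinguishes *phased* site sets (the three Cpx
exon-7A adenosines at transcript positions 375/388/389) from *independent*
ones (synapsin N15/R19/R20, syntaxin-1A M244), and for phased sets emits a
read call only when a single contiguous aligned segment covers every site
with base quality at or above the threshold. "One continuous read" is taken
strictly as one aligned segment of one sequencing read: paired mates are
never merged, and an indel or reference skip over any site drops the read.
This is the stricter of the two defensible readings of the rule; merging
non-conflicting mates would raise yield at the cost of occasionally phasing
across an unobserved gap.

Base calls are normalised to the mRNA sense strand (a minus-strand gene's
genomic T→C mismatch is an edited call). Calls outside {A, G} — sequencing
errors or SNVs — are tallied but removed from both the numerator and the
denominator of every fraction, so they can never create phantom haplotypes.
Each extracted read falls into exactly one accounting class (passing,
failing coverage, failing quality, off-model base), and that partition is
asserted on every run.

### Recoding

Each edit state substitutes G at the edited positions of the reference
codons; codons are translated with the standard nuclear genetic code
(Biopython). Variant names render every codon touched by the site set,
unchanged residues without a suffix: the unedited state of the Cpx set is
`"I125,N130"`, the triple edit `"I125M,N130G"`. Names are protein-level, so
synonymous edits collapse: enumeration deduplicates by name and can return
fewer than `2^k` variants.

### Per-cell quantities and filters

A cell's variant percent is that variant's phased-read count divided by the
cell's total phased reads, × 100 — the denominator under which the eight
variant percentages of a cell sum to exactly 100. The alternative
denominator (all reads touching any site) does not have that property and
is not used; site-level fractions use per-site denominators instead
(edited / (ref + edited) at that site), which serves independent site sets
and the cross-gene comparison.

A cell is excluded when any site of interest has fewer than `min_reads`
(default 10) evaluable reads. The cross-gene table applies the joint form
of the same rule: a cell appears only if every base of every gene passes,
which is by construction the intersection of the per-base filters.

### Population summaries

Group means are arithmetic means over QC-pass cells; SEM uses the sample
(n−1) standard deviation divided by √n, matching conventional mean ± SEM
reporting (undefined, NaN, for n = 1). A cell "expresses" a variant when
its percent is strictly above 0 (one phased read suffices; the threshold is
configurable), and conditional means average only over expressing cells.
"Any editing" counts cells whose unedited percent is below 100. The profile
matrix orders groups lexicographically and cells within a group by
descending unedited percent, ties broken by cell id, so output is fully
deterministic.

### Editing vs ADAR expression

The relation between a cell's edit percent and its ADAR TPM is summarised
by ordinary least squares (statsmodels), reporting slope, intercept,
Pearson r, the two-sided p-value for the slope, and the pointwise 95%
confidence band for the *mean response* (t-distribution, n − 2 df) over the
observed TPM range — a confidence band, not a prediction interval. TPM is
consumed as provided rather than recomputed from reads: full-transcriptome
quantification is outside this package's scope, and the simulator emits TPM
directly. At least three pairs and non-constant TPM are required; anything
less raises a degenerate-fit error.

## The synthetic cohort generator

The simulator emulates deep full-length single-cell RNA-seq of two
motoneuron classes over the edited exon. Per cell it draws:

- **editing propensity at 375** (`p375`) from a mixture: point mass at 0
  (weight 0.05, fully unedited cells), point mass at 1 (weight 0.03, cells
  that edit every transcript), and a Beta(1.2, 2.6) body — mean ≈ 0.30
  overall, spanning the full 0–100% range;
- **conditional downstream rates**: per-read editing of 388/389 given an
  edited 375 from Beta(1.0, 10.0) and Beta(1.5, 3.7) (means ≈ 0.09 and
  0.29), versus fixed rates 0.005 and 0.03 on unedited transcripts. This
  per-read conditional-independence model is the simplest mechanism
  consistent with 375-editing enabling the downstream edits, and it makes
  double-edit variants (I125M with an N130 change) far more common than
  lone N130 edits. The induced mixture of variant means is of the same
  shape and order as published motoneuron profiles (unedited dominant,
  I125M,N130S the leading N130 change, N130D rare);
- **read depth** from a negative binomial (mean 500, shape 10) — deep
  per-cell coverage of one exon, not a whole-transcriptome read budget;
- **ADAR TPM** log-normally (median 50, σ_log 0.6), independent of editing
  by default; an optional logit-scale coupling parameter exists solely to
  give the regression stage something to detect in power studies.

Per-read site states are Bernoulli draws from the cell's parameters
(conditionally independent given the 375 state); reads are emitted
pre-aligned over a synthetic reference in which transcript coordinates
equal contig coordinates, with a configurable fraction (default 0.1) placed
to cover the first site but end before the last, exercising the phasing
filter. Sequencing errors substitute a uniform random other base at rate
0.001 per base (Q30-class chemistry). The truth table records every
generative parameter, the expected fractions of all eight haplotypes under
the factorized model, and the realized counts of the phasing-passing reads,
so each pipeline estimate can be scored per cell.

What the generator does *not* emulate: positional coverage bias, intronic
or pre-mRNA reads, alignment artefacts, splice-isoform mixtures, PCR
duplicates, or any dependence structure beyond the single conditioning on
the 375 state. Tests passing on these cohorts therefore demonstrate
correctness of the counting, phasing, filtering and summarisation logic
under the stated generative model — not robustness to real-data artefacts
upstream of it.

## Numerical and design choices

- Coordinates: genomic inputs are 0-based half-open; transcript positions
  1-based; the conversion is explicit in the site configs and tested.
- Mapping/base-quality defaults are 20/20 and per-site low-quality bases
  are treated as uncovered; no duplicate or UMI handling (full-length
  chemistry has none).
- Enumeration and matrix ordering use binary state order (first site most
  significant), making all outputs reproducible byte for byte from a seed.
- Simulated study sizes (100 cells per group, 500 reads per cell, 20
  replicate seeds for recovery studies; 1,000 replicates of 95-cell fits
  for interval calibration) were chosen once as desk-scale analogues of a
  ~200-cell Patch-seq cohort and kept fixed.
- The acceptance script re-derives its brute-force cross-checks
  independently of the library implementations it scores.

## Known limitations

- Fragment-level phasing (merging read pairs) is not implemented; the read
  yield on paired-end data is correspondingly conservative.
- Site configs are per-gene; multi-gene analyses iterate gene by gene.
- The regression stage fits a straight line only; monotone nonlinear
  relations between editing and ADAR abundance would be summarised, not
  modelled.
- `fully_edited_fraction` uses the phased marginal at a site, which equals
  the site-level fraction only over the same evaluable reads; with heavy
  off-model base contamination the two denominators can differ slightly.
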