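# Methods

This note records the models, parameter choices and numerical decisions
behind `mirpipe`, and what the synthetic-data tests do and do not show.

## Study design assumed by the pipeline

The pipeline targets the single-pooled-sample design common in early
plant sRNA studies: one library per condition, each pooled from several
plants, sequenced once. There are no biological replicates, so dispersion
cannot be estimated and differential expression rests on an exact
conditional test of the two counts (below). Nothing in the pipeline
corrects for multiple testing — calls are made at raw p < 0.01, as is
conventional for this design — and users should treat the resulting lists
as candidate sets for qRT-PCR follow-up, which is exactly how the
validation/concordance module is meant to be used.

## Read cleaning (preprocess)

Reads are cleaned in three steps, in order: mean-quality filter, N filter,
3′-adapter trim, then retention-length filter on the trimmed insert.

* **Adapter policy.** The leftmost exact occurrence of an adapter prefix of
  at least 8 nt marks the insert end; reads with no hit are kept whole.
  Longer prefixes are preferred only insofar as any ≥ 8-nt prefix hit
  counts; among hits the leftmost wins, which makes trimming deterministic
  and immune to adapter read-through repeats.
* **Quality policy.** Mean Phred < 20 or any N discards the read. These
  cutoffs are explicit knobs (`min_quality`, and the bounds below), chosen
  as ordinary defaults for this kind of data, not as reconstructions of any
  particular study's unstated settings.
* **Length bounds.** Default retention window 18–30 nt: the lower edge is
  the minimum mature-miRNA length the predictor accepts, the upper edge
  adds margin over the 25-nt maximum so that length-24 siRNA-like tags are
  retained for the annotation accounting.

Internally every sequence is DNA (T); U↔T conversion happens only at the
mature-miRNA-reference boundary and in RNA-facing reports.

## Annotation cascade (annotate)

Classification is first-match-wins in the order rRNA > tRNA > snRNA >
snoRNA > known miRNA > repeat > exon > intron > unannotated.

* The four housekeeping ncRNA classes form one stage internally ordered
  rRNA > tRNA > snRNA > snoRNA; matching is exact substring containment of
  the tag (either strand) in a reference sequence. This replaces a
  BLASTn-with-E-value step with a deterministic, dependency-free criterion;
  a BLAST-like backend can be plugged in where sensitivity to imperfect
  ncRNA matches matters.
* Known-miRNA assignment is an ungapped same-length comparison against the
  mature reference with ≤ 2 substitutions, tags going to the reference with
  the fewest mismatches (ties by id). By default an assignment does not
  require a genomic hit — a reference built from many species covers
  family members whose loci are absent from the assembly under study — and
  such tags count toward the miRNA category but not toward
  "mapped to genome". A flag (`require_genome_hit_for_known`) enforces the
  stricter behaviour.
* A multi-locus tag is still one tag: category accounting tallies tags and
  reads, never loci, and no locus cap applies at annotation (the 20-locus
  cap belongs to novel-miRNA prediction only).
* Percentages in the accounting table are count / clean reads × 100
  rounded to two decimals, computed per library and per column (unique
  percentages against the unique-tag total).

## Folding engine (fold)

The default engine minimises a deliberately simple stacked-pair energy:
a pair (i, j) whose inner neighbour (i+1, j-1) is also paired contributes
the stack energy of the outer pair — GC/CG −3.0, AU/UA −2.0, GU/UG −1.0
kcal/mol — with hairpin loops ≥ 3 nt and no loop, dangling-end or
multiloop terms. Consequences worth knowing:

* Isolated pairs carry zero energy; traceback breaks ties toward fewer
  pairs, so they are never reported and an unpairable sequence folds to
  all dots at exactly 0.
* Absolute MFEs are not comparable to Turner-parameter folders
  (ViennaRNA); the −18 kcal/mol precursor gate is meaningful *under this
  model*, and all threshold fixtures are constructed under it. Any backend
  honouring the `FoldResult` contract (structure + MFE) can be substituted
  through `fold_fn`, in which case the gate should be recalibrated by the
  user.
* The dynamic programme (O(n³), optionally numba-JIT-compiled above 60 nt)
  is verified against exhaustive enumeration of all nested structures for
  sequences ≤ 20 nt; the enumeration oracle shares only the energy table,
  not the search.
* Because the model has no loop penalties, spurious long-range pairings
  are cheaper than in thermodynamic reality; the hairpin predictor
  compensates by scanning precursor extents smallest-first (below).

## Novel-miRNA prediction (novel_mirna)

Hairpin acceptance uses the standard Mireap-style parameter set: mature
18–25 nt, star arm 20–23 nt, ≤ 20 genomic loci per tag, precursor MFE ≤
−18 kcal/mol, mature–star gap ≤ 300 nt, ≥ 16 mature bases paired in the
duplex, duplex bulge ≤ 4 nt, asymmetry ≤ 4 nt, 20-nt flanks. Decisions on
points the parameter set leaves open:

* **Dicer geometry.** The star is read off the MFE structure as the duplex
  partner of the mature minus its final two bases, extended two bases at
  its own 3′ end — i.e. 2-nt 3′ overhangs on both arms. The
  20–23-nt "reference sequence length" bounds are applied to this star
  sequence.
* **Precursor windows.** For each genomic locus and each arm assumption
  (mature 5p or 3p) the predictor folds windows with star-side reach 60,
  120, 220 and finally 343 nt (300-nt max gap + star + flank), accepting
  the smallest extent that satisfies every criterion. Smallest-first
  scanning keeps a compact genuine hairpin from being masked by
  longer-range pairings that the simplified energy model makes
  artificially cheap.
* **Star evidence.** A sequenced star tag is not required; strict
  star-evidence mode is available (`require_star_tag`).
* **Copy-number cap.** The ≤ 20 limit is applied as loci per tag.
* A consensus across multiple external predictors is out of scope; the
  predictor instead exposes every acceptance diagnostic per candidate so
  that downstream filtering is transparent.

## Differential expression (diffexpr)

* The point probability is computed in log space (log-gamma terms); the
  lower tail by log-sum-exp over y′ ≤ y; the upper tail from the
  complement when the lower tail is < 0.5 and otherwise by direct forward
  summation with the pmf ratio recurrence until terms fall below 10⁻¹⁷ of
  the running sum — so both tails retain full relative precision. Agreement
  with an exact-rational (fractions) oracle is ≤ ~10⁻¹⁴ on the tested grid.
* The reported p is min(lower, upper), a one-sided convention without
  doubling (configurable to 2·min capped at 1). Under the null this makes
  the nominal rate at p < 0.01 about 2%, comfortably inside the 3%
  calibration bound used in the tests.
* The 1.5 fold-change gate is applied to |log₂FC| by default (the scale on
  which fold changes are defined and reported here, where values like ±17
  arise); applying it to the raw ratio instead is a config switch.
* Zeros are replaced by a 0.01-TPM pseudocount before the ratio — required
  for finite fold changes when a miRNA is entirely absent from one library.
* The TPM ≥ 10 retention filter keeps a miRNA expressed in *either*
  library; only miRNAs low in both are dropped.

## Target rules (target_prediction)

* Rule (b) fails only for runs of **more than two** adjacent
  mismatch/bulge positions; rule (c) tightens this to no adjacent
  mismatches within positions 2–12. G:U wobbles weigh 0.5 toward the
  scores but never count toward adjacency by default (a strictness flag
  flips this); rule (d) demands strict Watson–Crick at positions 10–11 —
  a wobble is half a mismatch and "no mismatches" excludes it.
* Alignment is positional and antiparallel. At most one single-nucleotide
  bulge is allowed, placed to minimise the score, so only length
  differences ≤ 1 are alignable; transcript scanning uses same-length
  windows only, where no bulge search is needed and results are exactly
  reproducible by an independent per-window checker.
* Duplex energies use the same stacked-pair table as the folding engine,
  restricted to intermolecular stacks (a stack step counts when adjacent
  miRNA positions both pair, keyed by the 5′-most pair). Rule (f)'s ratio
  therefore compares like with like and approaches 1 exactly as the site
  approaches the perfect complement.
* Overlapping passing windows of one miRNA on one transcript collapse to
  the best-scoring one (leftmost on ties).

## Validation reporting (validation_reporting)

* ΔΔCt: technical replicates are averaged first, ΔCt per biological
  replicate, ΔΔCt against the mean control ΔCt, relative expression
  2^−ΔΔCt (control mean ≡ 1 by construction; invariant to adding a
  constant to every Ct). The same internal standard is used for miRNAs and
  targets, as in the validated workflow this reproduces.
* Concordance uses only signs: miRNA direction from the sequencing log₂
  fold change, target direction from the qRT-PCR ratio vs 1. A target at
  exactly 1 counts as "same" (no change is not a reversal) and is logged.
  Statistical significance marks on individual rows are ignored — the
  bundled 77-row transcription of the published validation table
  partitions into 56/17/4 from the sign rule alone, which the tests pin.
* GO tallies count each gene once per distinct term per category; genes
  with no mapping are reported as unannotated. No enrichment statistics
  are computed.

## Synthetic data (synthetic_data)

The generator emulates the *structure* of a leaf sRNA experiment, not its
full biology:

* A single 60-kb chromosome (default) carries non-overlapping feature
  blocks separated by ≥ 15-nt random gaps: designed hairpins (known and
  novel), full-length ncRNA genes (rRNA 120, tRNA 75, snRNA 100,
  snoRNA 90 nt) of which one 20–24-nt fragment each becomes a read tag,
  two-exon/one-intron genes (120/90/120 nt) contributing exon- and
  intron-fragment tags, 150-nt repeats, plus unmappable tags. Every mapped
  truth tag is verified to occur exactly once genome-wide.
* **Hairpins** are near-perfect inverted repeats: mature 21–22 nt, loop
  8–12 nt, star = reverse complement of the mature carrying one G:U wobble
  — fully paired yet not an exact reverse complement, so the mature maps
  to a single locus. Acceptance under the default engine (with genomic
  flanks attached) is verified at build time; a failed draw is redrawn.
* **Target sites**: each gene's second exon carries the
  wobbled-complement site of one known miRNA (single G:U away from
  positions 10–11), giving the target stage true positives that pass all
  six rules with score 0.5 and MFE ratios ≈ 0.96–0.98.
* **Libraries**: feature proportions derive from baseline TPMs
  (log-uniform, 50–5000 for miRNA features, 20–2000 otherwise), the
  treatment library re-weighted by per-feature 2^log2FC; counts are one
  multinomial draw per library; reads are tag + adapter with
  substitution errors at 0.5% per base and 2% low-quality reads (Phred
  10) to exercise cleaning. Defaults: 100k reads per library, ±3 log₂FC
  on half the miRNA features.
* `weaken_hairpin` builds MFE-weakened mutant precursors for negative
  controls: the mature is preserved and the rest of the precursor is
  overwritten base-by-base with a homopolymer background (C, or A when
  the mature is G-rich enough to pair cytosines) until the precursor
  folds above −18 kcal/mol; the mutant is evaluated in isolation because
  in the full genome a neighbouring locus within the 300-nt reach can
  legitimately supply an alternative hairpin.

What passing on this data does *not* show: robustness to realistic
Illumina error profiles, PCR duplicates, imperfect (bulged) real
hairpins, isomiR heterogeneity, or cross-mapping in a genome with
repetitive miRNA families. Library-size normalisation also compresses
apparent fold changes when strong effects shift the composition — the
designed ±3 log₂FC features measure at about ±2.3 here — which is a real
property of proportion-based normalisation, not an artefact.

## Problem sizes

Defaults are sized so the whole suite and the acceptance script each run
in well under a minute on one CPU: 60-kb genome, 43 truth features, 20k-
to 100k-read libraries, 1000-feature calibration panels at 5×10⁵ depth,
200-sequence folding batteries. All sizes are plain parameters and scale
up without code changes.
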