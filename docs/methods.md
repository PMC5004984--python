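# Methods

This note documents the statistical procedures implemented in `hoxloci`,
the conventions and defaults they use, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
underlying analysis admitted more than one reasonable formalization.

## Coordinate model

All internal coordinates are 0-based half-open (`[start, end)`), the native
convention of BED and bedGraph; 1-based inclusive records (peak-caller
tables, GFF) are converted at the I/O boundary only.  "Overlap" between two
features means at least one shared base pair unless an operation states a
summit/point rule.  Book-ended intervals merge under union semantics, which
matters when contiguously tiling scan windows are collapsed into loci.
Peaks on chromosomes absent from the genome table are rejected with an
error rather than silently dropped, because silent loss corrupts the
denominators of every enrichment test downstream.  Strand is carried but
ignored by all overlap logic except motif scanning, since ChIP peaks are
unstranded.

## Peak QC

The empirical FDR of a ChIP peak set is the ratio of peak counts called at
the same score threshold in a mock immunoprecipitation (untagged strain)
and in the tagged ChIP sample, expressed as a percentage.  The ratio is
used raw, without pseudocounts: with zero mock peaks the FDR is exactly 0%,
and with zero ChIP peaks it is reported as undefined rather than a
division.

Replicate concordance is the Pearson correlation of two coverage-like
tracks averaged over fixed genomic bins (default 1 kb, configurable; the
bin size is a free parameter of this kind of analysis).  Bins without
coverage score 0 — read-coverage semantics — and a zero-variance binned
vector raises an explicit undefined-correlation error.

## Genomic annotation

Peaks are classified by the single base of their summit, which avoids the
multi-category ambiguity of interval-based classification and uses the best
available estimate of the binding position.  When the summit touches
features of several transcripts, the precedence

    promoter > 5'UTR > coding exon > 3'UTR > intron > intergenic

resolves the tie.  The promoter is a window around each transcription start
site, default 500 bp upstream / 100 bp downstream; promoter definitions
vary across the literature and the numbers produced depend on the
annotation version, so the window is configurable and the genome background
column is always computed with the identical rule applied per base —
internal consistency is what makes the two columns of the distribution
summary comparable.  UTRs are derived as exonic bases outside the CDS span;
transcripts without a CDS contribute only at the intron (gene-body) level.
The per-base category map is materialized as one byte per genome base and
cached per promoter definition; at the multi-megabase scale this package
targets, that is the simplest structure that makes summit lookup,
background composition and territory sampling all O(1)-per-base.

## Highly targeted genomic loci

One window of width *W* (default 100 kb) is anchored at every peak summit
(`[summit, summit + W)`, clipped at the chromosome end), so the window
family covers every window containing at least one peak.  Anchoring at the
summit rather than the interval start keeps the window rule consistent with
the summit-in-window membership count, which in turn prevents a wide peak
from being counted by two abutting windows.  Windows with at least *C*
summits (default 25) merge by union into loci, so reported loci are
non-overlapping by construction; per-locus statistics are recomputed on the
merged interval.

The background rate λ (peaks per window) defaults to the empirical mean
count over the peak-anchored window family itself and can be overridden by
a constant — the two obvious averaging populations (peak-anchored windows
vs all genomic windows) differ, and both modes are exposed.  Note that the
peak-anchored mean includes the anchor, so at uniform per-bp density *d*
its expectation is *d·W* + 1, and in a clustered genome it is dominated by
the clusters; for locus-level significance against a genome-wide
expectation, passing an explicit λ is the appropriate mode.  Enrichment of
a locus of length *L* holding *n* peaks is *n*/μ with μ = λ·*L*/*W*, and
significance is the Poisson upper tail *P*(X ≥ *n*), evaluated through the
regularized incomplete gamma function (scipy's survival function), which
agrees with term-wise log-space summation to at least six significant
digits across μ ≤ 50, *n* ≤ 200 (verified in the test-suite).

## Tile enrichment

Two binding rules are used, because two are needed: plain bound-tile
enrichment uses summit-in-tile (flank 0), while co-binding analyses use a
±250 bp window around the summit; both are parameters.  All significance is
the hypergeometric upper tail *P*(X ≥ *k*) — the standard enrichment
convention; at the scales involved the difference from *P*(X > *k*) is
negligible, but the choice is fixed.  The two-subset comparison (e.g.
tiles bound inside loci vs outside) treats A ∪ B as the population, all
active tiles as successes and A as the draw.  A tile overlapping summits of
both classes counts as in-locus — the classes must be exclusive and this is
the deterministic tie rule.  HOT-region stratification partitions tiles by
(bound × HOT) and compares the bound cell of each stratum against all tiles
of that stratum, mirroring the unstratified bound-vs-all comparison.  The
per-stage analysis reports one enrichment per developmental-stage activity
flag plus the mean per-stage fold; a stage with no active tiles yields fold
0 and p 1.

## Matched controls

Control regions are fixed-width (default: the median peak-interval width,
since no canonical control width exists) and matched on the summit-category
distribution — the same classifier as the annotation stage, so "genomic
distribution" means one thing throughout the package.  Target per-category
counts are the largest-remainder rounding of *n* × the peak fractions
(hence each category count is within 1 of its exact share and the total is
exactly *n*).  Region midpoints are drawn uniformly from the category's
genomic territory; candidates overlapping any peak interval or a previously
accepted control are rejected, with a cap of 10⁴ attempts per region before
erroring with the offending category named.  Sampling is fully determined
by the seed.

## Signal association

Signal tracks are stepwise-constant per chromosome; querying outside any
step yields NaN, the declared missing value.  Point extraction takes the
covering step's value at each summit.  Region extraction takes the
base-weighted median of step values over the region after subtracting an
exclusion set (e.g. HOT regions), with the even-count convention (mean of
the two central base values); base weighting is required because steps have
unequal widths.  Foreground/background comparison is the one-sided Wilcoxon
rank-sum test (foreground greater), using the tie-corrected normal
approximation — exact small-sample p-values are unnecessary at
genome-scale site-set sizes.  Missing values are excluded from the rank
test (it needs real values) but counted in the denominator of
threshold-sweep curves, whose fractions must remain comparable across site
sets of different sizes; the curves report the fraction of sites strictly
above each threshold and are ranked by trapezoidal area, ties broken by
name for determinism.

## Motif enrichment

IUPAC motifs are scanned on both strands of the forward sequence with
overlapping occurrences counted individually (a fixed rule; GCCATT cannot
self-overlap but degenerate motifs can) and palindromic forward/reverse
hits at the same offset deduplicated.  `N` bases in the sequence never
match.  Enrichment between region sets is the ratio of per-bp hit
densities, with an upper-tail binomial p-value for the foreground count at
the background rate — the simplest defensible statistic for a
density-ratio question; with zero background hits the fold is reported as
undefined and the p-value is computed against the pseudocount rate
(bg_hits + 1)/bg_bp.  The plug-in background rate makes the test mildly
anti-conservative by a factor √(1 + fg_bp/bg_bp) in the rejection
threshold; with background footprints several times the foreground this
stays close to nominal (quantified in the test-suite).

## Synthetic data

The generator draws every output from a single seeded RNG in fixed order,
so a scenario plus seed determines every byte of the dataset.  The default
conditions mirror the study-like structure each stage assumes, at a
desk-scale 22-Mb four-chromosome genome:

* **Peaks** — 550 background peaks placed uniformly plus 12 clusters of 30
  peaks over 60-kb spans (clusters separated by ≥ 300 kb so merged loci
  never bridge two clusters).  Scores are score_low + Exponential, scaled
  so that 28% of peaks exceed the strong threshold of 5 (the ratio of
  strong to total peaks in the motivating dataset, 1479/5282).  Background
  density is ~2.5 peaks per 100 kb, below the 3-per-window scale, so a
  spurious 25-peak window away from a planted cluster is essentially
  impossible — which is what makes planted-recovery a sharp test.
* **Mock peaks** — an independent uniform set of size round(0.001 ×
  n_peaks), planting a 0.1% FDR.
* **Tiles** — 2000 non-overlapping 2-kb tiles on a regular pitch.  Activity
  is conditional-Bernoulli on binding: P(active | bound) = 0.774,
  P(active | unbound) = 0.45, pooling to ≈ 46–47% overall — the minimal
  two-parameter structure that produces the bound-tile enrichment signal.
  Per-stage flags are i.i.d. with per-stage probability 1 − (1 − p)^(1/k)
  so their OR equals the overall activity probability exactly.  An optional
  override makes HOT-overlapping tiles active at a fixed rate regardless of
  binding, for stratification tests.
* **Signal** — Gaussian 100-bp steps (mean 0, sd 1) with a +1.0 log2 shift
  planted at a random half of peak summits ± 500 bp.  A separate helper
  generates two replicate-like tracks sharing a common component, whose
  binned Pearson correlation is analytically v_shared/(v_shared + v_noise)
  (0.862 at the defaults — the high-concordance regime of good replicates).
* **Sequence** — i.i.d. uniform ACGT, which already carries the motif at
  rate 2·4⁻⁶ per bp; additional copies are planted to reach a 0.002/bp
  background density, and summit ± 250 bp windows (merged, so the rate is
  uniform across foreground bases) are topped up to 2.3 × background.
* **Gene models** — fixed-structure 10-kb genes on a 25-kb pitch with
  alternating strand, giving every category non-trivial territory.

What the generator does **not** emulate: read-level noise and mappability,
peak-width and score correlations, GC composition, clustered gene
architecture, correlated tile activity between neighbours, and the real
genome's category proportions.  Tests passing on this synthetic structure
therefore validate the *statistical machinery* — counting rules, tails,
matching, recovery — not agreement with any real-data figure; the
quantities that require the deposited ChIP-seq data (absolute peak counts,
the real genomic distribution, real Pc/Pho signal bounds) are explicitly
out of reach at desk scale and are covered only by these analogues.

## Numerical and degenerate-input conventions

Distribution tails (Poisson, hypergeometric, binomial, rank-sum) are
computed by scipy's survival functions, which are log-space/regularized
implementations; the test-suite pins each against an independent
enumeration or log-space-summation oracle to ≥ 6 significant digits.
Upper tails at k = 0 (or n = 0) are exactly 1.  Infeasible contingency
counts, empty subsets, empty grids, all-missing samples, zero-variance
binned tracks, unplaceable control quotas and unpackable cluster scenarios
all raise typed validation errors rather than returning sentinel values.

## Problem sizes used in validation

The validation runs use the generator's default 22-Mb genome with 910
peaks and 2000 tiles, 20 generator draws for cluster recovery, 10 for
motif-fold recovery, 300 matched controls, and 1000–2000 replicates for the
calibration checks — sizes at which every binomial standard error used in
an assertion is small relative to the effect being checked.
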