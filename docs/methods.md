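# Methods

`evoreg` re-implements, as a tested pipeline over synthetic data with planted
ground truths, the computational chain that links human-evolved noncoding
elements to putative target genes and characterises those genes: chromatin
contact significance against a matched-background Weibull null, matched
random-region enrichment statistics, developmental and cell-type expression
profiling, cross-species expression contrasts, and covariate-adjusted
gene-set enrichment.

## Element classification

Coordinates are 0-based half-open throughout (BED native; GTF converted on
read).  An element is *coding* when it overlaps an exon (the coding portion,
i.e. exon minus UTRs), a 5'/3' UTR, the 1 kb window upstream of a TSS, or
the 1 kb window downstream of a TES; otherwise it is intronic or intergenic
(*noncoding*).  When an element overlaps several feature types the
highest-precedence category wins (exon > utr5 > utr3 > promoter1kb >
downstream1kb > intron > intergenic) — precedence is a design choice; the
coding-first ordering maximises direct assignments, matching the two-branch
assignment design (coding elements are assigned to their host genes
directly, noncoding elements through chromatin contacts).  An element
overlapping features of several genes owns all of them; dropping ownership
information would only lose assignments.  Two distinct promoter widths are
used deliberately: 1 kb for the coding/noncoding classification, 2 kb
upstream of the TSS for interaction target mapping.

## Matched backgrounds

Two null constructions, both by rejection sampling with a per-element seeded
substream (so editing the element list never perturbs other elements'
draws):

* **GC/length-matched (contact null).**  For each element, `reps` (default
  40) same-chromosome regions of identical length with GC content within 5
  percentage points (GC computed case-insensitively, ambiguous bases
  excluded from numerator and denominator).  At the default 2,737 elements
  this draws 2,737 x 40 = 109,480 regions; exact duplicates are removed
  after pooling and both counts are reported.  A per-chromosome prefix-sum
  GC index makes each candidate an O(1) check; the full construction takes
  a couple of seconds.  `max_attempts` = 10,000 candidates per missing
  draw; on exhaustion the nearest-GC candidates are used with a warning.
* **Size/conservation-matched (permutation null).**  Genome-wide control
  sets with identical length and mean conservation score within 0.05 of the
  source (the tolerance is a design choice; matching "the same scores"
  exactly is measure-zero).  Placement is genome-wide rather than
  same-chromosome — with only two synthetic chromosomes a same-chromosome
  constraint would be vacuous.

Conserved regions are maximal runs of bases with score strictly greater
than 0.40 and length strictly greater than 20 bp, computed on a run-length
encoded track (gaps read as score 0).

## Annotation enrichment

Overlap is >= 1 bp everywhere.  Three estimators:

* **Binomial (region-based).**  p = merged annotation span / genome length,
  n = number of elements, s = elements overlapping; significance is the
  upper tail Pr(k >= s | n, p) and fold enrichment (s/n)/p.  Because p
  ignores element width, wide elements inflate the fold even for neutral
  annotations — visible in `analysis/03` for the enhancer-sized classes
  against the neutral annotation.  This is a property of the estimator, and
  the reason the conservation-controlled Fisher test exists.
* **Fisher with conserved background.**  2x2 table of elements vs conserved
  regions (overlap vs not), two-sided exact p, sample OR = AD/BC, 95% CI by
  the Woolf log-OR normal approximation with Haldane +0.5 when a cell is
  zero (flagged).  Any zero margin raises a degenerate-table error naming
  the margin.
* **Permutation OR.**  The same table is rebuilt substituting each matched
  control set for the elements; the empirical p is
  (1 + #{null OR >= observed}) / (n_valid + 1), degenerate null tables
  skipped and counted.

## Contact significance (the core method)

Contacts are consumed as given (raw or normalised; no balancing) in 10 kb
bins, upper-triangular sparse storage per chromosome.  Each noncoding
element maps to every bin it intersects; each anchor's locus profile holds
the 99 bins on either side (distances 10-990 kb, strictly inside the 1 Mb
flank, anchor excluded) — 198 candidate bins per interior locus, fewer at
chromosome ends (clipped).

The null is a two-parameter Weibull fitted by maximum likelihood
(`scipy.stats.weibull_min`, location fixed at 0) to the strictly positive
background contacts of the matched controls, separately for every
(chromosome, distance) cell.  Zeros are excluded from the fit — the Weibull
support is positive — and an observed zero contact gets p = 1; the per-cell
zero fraction is recorded.  Cells with fewer than `min_obs` = 30 positive
values are pooled with the nearest distances on the same chromosome
(pooled flag set); a cell empty after pooling is an error.  Very large
cells may be subsampled (`max_obs`) for speed; the default analyses fit on
roughly 4,000 observations per cell.

Significance of an observed contact x > 0 at (chromosome, distance) is the
Weibull survival probability p = exp(-(x/lambda)^kappa).  All candidate
p-values of all elements form one family corrected by Benjamini-Hochberg;
a call is significant when q < 0.01.  (A boundary convention: FDR >= 1
selects everything, since q is capped at 1 and the strict inequality would
silently drop q = 1 cells.)  "Adjusted to the number of elements and bins"
is implemented as this single BH family — a Bonferroni-then-FDR double
correction is not a coherent procedure.

Target assignment has three modes matching how each element class is
handled: `fetal_full` (coding elements to host genes, noncoding by
interaction), `promoter_split` (2 kb promoter overlap decides direct vs
interaction), and `adult_promoter_only` (promoter-overlapping elements
dropped; interaction only).  Interaction evidence always requires a
significant candidate bin intersecting a 2 kb promoter; multi-bin elements
pool calls over their anchors, collapsing duplicate (element, gene) pairs
to the minimum q.  Assignment is order-stable (sorted output).

## Synthetic data and its planted truths

Everything is a pure function of (config, seed); per-stage and per-element
RNG substreams keep outputs stable under local edits.  Defaults are the
study conditions: 2 chromosomes x 20 Mb, element counts 2,737 / 2,104 /
1,518 / 1,779, 700 genes, 10 kb bins.

* **Genome.**  Per-kilobase GC probability follows a slow sinusoidal drift
  plus noise, clipped to [0.25, 0.65], so GC matching is non-trivial.
* **Conservation.**  ~4,000 islands (200-800 bp, scores 0.55-0.95) over a
  low-score background (< 0.25), covering ~5% of the genome.  The
  sequence-conserved element class is placed on islands; a fraction of
  islands carries an annotation peak such that the element-vs-conserved
  OR equals the planted value (default 3.0) in expectation.  A neutral
  annotation is placed independently of everything for null calibration.
* **Contacts.**  Background contact at bin offset o is Weibull(kappa,
  lambda_0 o^-alpha) with kappa = 4, lambda_0 = 10, alpha = 1, zeroed with
  probability 0.10; 100 planted loops multiply the scale (hence the mean)
  by 3 at (intergenic element bin, gene promoter bin) pairs 50-990 kb
  apart.  kappa = 4 (CV ~ 0.28) represents distance-normalised contact
  spread concentrated enough that a 3x loop is detectable at desk scale;
  it also makes the caller's parametric family well-specified, separating
  correctness from robustness.  The misspecification mode swaps the
  background for a log-normal with the same mean (sigma = 0.35):
  `analysis/04` reports that the Weibull null then keeps its nominal 5%
  type-I rate at alpha = 0.05 but loses FDR control in the extreme tail
  (observed FDP ~0.9 at q < 0.01) — the survival extrapolation, not the
  bulk fit, is what breaks.  This is reported, not gated.
* **Expression.**  4,125 orthologs share logistic-ramp trajectories across
  the two species' developmental event-score grids; the macaque grid
  mirrors the human grid except at the three matched stages (0.46↔0.48,
  0.54↔0.51, 0.76↔0.77), which is what event scores are for.  Every gene
  carries a minimum ramp amplitude (2.0 on the log2 scale) and stage noise
  has SD 0.2, so stage Z-scores reflect trajectory shape rather than
  noise; with these defaults the standard error of a 500-gene planted-set
  mean ΔZ is ~0.01, comfortably inside the ±0.03 recovery check.  The
  planted stage-shift set receives, at the matched human stages, an
  additive shift of 0.128 times the gene's across-stage SD (computed
  pre-shift), mean-compensated at the remaining stages so the row mean is
  unchanged and the post-normalisation ΔZ equals 0.128 up to a <1% SD
  inflation.  Breakpoint differences are N(0, 0.1) with a -0.05 planted
  shift (negative = earlier in human); dN/dS is log-normal (background
  median 0.5, planted purifying set 0.2, sigma 0.6); one co-expression
  module is constructed to overlap a planted set at OR ~ 7; bulk samples
  (12 stages x 5) carry a +1 SD prenatal shift for a planted set; one cell
  cluster gets a 5x marker fold.
* **What the generator does not emulate:** read-level noise, Hi-C
  artefacts (fragment bias, balancing), batch structure, realistic gene
  architecture or linkage between element classes.  Passing tests show the
  estimators recover the statistical structure they assume; they do not
  certify behaviour under real-data artefacts outside that structure (the
  misspecification report is the one probe in that direction).

One synthetic-design consequence worth naming: planted loop targets are
drawn 50-990 kb away while genes are spaced ~57 kb, so the nearest gene is
essentially never the looped target and the nearest-gene concordance
reported by `analysis/04` is ~0 — the synthetic design makes the
nearest-gene heuristic maximally wrong rather than partially wrong.

## Expression and cross-species statistics

Bulk matrices are log2(x+1)-transformed and centred per sample with a +1
offset (column means exactly 1 afterwards); single cells are centred per
cell without the offset — the two conventions are intentionally different
and implemented exactly.  Gene-set trajectories are per-sample means over
the set; class comparisons within a developmental period use one-way ANOVA
with Tukey post-hoc contrasts, FDR-corrected across all contrasts.

Stage Z-scores standardise each gene across stages (SD with n-1); constant
genes are excluded and reported.  ΔZ(gene, pair) = Z_human at the human
stage minus Z_macaque at the matched macaque stage; the gene-set test is a
two-sided Welch t-test of pooled set ΔZ against pooled non-set ΔZ over the
matched pairs (a two-sample formulation; comparing against the non-set
genes rather than against zero).  Breakpoint shifts and log2(dN/dS)
contrasts use two-sided Wilcoxon rank-sum tests; module enrichment is the
covariate-free 2x2 per module over an explicit background with BH across
modules.

## Gene-set enrichment

Logistic regression of the element-associated flag on curated-set
membership over an explicitly declared background (never inferred), with
the coding-sequence-length covariate log1p-transformed for stability.
Without the covariate the fitted OR equals the sample AD/BC exactly, i.e.
Fisher's exact test; complete separation is detected before fitting and
returned as a flagged infinite/zero OR with a warning rather than a silent
number.  The classes x sets grid is BH-corrected over all tested cells
with the family size recorded ("multiple correction" left unnamed in the
source description; BH chosen and stamped in the output).

## Problem sizes and determinism

Default analyses run on the 2 x 20 Mb study: null fitting on 2,000 control
profiles (~4,000 positive observations per distance cell), 200 permutation
sets for the empirical OR, the 20-seed annotation-OR replication on reduced
4 Mb genomes (1,000 elements), and the full 59,400-test null calibration.
The end-to-end demo completes in about a minute on one CPU and is
byte-identical under a fixed seed; reruns with an unchanged config reuse
cached outputs keyed by a config hash.

## Known limitations

* The Weibull tail is an extrapolation: heavy-tailed backgrounds inflate
  the extreme-tail false discovery rate even when the bulk fit looks
  calibrated (see the misspecification report).
* One representative transcript per gene (5'-most TSS); alternative
  promoters are out of scope.
* Breakpoint estimation, module derivation, dN/dS computation and pLI
  scores are consumed as input tables; only the downstream contrasts are
  implemented.
* Whether 1 kb-promoter coding elements should also receive
  interaction-based targets is undecidable from the method description;
  here the coding branch wins and such elements get direct assignments
  only (`fetal_full`).
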