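# evoreg

Target-gene assignment and enrichment statistics for human-evolved
regulatory elements.

Most of the genomic elements that changed on the human lineage — sequence-
accelerated regions and regions that gained or lost enhancer activity
(H3K27ac) relative to other primates — are noncoding, so knowing *which
gene* each element regulates is the central problem.  Assigning each
element to its nearest gene is known to be unreliable; this package instead
assigns elements to genes through chromatin-contact (Hi-C-style) profiles,
and provides the statistical machinery around that assignment:

* **Interaction calling.**  Each noncoding element is mapped to its 10 kb
  bin and the contacts to the 198 candidate bins within its 1 Mb flank are
  scored against a background null: a two-parameter Weibull fitted per
  (chromosome, distance) to the contact profiles of GC/length-matched
  random regions (40 per element).  Significance of a contact x is the
  survival probability p = exp(−(x/λ)^κ); Benjamini–Hochberg over the full
  elements × bins family at FDR < 0.01; significant bins overlapping a 2 kb
  promoter yield element → gene assignments.  Coding elements are assigned
  to their host genes directly.
* **Annotation enrichment** of element sets in regulatory peaks: a
  region-based binomial tail Pr(k ≥ s | n, p), a Fisher's exact test
  against conserved-region backgrounds (OR = AD/BC with 95% CI), and an
  empirical OR null over size/conservation-matched permutation sets.
* **Expression profiling** with the two centring conventions (per-sample
  +1 for bulk developmental data, per-cell for single cells), ANOVA/Tukey
  trajectory comparisons, and cell-type profiles.
* **Cross-species statistics:** per-gene stage Z-scores, the human-minus-
  macaque Δ expression Z-score at developmental event-score-matched stages,
  breakpoint-shift and log2(dN/dS) rank tests, and co-expression-module
  enrichment.
* **Gene-set enrichment** by logistic regression with a coding-sequence-
  length covariate over explicit background gene lists, BH-corrected across
  the classes × sets grid.

Because the real fetal/adult contact maps and primate atlases are
controlled-access, the package ships a first-class synthetic-data module
(`evoreg.simulate`) generating every input — genome with drifting GC,
conservation islands, gene models, element classes, contact maps with
distance decay, two-species expression atlases — with *planted* truths
(loops, odds ratios, expression shifts) so that every stage is testable by
parameter recovery.

## Worked example

```python
from evoreg import SynthConfig, make_genome_and_annotation, make_contact_map
from evoreg.backgrounds import sample_gc_length_matched
from evoreg.hic import (fit_null, profiles_for_intervals,
                        interaction_pvalues, correct_and_call, assign_targets)
import numpy as np, pandas as pd

cfg = SynthConfig(seed=0)                      # 2 x 20 Mb, 2,737 conserved elements
study = make_genome_and_annotation(cfg)
contacts, loops = make_contact_map(cfg, study) # 100 planted loops at 3x decay mean

har = study.elements["HAR"]
matched = sample_gc_length_matched(har, study.genome, reps=40, seed=0)
print(matched.total_drawn)                     # 109480  (2737 x 40 draws)

rng = np.random.default_rng(0)
ctrl = matched.pooled.subset(rng.choice(len(matched.pooled), 2000, replace=False))
null = fit_null([p for _, p in profiles_for_intervals(contacts, ctrl)],
                max_obs=5000, rng=rng)

frames = [interaction_pvalues(p, null, name)
          for name, p in profiles_for_intervals(contacts, har)]
calls = correct_and_call(pd.concat(frames, ignore_index=True), fdr=0.01)
targets = assign_targets(calls, har, study.genes, mode="fetal_full")
print(int(calls.significant.sum()), targets.gene.nunique())   # 232 204
```

232 element–bin contacts pass FDR < 0.01 out of a family of 529,086 tests
(2,737 elements × ≤198 candidate bins); mapping significant bins onto 2 kb
promoters (plus direct assignment of coding elements) links the elements to
204 distinct genes.  Of the 100 planted loops, 86 are recovered, with an
observed false-discovery proportion of about 1%.

The numbered scripts under `analysis/` run each stage as a standalone
narrative (simulation, classification, enrichment, interaction calling with
a null-misspecification report, expression profiles, cross-species
statistics, gene-set grid) and write their tables under `results/`.  The
end-to-end pipeline is also available as `evoreg run-all` (or
`evoreg.pipeline.run_all`), which completes in about a minute and is
byte-identical under a fixed seed.

From `analysis/06_cross_species.py` (seed 0; planted values in the last
column):

```
              statistic     value             p  planted
      delta_z_set_shift  0.122691  2.512123e-41    0.128
breakpoint_median_shift -0.057159  1.475452e-11   -0.050
   dnds_set_median_log2 -2.335015 1.069035e-129      NaN
          module_top_or  7.144284  4.678399e-06    7.000
```

The planted +0.128 stage-matched expression shift, the −0.05 breakpoint
shift (earlier developmental change in human), the purifying-selection
signal and the OR-7 module are all recovered.

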