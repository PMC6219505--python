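# oligoprog

Computational assessment of risk and progression in oligodendroglioma
— a reusable, tested implementation of a multi-stage analysis for
molecularly defined (*IDH*-mutant, 1p/19q co-deleted) oligodendroglioma
cohorts, exercisable end-to-end on synthetic cohorts with known planted
structure.

The package is aimed at computational biologists and biostatisticians
who want to apply (or scrutinise) this kind of multi-platform risk
analysis without access to the original patient data: every stage runs
on simulated inputs whose ground truth is known, so each method's
behaviour can be verified quantitatively.

## What it computes

**Neural-network Cox risk model** (`oligoprog.survnet`).  A small
feed-forward network maps molecular/clinical features *x* to a scalar
risk *r(x)*, trained by minimising the negative Cox partial
log-likelihood (Breslow ties)

    L = − Σ_{i: event} [ r(x_i) − log Σ_{j: t_j ≥ t_i} exp(r(x_j)) ]

with RMSprop (lr 1e-3, 25 epochs, dropout 10%; three hidden layers of
100 neurons for genetic-protein inputs or 500 for transcriptional
inputs).  Accuracy is Harrell's concordance index under Monte-Carlo
cross-validation (20 random 80/20 splits), and each feature's
prognostic significance is the mean derivative ∂r/∂x_f across samples,
aggregated by median over the CV replicate models — positive scores
mean the feature raises predicted risk.

**Preranked GSEA** (`oligoprog.enrichment`).  Transcript-level
prognostic scores are ranked and each curated pathway's enrichment
score is the maximal deviation of the weighted running sum
(hits weighted by |score|, uniform miss decrement).  Significance comes
from a gene-label permutation null; NES divides ES by the mean |null ES|
of matching sign.  Pathways split into poor-prognosis (ES > 0) and
good-prognosis (ES < 0) tables.

**Cellular density from nuclei point patterns**
(`oligoprog.histodensity`).  Nearest-neighbor spacings (KD-tree,
exactly equal to exhaustive search) of nuclei in a planar field follow,
under a homogeneous Poisson process of intensity λ (nuclei/µm²), the
law *f(r) = 2πλr·exp(−πλr²)*.  A two-component mixture of this law is
deconvolved by EM (closed-form M-step) into λ_tumor and λ_normal; the
cohort median of λ_tumor defines "less dense" vs "more dense" tumors.

**Association and survival statistics** (`oligoprog.stats`).
Arm-level copy-number fractions dichotomized at |0.10|; alterations
under 5% frequency dropped; 2×2 association testing with the rule
*χ² unless any expected cell count < 5, then Fisher's exact test*
(two-sided, probability-mass rule); Wilcoxon rank-sum, Pearson,
Kaplan–Meier/log-rank and classical Cox PH fits; MKI67 "high"
expression calibrated by inverting the labeling-index regression at
15% (the ≥700 cutoff).

**Synthetic cohorts** (`oligoprog.synthetic`) generate all the inputs:
binary alterations with planted log-hazards, right-censored exponential
survival, a contrast-enhancement label logistically coupled to the
alterations, expression matrices with a planted prognostic pathway,
and two-intensity Poisson nuclei fields.

## Worked example

```
$ oligoprog simulate --out cohort --seed 1
cohort written to cohort
$ oligoprog train --features cohort/features.tsv --outcomes cohort/clinical.tsv \
      --splits 5 --seed 1 --out survout
median c-index 0.564 (SD 0.041)
$ oligoprog assoc --features cohort/features.tsv --clinical cohort/clinical.tsv --label ce
feature  pos_label_pos  pos_label_neg  neg_label_pos  neg_label_neg         test        p
  ALT15             66              9             56             38   chi_square 0.000042
  ALT03             16              1            106             46 fisher_exact 0.042976
  ALT06             32              6             90             41   chi_square 0.060317
```

The simulated 169-sample cohort plants five log-hazard effects among
20 alterations and couples the contrast-enhancement (CE) label to the
three risk alterations (ALT01/ALT06/ALT15).  The association screen
recovers ALT15 as the strongest CE association and chooses χ² or
Fisher per the expected-count rule; the modest c-index (0.56 at n=169
with weak planted effects) illustrates how cohort size and effect
strength bound discrimination.  On the stronger planted-signal
benchmark cohort (`synthetic.benchmark_cohort_config()`, n=400, five
hazard ratios of 4.5–12) the same 20-split cross-validation reaches a
median c-index of 0.79 — the regime the genetic-protein model shows on
real cohorts.  `oligoprog run-all --out demo --seed 1` runs every
stage (risk model, ranking, GSEA, density, associations, survival) and
writes a JSON report.

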