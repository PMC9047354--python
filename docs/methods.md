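# Methods

This note documents the models, estimators and design choices behind
`methfert`, and what the synthetic-data generator does and does not emulate.

## Phenotype: corrected non-return rate

Each AI record carries a 0/1 score: 0 if the mated cow was re-inseminated
within 56 days, 1 otherwise. The bull phenotype is the BLUP of the bull
random effect in a **linear** model on these scores — deliberately linear,
not logistic, because that is how national sire-fertility evaluations score
non-return and it keeps the estimate on the outcome scale. The mixed-model
equations add the ridge term λ_b = (1 − r_b)/r_b to the bull block, with
r_b = σ²_bull/σ²_phenotypic = 0.01 by default. Fixed effects (herd-year,
month-year, parity, calving-to-insemination interval class, weekday,
technician, semen category) are one-hot encoded with the first level as
reference; an intercept is always included. A cow random effect is available
but off by default: at desk scale almost every cow appears once, so its
variance is absorbed by the residual; when other random terms are disabled
their variance is folded into the residual, which makes λ_b a documented
approximation rather than the full multi-component system.

Consequences used as invariants: bull effects sum to exactly zero whenever
every bull has records (the intercept equation forces λ·Σu = 0); each bull's
equation gives the shrinkage identity u_b = (n_b/(n_b+λ))(ȳ_b − μ̂) when only
the intercept is fixed; and as r_b → 1 the estimates converge to deviations
of bull means from their unweighted average.

The fertile/subfertile cut is **not** a modelled quantity: it is exposed as
a user rule (quantile of the estimate distribution, or a fixed threshold)
because no principled value exists; ties under the quantile rule break by
bull id so the assignment is reproducible.

## Site filtering

A cell (site × sample) is *CpG10* when its total read count is ≥ 10
(inclusive). The testing background applies, in order for reporting
purposes (the surviving set is order-independent):

1. chromosome allow-list (stand-in for dropping unplaced scaffolds that
   lack variant information);
2. variant mask — a CpG is removed when a masked position hits its C
   position *or* the G at pos+1, since a polymorphism on either strand
   corrupts the bisulfite readout;
3. group presence — CpG10 in at least ⌈min(n₁,n₂)/2⌉ samples of **both**
   classes ("auto"; 57/43 gives 22). Ceiling is used because it reproduces
   the canonical 22-of-43 threshold.

Global summaries (per-sample mean methylation; hypomethylated < 20%,
intermediate [20%, 80%] closed, hypermethylated > 80%) are computed over
CpG10 cells only; a sample with none is flagged undefined rather than
reported as zero.

## Differential methylation

Both tests consume only CpG10 cells and report the coverage-weighted class
percentages 100·Σm/Σn and their difference Δ = subfertile − fertile.

**Pooled LR test.** Binomial regression of (methylated, unmethylated) on
class membership has the pooled class counts as sufficient statistics, so
the LR statistic is computed in closed form from the two pooled proportions
against the common-proportion null, with p from χ²(1). Identical pooled
proportions short-circuit to p = 1.

**Dispersion-aware Wald test.** Per class, the beta-binomial overdispersion
φ is estimated by the method of moments from the chi-square of per-sample
proportions around the pooled proportion,
φ̂ = max(0, (X² − (k−1)) / Σ(nᵢ−1)), and the variance of the pooled
proportion is p(1−p)·Σ nᵢ(1+(nᵢ−1)φ̂)/N². The test statistic is the
difference of class proportions over the root of the summed variances. The
pooled proportion is clamped to [0.5/N, 1−0.5/N] inside the variance so it
never degenerates exactly at 0 or 1. Sites with fewer than two usable
samples in either class are skipped and counted, never imputed. No
shrinkage of dispersions across sites is attempted — the smoothing used by
dispersion-aware DML packages is intentionally out of scope, which makes
this test conservative site by site.

**Multiplicity.** Benjamini–Hochberg step-up replaces the bespoke SLIM and
IHW procedures of the original tool chain; the threshold semantics are kept
(q < 0.01 pooled, q < 0.1 dispersion). This is a deliberate, documented
substitution: BH is the conservative standard and the two bespoke methods
are publications of their own.

**Calling.** DMC ⇔ q below threshold AND |Δ| ≥ 10 points; both criteria are
required, so a massively significant 5-point shift is not a DMC. The
10-point rule is evaluated on the coverage-weighted (pooled) percentages.
DMRs are maximal runs of ≥ 3 DMCs with consecutive inter-DMC gaps ≤ 100 bp
(inclusive); the span is first-to-last member. Regions are not required to
be direction-consistent; direction is the sign of the mean member Δ and
mixed runs are flagged. Per-sample DMR means average member CpG10
percentages unweighted; samples covering no member are missing.

## Annotation

Windows: TSS ±100 bp; promoter −2000..−100 bp upstream of the TSS on the
annotated strand; TTS ±100 bp; upstream/downstream and gene assignment
10 kb; shore ≤ 2 kb from a CGI; shelf the next 2 kb. Sites take exactly one
gene-feature label by precedence (TSS > promoter > TTS > 5′UTR > 3′UTR >
exon > intron > upstream > downstream > intergenic) and one CGI-context
label by point membership (CGI > shore > shelf > open sea). Regions use
any-overlap for gene features but require ≥ 75% of their length inside the
island (resp. shore band, shelf band) for a CGI context — a region mostly
but not three-quarters inside an island is open sea, by construction of the
threshold. The 75% rule applies to regions only; a 1-bp region degenerates
to point membership and agrees with the site annotator. Repeat overlap
counts whatever its extent. Unstranded genes are treated as plus strand
with a warning. Enrichment compares category proportions among DMCs against
the background with two-sided Fisher tests, separately for hyper- and
hypomethylated subsets when requested.

## Classification

Features are methylation percentages at DMCs (samples × sites); a cell is
missing when the sample lacks CpG10 coverage there. Policies:
`complete_only` keeps zero-missing features; `impute_lt_10pct` keeps
features with < 10% missing and fills them by iterative low-rank SVD
completion (missing cells start at column means; the reconstruction rank is
chosen by internal cross-validation on 10% of held-out observed cells;
seed-fixed). The low-rank imputer is this package's own implementation of
PCA-style matrix completion.

The classifier is a 500-tree Random Forest with ⌊√p⌋ candidate features per
split. **The positive class is fertile** — sensitivity is the true-positive
rate on fertile bulls, specificity the true-negative rate on subfertile
bulls — which inverts the usual disease convention and is stated wherever
metrics are reported. Predicted class = fertile iff its probability ≥ 0.5;
ROC and AUC (trapezoidal) come from the probabilities, not votes.

Evaluation designs: (1) stratified resampling — per class, round-half-up of
2/3 of the class goes to training (57/43 → 38+29 = 67 train, 33 test),
repeated 50 times with means and SDs of the four indicators (iteration i
derives its child seed from the run seed and the iteration index, so one
iteration reproduces a single split/train/evaluate run); (2) group split —
train on one collection center, test on the other, both directions, no
resampling; (3) independent — train on the whole main cohort, evaluate once
on an independent cohort sharing the DMC columns. Misclassification
structure is characterized by PCA on centered (unscaled — the features share
units; scaling is a toggle) percentages with actual/predicted quadrant tags
FF/FS/SF/SS.

Auxiliary statistics follow the cohort's test-selection rule: two-sample
t-test only when both groups have more than 15 values, pass Shapiro–Wilk
normality and the F-test for equal variances (all at 0.05); otherwise the
Wilcoxon rank-sum test, with the test used always reported. Hierarchical
clustering uses Ward linkage on 1 − Pearson correlation between sample
profiles. Batch correction takes OLS residuals on batch indicators
(equivalently per-batch centering), so per-batch residual means are exactly
zero and a single-sample batch gets residual zero.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions. Per sample s and site j:

* coverage n_sj ~ NegBin(mean 23, Var = μ + φμ² with φ = 0.05), zeroed with
  probability 0.05 (missing);
* methylated reads m_sj ~ Binomial(n_sj, p_sj) with
  logit(p_sj) = logit(baseline_j) + a_s + δ_j·1[s subfertile];
* baseline_j from a two-mode mixture (5% / 85%, weight 0.5 on the low mode)
  with the low mode concentrated inside CpG islands — giving ≈ 46% grand
  mean methylation and ≈ half of sites below 20%;
* a_s ~ Normal(0, indiv_sd²) on the logit scale captures inter-individual
  variability shared across sites. The real-data magnitude of this variance
  is unknown; the default 0.5 is a visible-but-moderate choice and tests
  sweep it (0 for null calibration, 1.5 for the overdispersion contrast)
  rather than asserting any particular value;
* planted DMCs (1% of sites by default, 21% of them hypomethylated in the
  subfertile class) shift the subfertile probability by effect_delta
  percentage points (default 15), realized as a per-site logit offset.
  Planting is baseline-aware: hyper effects need headroom above the
  baseline and hypo effects room below, so every planted effect is fully
  realizable; if the baseline leaves no feasible site the shortfall is
  logged. Hypo DMCs are placed in spatial clusters no wider than 1000 bp,
  emulating discrete domains of methylation loss; hyper DMCs scatter;
* genotype-confounded sites (1%) ignore the model and emit ≈ 100/50/0%
  methylation by a per-sample dosage 0/1/2; an optional allele-frequency
  shift between classes reproduces the confounding that a pooled test
  mistakes for differential methylation;
* logit-normal individual effects composed with binomial draws stand in for
  an explicit beta-binomial: the two are close in distribution and the
  logit-scale formulation composes class, individual and genotype effects
  additively with no extra parameters.

AI records are generated with a **linear probability model**
(base rate 0.68 + bull effect + fixed effects, clipped), matching the
evaluation model's linearity; fixed-effect levels are assigned uniformly per
record.

What the generator does *not* emulate: read-level data (fastq), bisulfite
conversion errors, multimapping of repeat-derived reads, linkage between
neighbouring CpGs beyond planted clusters, and realistic genome geometry
(two ~1 Mb toy chromosomes). Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated statistical
model, not performance on real RRBS libraries.

One global seed fans out to per-stage child seeds via a stable hash of
(seed, stage name), so any stage re-run in isolation reproduces its
full-pipeline result, and all child seeds stay below 2³¹.

## Problem sizes and numerics

Simulation suites use 5,000–12,000 sites and 20–25 samples per class —
enough that the empirical type-I error of the pooled test at α = 0.01 is
estimated to ±0.003 and planted-effect recovery is essentially
deterministic — and classifier checks use 50 resampling iterations of a
500-tree forest on ~40 samples, with label-permutation nulls at reduced
iteration counts. Binomial log-likelihoods clip probabilities at 1e−12;
the LR statistic is floored at 0; BH uses a stable mergesort so equal
p-values keep input order; probability-scale clipping in the generator is
[0.01, 0.99] and is logged when it binds.

## Known limitations

* The dispersion test's method-of-moments φ is noisy at few samples per
  class; with < 2 usable samples the site is skipped, and power is low for
  5–10 samples per class — by design it errs conservative.
* BH is not SLIM/IHW; q-values are comparable in semantics but not
  numerically identical to those procedures.
* The BLUP model folds disabled random terms into the residual; with the
  cow effect off, λ_b slightly overstates shrinkage relative to the full
  multi-component evaluation.
* DMR direction and span rules are the simplest consistent reading of the
  calling rule; no smoothing or direction consistency is imposed.
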