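# methfert

Sperm DNA-methylation analysis of male fertility, from per-CpG bisulfite
read counts and artificial-insemination (AI) records to differentially
methylated cytosines (DMCs) and regions (DMRs), genomic annotation, and a
Random-Forest classifier of fertility status.

The package targets the analysis setting of AI bull cohorts, where a sire's
field fertility can be measured precisely: each insemination is scored 0/1
by whether the cow was re-bred within 56 days, and the bull's *corrected
non-return rate* (corrected NRR 56) is the BLUP of the bull random effect in
a linear mixed model on those scores. Bulls are classed fertile/subfertile
from this phenotype, and reduced-representation bisulfite sequencing (RRBS)
of pooled semen samples provides per-CpG methylation counts. Everything
downstream of alignment is implemented here; a synthetic-data module
generates realistic cohorts with known ground truth, so the full pipeline is
exercisable and testable at desk scale.

## What it computes

**Phenotype.** For AI records with fixed effects (herd-year, month-year,
parity, calving-to-insemination interval, weekday, technician, semen
category), the mixed-model equations

```
[ X'X      X'Z        ] [b]   [X'y]
[ Z'X   Z'Z + λ_b I   ] [u] = [Z'y],   λ_b = (1 − r_b)/r_b,  r_b = σ²_bull/σ²_p
```

are solved for the per-bull BLUP u (corrected NRR 56), with r_b = 0.01 by
default.

**Site filtering.** A cell is *CpG10* when covered by ≥ 10 reads. The
testing background keeps sites that survive a variant mask (a CpG is dropped
if a polymorphism hits its C *or* G position), lie on allowed chromosomes,
and are CpG10 in at least ⌈min(n₁,n₂)/2⌉ samples of *both* classes.

**Differential methylation.** Two site-level tests:

* *pooled* — likelihood-ratio test comparing coverage-pooled class
  proportions (χ², 1 df); powerful, but blind to inter-individual
  overdispersion (methylKit-style);
* *dispersion* — Wald test with beta-binomial variance, per-class dispersion
  estimated by method of moments (DSS-style in spirit).

A DMC requires a Benjamini–Hochberg q-value below threshold (0.01 pooled /
0.1 dispersion) **and** a coverage-weighted group difference
Δ = %meth(subfertile) − %meth(fertile) of at least 10 points. DMRs are
maximal runs of ≥ 3 DMCs with consecutive gaps ≤ 100 bp.

**Annotation.** Gene features with precedence TSS (±100 bp) > promoter
(−2000..−100) > TTS (±100) > 5′UTR > 3′UTR > exon > intron > upstream
(10 kb) > downstream (10 kb) > intergenic; CpG-island context CGI > shore
(2 kb) > shelf (2 kb) > open sea, with a 75% minimum overlap for regions;
repeats by any overlap. Category enrichment against the background uses
two-sided Fisher tests.

**Classification.** Samples × DMC methylation percentages feed a 500-tree
Random Forest (mtry = ⌊√p⌋), with fertile as the positive class, evaluated
by accuracy / AUC / sensitivity / specificity under three designs: 50×
stratified 2/3–1/3 resampling, a two-direction collection-center split, and
train-on-main / test-on-independent-cohort.

## Worked example

```python
import numpy as np
from methfert import sitefilter, diffmeth, classify
from methfert.synth import SimParams, simulate_annotation, simulate_methylation

ann = simulate_annotation(n_genes=5, genome_length=1_000_000, seed=1)
params = SimParams(n_fertile=20, n_subfertile=20, n_cpg=5000,
                   frac_dmc=0.05, effect_delta=25.0, indiv_sd=0.1, cov_mean=20)
matrix, truth, sheet = simulate_methylation(params, ann, seed=2)
classes = sheet.set_index("sample_id")["fertility_class"]

mask = {(c, int(p)) for c, p in
        truth.loc[truth.is_variant_site, ["chrom", "pos"]].itertuples(index=False)}
keep, report, thr = sitefilter.apply_filters(matrix, classes, variant_mask=mask)
print(report.to_dict(), "group threshold:", thr)

bg = matrix.subset_sites(np.flatnonzero(keep))
dmcs = diffmeth.call_dmcs(bg, classes, test="pooled")
print(len(dmcs), "DMCs")

feats = classify.prepare_features(matrix, dmcs, policy="complete_only")
summary = classify.crossvalidate_resampled(feats, classes.reindex(feats.index),
                                           iterations=10, seed=1, n_trees=200)
print(round(summary["mean_auc"], 3), round(summary["mean_accuracy"], 3))
```

prints

```
{'sites_in': 5000, 'removed_scaffold': 0, 'removed_variant': 54,
 'removed_group_presence': 0, 'sites_out': 4946} group threshold: 10
250 DMCs
1.0 0.979
```

i.e. 54 genotype-confounded sites are masked, the background keeps 4946
sites CpG10 in ≥10 samples per class, the caller recovers the 250 planted
25-point DMCs (recall 1.0 at empirical FDR < 0.01 against the truth table),
and the cross-validated forest separates this strongly separable cohort with
mean AUC 1.0 and mean accuracy 0.98.

The same pipeline runs from the shell:

```bash
methfert all --outdir out/ --seed 7
```

writing per-sample Bismark coverage files, the sample sheet, truth table,
filter report, DMC/DMR tables (TSV + BED), annotations, model report and a
manifest with content hashes.

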