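# hdomics

Desk-scale building blocks for multi-omics studies of Huntington disease
(HD) peripheral tissues — skeletal muscle, skin, adipose — in mutation
carriers and controls. The package re-implements, as a tested Python
library, the bespoke computational steps such studies rely on:

- **TMT 10-plex PSM processing** — reporter-signal filtering, isotope
  impurity correction (solving the channel cross-contamination linear
  system per spectrum), sum-scaling normalization, log2 ratios to a
  pooled-reference channel, and collapse of PSMs to peptides and proteins.
- **Sample quality control** — median/IQR control charts (3-SD rule) and a
  dual-criterion expression-outlier detector (outside a 68% probability
  ellipse in PCA **and** standardized connectivity below −2.5).
- **Imputation and normalization** — iterative-PCA (EM-style low-rank)
  completion of missing abundances, quantile normalization across plex
  sets, and linear-model removal of nuisance covariates (plex, site,
  gender, age, BMI) that preserves protected disease-stage effects.
- **Reproducibility-optimized differential abundance** — a from-scratch
  ROTS-style procedure: for the statistic family
  `d_g = |x̄₁g − x̄₂g| / (α₁ + α₂·s_g)` (with `s_g` the Welch standard
  error), choose `(α, k)` to maximize the bootstrap top-`k` overlap
  Z-score `Z = (R_k − R⁰_k)/sd(R⁰_k)` against a permutation null, then
  assign permutation p-values and FDR.
- **HTT haplotyping** — construct haplotypes over the 21 defining variants
  (20 SNPs + the rs149109767 indel) from phased genotypes, name them by
  descending frequency after a reserved published set (hap.1–hap.16, with
  novel vectors continuing at hap.17), assign per-sample diplotypes, and
  cluster by binary (Jaccard) distance with Ward dendrograms and k-means
  (k = 3), separately for normal and mutant chromosomes.
- **Clinical bookkeeping** — disease burden score `DBS = (CAG − 35.5) × age`,
  staging (pre-HD: diagnostic confidence ≤ 2; early-HD: TFC 7–13), and
  per-group descriptive summaries.

Because raw patient-level data of this kind are access-controlled, the
`synthetic` module generates every input with planted ground truth (group
effects, batch shifts, outlier samples, haplotype frequencies), so the
entire pipeline is exercisable and testable end to end.

## Worked example

`examples/differential_abundance.py` plants a 3σ effect on 100 of 1000
features (10 vs 10 samples) and runs the full reproducibility-optimized
test:

```
chosen statistic: alpha1=0.01, alpha2=1.0, k=100
reproducibility Z = 6.39 (> 2 indicates a reproducible ranking, as required of a usable run)
bootstrap top-100 overlap 0.893 vs null 0.278
103 features at FDR < 0.05; 100/100 planted recovered, 3 false
```

The optimizer lands on a t-like statistic with a small stabilizing offset
and a top-list size matching the planted signal; the observed bootstrap
overlap (0.89) far exceeds chance (0.28), giving Z ≈ 6.4, and the
permutation FDR recovers all planted features with 3 false positives at
the 5% level. The other scripts in `examples/` demonstrate the TMT chain
(`tmt_pipeline.py` recovers planted ±1 log2 effects to ~0.01 through
impurity mixing, loading differences and 10% missingness), outlier
detection, imputation + batch removal, haplotyping and cohort summaries.

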