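# Methods

This note documents the models and procedures implemented in `hdomics`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions.

## TMT 10-plex PSM chain (`hdomics.tmt`)

A 10-plex run is a table of PSMs (peptide-spectrum matches), each with up
to ten reporter-ion intensities (channels 126–131). The chain applies, in
order:

1. **Signal filter** — keep PSMs with a present, strictly positive
   intensity in at least one channel.
2. **Isotope-impurity correction** — reporter channels cross-contaminate
   according to a lot-specific mixing matrix `M` (column-stochastic-like,
   diagonally dominant): `observed = M · true`. We solve the linear
   system per PSM, restricted to the present channels (the corresponding
   submatrix), and clamp small negative solutions to zero. Full inversion
   was chosen over sequential subtraction because it is exact and
   testable by a round trip (`M · corrected = observed` whenever no
   clamping occurred, verified at 1e-8 relative). Matrices with condition
   number above 1e8 (configurable) are rejected with the lot named.
3. **Sum-scaling** — per run, channel sums `S_c` are computed over
   present values and every channel is multiplied by `median(S)/S_c`, so
   all channel totals equal the median afterwards (relative tolerance
   1e-9, asserted by tests). The opposite factor (`S_c/median`) is
   available behind `literal=True`; it amplifies high-loading channels
   and is provided only for comparability with pipelines that implement
   the scaling that way. Channels with zero total have no defined factor
   and are left unscaled with a warning.
4. **Reference ratios** — log2(sample/reference) per PSM against the
   designated reference channel. The reference defaults to channel 131, a
   common position for a pooled reference; it is configurable per plex
   because labeling schemes differ. Missing or zero reference yields an
   all-missing row (never ±inf), counted in the log.
5. **Collapse** — shared (non-unique gene mapping) rows are dropped
   first, then rows without a protein ID; one representative PSM per
   peptide is kept, the one with the maximum row mean (ties to the first
   in input order). Protein aggregation applies the same max-mean
   representative rule to peptides; it is simple, deterministic and
   consistent with the peptide collapse. A median-polish style summary
   was considered and rejected to keep the peptide and protein levels
   directly comparable.

Fractionated runs of the same plex are concatenated by run before
filtering; fractionation affects data volume, not the algorithms.

## Sample QC (`hdomics.qc`)

**Control charts.** Per sample, the median (central tendency) and IQR
(scale) of its abundance distribution; a sample is flagged on a metric
when it lies more than 3 SD (configurable) from the across-sample mean of
that metric, and is a "strong outlier" if either metric flags. Note that
with `n` samples the largest attainable standardized deviation is
`(n−1)/√n`, so the 3-SD rule can only trigger for n ≳ 11; this matches
its intended use on cohort-sized sample sets.

**Dual-criterion expression outliers.** Samples are scored on the first
two principal components of the feature-centered matrix (samples as
observations, features centered but not scaled — two components being
the plotting convention the ellipse refers to). A bivariate normal is fit
to the scores and the ellipse boundary set at the chi-square(2 df)
quantile of the coverage probability (default 0.68). Connectivity is the
mean Euclidean distance of a sample to all others, standardized with a
sign flip, `Z_s = −(k_s − k̄)/sd(k)`, so distant samples get negative Z;
a sample is an outlier iff it is outside the ellipse **and** `Z < −2.5`.
The two criteria are strongly correlated, so the conjunction does not
multiply their tail probabilities; on homogeneous Gaussian matrices
(n = 20, p = 500) the measured false-flag rate is below 1% of samples
(asserted over 200 simulated matrices). Whether distances should use all
features or only the most variable ones is left to the caller (the
detector is matrix-agnostic); defaults use all features.

**Prevalence filter.** A count-matrix feature is kept iff, in at least
one group involved in at least one requested comparison, at least
`min_samples` (default 9) samples have a nonzero count. Lowering the
threshold never removes a kept feature (monotonicity is a tested
property).

**Covariate factorization.** Continuous covariates (age, BMI) are cut
into `n_bins` (default 5) equal-width intervals, the range widened by
0.1% at both edges so the extremes fall inside the outer bins — the
convention of R's `cut`.

## Imputation and normalization (`hdomics.normalize`)

**Iterative PCA.** Missing cells start at their column means; each
iteration column-centers the completed matrix, fits a rank-`r` truncated
SVD, and overwrites the missing cells with fitted values, until the
maximum relative change over imputed cells drops below `tol` (1e-6) or
`max_iter` (1000) is reached (then a warning, never an exception).
Observed cells are never altered. Plain truncated-SVD iteration is used,
without ridge regularization; a regularized variant would only matter
near rank deficiency, which the rank cap avoids. When no rank is given it
is chosen by cross-validated masking: 5% of observed cells are held out
and the rank in 1..10 minimizing their reconstruction RMSE is used.
Imputation is applied at the peptide and protein level (after collapse);
applying it at the PSM level instead is possible but noisier.

**Quantile normalization.** Every column is mapped onto the mean of the
per-column sorted distributions; ties within a column share the mean of
the reference quantiles they span. Requires a complete matrix (run after
imputation). Rank order within each column and the grand mean are
preserved exactly.

**Covariate removal.** Per feature, a least-squares linear model with an
intercept, the protected factors (disease stage) and the nuisance terms
(plex set, site, gender, age, BMI; dummy-encoded with treatment
contrasts when categorical) is fitted jointly, and only the fitted
nuisance contribution is subtracted — the `removeBatchEffect` convention,
which is idempotent and preserves protected effects and residuals.
Sequential single-covariate removal in a stated order is available for
fidelity with pipelines that removed covariates consecutively; for
balanced (orthogonal) designs the two agree exactly, and the joint fit is
the default because it is order-invariant. Rank-deficient designs and
nuisance terms aliased with the protected block raise errors naming the
offending term. Continuous covariates may enter either as linear terms
(proteomics default) or factorized into 5 levels (the count-data
convention).

## Reproducibility-optimized testing (`hdomics.rots`)

The two-group statistic family is
`d_g = |x̄₁g − x̄₂g| / (α₁ + α₂·s_g)` with
`s_g = sqrt(v₁g/n₁ + v₂g/n₂)` (Welch standard error); `(α₁,α₂) = (1,0)`
is the plain absolute mean difference and `(0,1)` the absolute Welch t.
The default grid is α₁ ∈ {0, 0.01, 0.05, 0.1, 0.25, 0.5, 1, 2, 5} with
α₂ = 1, plus (1, 0); top-list sizes follow a logarithmic ladder
{10, 25, 50, 100, 250, 500, …} capped at the feature count.

For each of `B` rounds (default 1000) two datasets are drawn by
resampling samples with replacement within each group; features are
ranked by `d` in both and the fractional top-`k` overlap recorded. The
same scheme under random label permutation yields null overlaps; the
reproducibility Z-score is `Z_k(α) = (R_k − R⁰_k)/sd(R⁰_k)`, with the
denominator the SD over the `B` null pair overlaps. The grid point
maximizing Z is selected (ties prefer smaller k, then smaller α₂, then
smaller α₁; zero-spread points are skipped with a warning). Because the
denominator is the per-pair spread rather than the standard error of the
mean, null data give |Z| well below 2, while planted signals at realistic
effect sizes give Z ≫ 2 — matching the convention that a usable
comparison shows Z > 2.

Significance uses label permutations (optionally within strata): the
p-value of feature g is the add-one-smoothed fraction of pooled null |d|
at or above |d_g|; the FDR is the average per-permutation count of null
statistics ≥ |d_g| divided by the observed rank of |d_g|, made monotone
(a larger |d| never receives a larger FDR) and capped at 1. Features with
fewer than two observations in a group get missing statistics
(pairwise-complete means/variances are a safety net; proteomics matrices
are imputed upstream). Everything is reproducible bit-for-bit given the
seed. Whether (α, k) should be optimized per comparison or shared across
a tissue is a design choice; this implementation optimizes per comparison.

## Haplotyping (`hdomics.haplotype`)

Haplotypes are allele vectors (0 = reference, 1 = alternate) over an
ordered locus list, by default the 21 HTT-region defining variants.
Chromosomes with any missing call are excluded from construction (and
counted), since haplotype identity requires all loci. Naming: vectors
matching a reserved definition keep the reserved name whatever their
frequency; the rest are sorted by descending frequency (ties broken
lexicographically on the allele string, which makes naming independent
of input order) and numbered after the reserved set. The reserved
definitions are an input file — the package ships a schema, not the
published table — keeping the tool generic over any variant set.

The "binary distance" is the asymmetric Jaccard distance: disagreements
divided by the union of alternate-carrying loci, 0 for two all-reference
vectors by convention. It is computed with scipy's `jaccard` metric and
cross-checked in the tests against an exhaustive hand-rolled oracle on
all length-5 vectors (symmetry, identity, triangle inequality).
Dendrograms use Ward's linkage on that distance; flat clusters come from
k-means (k = 3, 100 seeded restarts) on the 0/1 vectors. Normal and
mutant haplotypes can be clustered separately; which phase carries the
expanded repeat is accepted as input metadata, since phasing the repeat
itself is out of scope. Panels are read/written as minimal uncompressed
phased VCF (GT `a|b`) or TSV.

## Clinical module (`hdomics.clinical`)

`DBS = (CAG − 35.5) × age`, defined only for carriers (controls have no
expanded allele and raise). Staging: non-carrier → control; carrier with
diagnostic confidence level ≤ 2 → pre-HD; carrier with DCL > 2 and TFC
7–13 (TFC stages 1–2) → early-HD; a diagnosed carrier with TFC < 7 falls
outside the study strata and returns "unclassified". Group summaries are
descriptive only (mean/min/max per numeric field); inferential
comparisons (ANOVA and post-hoc tests) are routine statistics outside
this package's scope. TFC is treated as recorded data for all groups,
not derived from stage.

## Synthetic data (`hdomics.synthetic`)

The generators emulate the statistical structure the pipeline assumes:

- **PSM tables**: log2 intensities `base + group effect + plex shift +
  channel loading + noise`, with base abundance ~ N(20, 2) log2 units
  (the dynamic range of reporter intensities), plex shifts ~ N(0, 0.25),
  channel loadings ~ N(0, 0.1), PSM noise 0.3 log2 units and 10%
  missingness by default (missing completely at random; real TMT
  missingness is partly abundance-dependent, which the generator does
  not emulate — left-censoring would mainly stress the imputation step).
  Linear intensities are then mixed by the impurity matrix and thinned.
  The nine sample channels alternate control/case; channel 131 is the
  pooled reference. Planted effects (default 1 log2 unit on 10% of
  peptides) come in up/down pairs whose base abundances are tied
  (`b_down = b_up · 2^e`), so each channel's total signal is unchanged —
  exactly the equal-loading assumption under which global normalization
  is valid. This is what makes the noiseless end-to-end recovery exact:
  batch shifts cancel in the reference ratio and channel loadings cancel
  under sum-scaling.
- **Expression matrices**: per-feature Gaussians; planted outlier samples
  are shifted by `shift_sd` feature-SDs (random sign) on a random half
  of the features — a gross-failure mode (swap, degradation), not subtle
  drift.
- **Phased panels**: chromosomes i.i.d. from specified haplotype
  frequencies; consecutive pairs form diploid samples. No linkage
  structure beyond the haplotypes themselves is simulated.
- **Cohort metadata**: ages U(30, 50), long CAG U{40..55} for carriers,
  TFC/DCL drawn consistently with the staging rules, balanced sites.

Every generator is a pure function of its arguments including the seed.
Passing tests on these generators demonstrates correctness of the
algorithms under their stated assumptions; it does not demonstrate
robustness to real-data pathologies the generators omit (abundance-
dependent missingness, heavy-tailed intensities, relatedness between
samples, genotyping error).

## Problem sizes and numerical conventions

The test suite and the acceptance script run the procedures at
deliberately desk-scale sizes chosen to make the statistical checks
sharp but quick: 1000 features and 10 vs 10 samples with B = 200
bootstrap pairs and 200 permutations for the reproducibility statistic
(B = 1000 remains the library default), 50–100 replicates for detector
and accuracy rates, and 10 000 chromosomes for haplotype frequency
recovery (binomial 3σ bounds). Tolerances: sum-scaling conservation and
idempotence at 1e-9–1e-10 relative; impurity round trip at 1e-8;
"exact" noiseless recovery asserted at 1e-9 absolute (floating-point
exp2/log2 round trips leave ~1e-15). Ties are always broken by stable
input order unless a documented rule (lexicographic allele strings,
smaller k/α) applies.
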