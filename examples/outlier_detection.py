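"""Flag outlying expression samples with the dual criterion.

A sample is an outlier only if it falls outside the 68% probability
ellipse on the first two principal components AND its standardized
connectivity (sign-flipped mean Euclidean distance to the other samples)
is below -2.5. Two samples are planted 10 feature-SDs away."""

from hdomics import qc, synthetic

matrix, truth = synthetic.gen_expression_matrix(
    n_features=500, n_samples=20, outliers=2, shift_sd=10, seed=3)

calls = qc.detect_expression_outliers(matrix, ellipse_prob=0.68, z_cutoff=-2.5)
for c in calls:
    if c.is_outlier or c.sample_id in truth.outlier_samples:
        mark = "planted" if c.sample_id in truth.outlier_samples else ""
        print(f"{c.sample_id}: outside ellipse={c.pca_outside_ellipse}, "
              f"connectivity Z={c.connectivity_z:+.2f}, "
              f"outlier={c.is_outlier} {mark}")
flagged = {c.sample_id for c in calls if c.is_outlier}
print(f"\nflagged {flagged} == planted {truth.outlier_samples}: "
      f"{flagged == truth.outlier_samples}")
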