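"""Process simulated TMT 10-plex reporter data end to end.

Two plexes are generated with planted +/-1 log2-unit effects on 10% of
peptides, channel loading differences, plex-level batch shifts, isotopic
impurity mixing and 10% missing signals; the chain (signal filter,
impurity correction, sum-scaling, log2 ratios to the channel-131
reference, peptide collapse) should recover the planted effects in the
case-vs-control ratio difference."""

import numpy as np

from hdomics import synthetic, tmt

impurities = tmt.make_impurity_matrix(spill=0.03)
tables, truth = synthetic.gen_psm_dataset(
    n_plexes=2, n_psms=1000, missing_rate=0.1, noise_sd=0.3, seed=4,
    impurities=impurities)

peptides, pep2prot = tmt.process_to_peptides(tables, impurities)
proteins = tmt.aggregate_to_proteins(peptides, pep2prot)
print(f"{sum(len(t) for t in tables)} PSMs -> {peptides.shape[0]} peptides "
      f"x {peptides.shape[1]} samples -> {proteins.shape[0]} proteins")

samples = synthetic.psm_sample_groups(tables)
case = samples.loc[samples.group == "case", "sample_id"]
ctrl = samples.loc[samples.group == "control", "sample_id"]
diff = peptides[case].mean(axis=1) - peptides[ctrl].mean(axis=1)

planted = sorted(truth.planted_effect_features)
est_up = diff[[p for p in planted if truth.effect_directions[p] > 0]].mean()
est_dn = diff[[p for p in planted if truth.effect_directions[p] < 0]].mean()
est_null = diff.drop(planted, errors="ignore").abs().mean()
print(f"planted +1 peptides: mean case-control log2 ratio {est_up:+.3f}")
print(f"planted -1 peptides: mean case-control log2 ratio {est_dn:+.3f}")
print(f"unplanted peptides:  mean |log2 ratio| {est_null:.3f} "
      "(noise floor; planted effects recovered near their true +/-1)")
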