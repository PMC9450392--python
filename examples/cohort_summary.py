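"""Simulate a study-sized cohort and summarize it per group.

The disease burden score DBS = (CAG - 35.5) * age accumulates exposure to
the expanded CAG tract; carriers are staged pre-HD (diagnostic confidence
<= 2) or early-HD (diagnosed, TFC 7-13)."""

from hdomics import clinical, synthetic

cohort = synthetic.gen_cohort_metadata(n_control=20, n_pre=21, n_early=20, seed=1)
print(f"{len(cohort)} participants:",
      cohort["group"].value_counts().to_dict())

example = cohort[cohort.group == "early-HD"].iloc[0]
print(f"\nexample carrier: CAG {example.cag_long:.0f}, age {example.age}, "
      f"DBS {clinical.compute_dbs(example.cag_long, example.age):.1f} "
      "(>= 250 was the screening threshold)")

summary = clinical.summarize_cohort(cohort)
print("\nper-group mean[min;max] of age and long CAG allele:")
for grp in ("control", "pre-HD", "early-HD"):
    age = summary.loc[grp, "age"]
    cag = summary.loc[grp, "cag_long"]
    print(f"  {grp:9s} age {age['mean']:.1f}[{age['min']:.1f};{age['max']:.1f}]"
          f"  CAG {cag['mean']:.1f}[{cag['min']:.0f};{cag['max']:.0f}]")
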