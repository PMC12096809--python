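"""End-to-end population comparison of FAF-like and dAC-like cohorts.

Runs the full pipeline (stimulus synthesis, unit simulation, preference
indices, confusion matrices, selectivity indices) on a small cohort of
each phenotype and prints the group statistics: the dAC-like cohort
classifies call categories far better than the FAF-like cohort, and the
2-ms integration window beats the 200-ms window in both.
"""

import batvoc as bv

config = bv.RunConfig(
    seed=3, n_faf=10, n_dac=10, n_trials=20, n_resamples=2_000,
    out_dir="scratch/pipeline_demo",
)
summary = bv.run_pipeline(config)

units = summary.units
for area in ("FAF", "dAC"):
    grp = units[units["area"] == area]
    print(f"{area}: mean best-category p  2 ms {grp['best_prob_2ms'].mean():.3f} | "
          f"200 ms {grp['best_prob_200ms'].mean():.3f};  "
          f"median SI  2 ms {grp['si_2ms'].median():.3f} | "
          f"200 ms {grp['si_200ms'].median():.3f}")

print("\ngroup comparisons (t = two-sample t-test, ranksum = Wilcoxon):")
cols = ["analysis", "test", "statistic", "p", "significant"]
print(summary.comparisons[cols].to_string(index=False))
print(f"\nper-unit tables written to {config.out_dir}/")
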