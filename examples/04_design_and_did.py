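"""Design-stage sample size and the between-arm difference-in-differences.

The study design detects an improvement in correlation with the benchmark
from 0.60 to 0.75 at 80 % power: the Fisher-z formula gives the per-arm n,
cross-checked by brute-force simulation. The difference-in-differences then
asks whether the two interview modalities diverge from the weighed record
by different amounts, using a respondent random-intercept mixed model.
"""

from dietval import (
    DesignParams,
    RunConfig,
    SimConfig,
    power_simulation_correlation,
    run_pipeline,
    sample_size_correlation,
)

design = sample_size_correlation(DesignParams())
print(f"sample size per arm: {design.n_per_arm} "
      f"(inflated for non-response: {design.n_inflated})")
power = power_simulation_correlation(design.n_per_arm, n_replicates=5000, seed=3)
print(f"empirical power at that n (5000 simulated studies): {power:.3f} "
      f"-> matches the designed 0.80")

result = run_pipeline(RunConfig(sim=SimConfig(seed=3)))
did = result.report.did.set_index("measure")
print("\ndifference-in-differences, (WFR - 24HR) contrast between arms:")
for measure in ("energy_kcal", "carb_g", "protein_g"):
    row = did.loc[measure]
    print(f"  {measure:12s} CAPI diff {row['mean_diff_capi']:+8.1f}  "
          f"PAPI diff {row['mean_diff_papi']:+8.1f}  "
          f"DiD {row['estimate']:+8.1f}  p = {row['p_value']:.3f}")
print("(both arms share the same generating error model here, so the DiD")
print(" should hover near zero with large p-values)")
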