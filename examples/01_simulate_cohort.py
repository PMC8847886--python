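"""Generate a synthetic family-structured cohort with a planted latent mode.

The generator plants a single latent score per subject (correlated within
families, MZ > DZ > siblings), loads it onto a dozen subject measures and a
sparse set of connectome edges, and adds confound effects, noise, missing
entries and four deliberately pathological SM columns.
"""

import numpy as np

from conncca import CohortSpec, generate_cohort

spec = CohortSpec(seed=0)  # desk scale: 300 subjects, 50 nodes
cohort = generate_cohort(spec, with_motion=True)

print("family composition:")
print(cohort.families["member_type"].value_counts().to_string())
print(f"\nSM table: {cohort.sm.shape[0]} subjects x {cohort.sm.shape[1]} SMs "
      f"({cohort.sm.isna().to_numpy().mean():.1%} missing)")
print(f"node time series: {cohort.timeseries.shape} (subjects, T, nodes)")
print(f"motion runs: {len(cohort.motion_runs)}")

# co-twin similarity of the planted score reflects the familial structure
scores = cohort.truth.subject_scores[:, 0]
mz = cohort.families.index[cohort.families["member_type"] == "MZ"].to_numpy()
pairs = scores[mz].reshape(-1, 2)
print(f"\nMZ co-twin score correlation: {np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]:.2f} "
      f"(target {spec.rho_mz})")
# Expect roughly the spec's rho_mz: co-twins share sqrt(rho) of the latent score.
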