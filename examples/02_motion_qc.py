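"""Head-motion quality control: censoring, run filtering, subject selection.

Framewise displacement (FD) above 0.3 mm flags a time point for removal, and
surviving low-motion segments shorter than 5 points are removed too.  A run
is usable if its mean FD stays under 0.3 mm and it has at least half of the
expected 380 time points; subjects need two good runs, 750 post-censoring
points, a passing anatomical scan, and a non-anomalous mean FD.
"""

import numpy as np

from conncca import CohortSpec, censor_timepoints, select_subjects
from conncca.cohort import generate_family_structure, generate_motion_table

spec = CohortSpec(seed=1, n_singles=100, n_mz_families=0, n_dz_families=0,
                  n_sib_families=0, n_sms=5, n_nodes=5)
families = generate_family_structure(spec)
runs, qc = generate_motion_table(
    spec, np.random.default_rng(1), families, bad_run_frac=0.15,
)

one = runs[0]
mask = censor_timepoints(one.fd)
print(f"run 0: {one.fd.size} points, mean FD {one.fd.mean():.3f} mm, "
      f"{mask.sum()} kept after censoring "
      f"({(~mask).sum()} flagged for motion or short segments)")

included, ledger = select_subjects(runs, qc)
print(f"\nincluded {len(included)} of {len(qc)} subjects")
if not ledger.empty:
    print("exclusions by first failed criterion:")
    print(ledger["reason"].value_counts().to_string())
# Criteria are attributed in order: too few good runs, then insufficient
# post-censor scan time, then anatomical QC, then the mean-FD tail trim.
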