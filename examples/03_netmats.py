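"""Estimate connectivity netmats and assemble the subjects-by-edges matrix.

Each subject's T x N node time series becomes an N x N Fisher-z partial
correlation matrix (ridge regularized, rho = 0.01, the production setting);
half-vectorizing the upper triangle of each and stacking gives the
subjects-by-edges matrix that feeds the CCA.  At the study's 200 nodes this
matrix has n(n-1)/2 = 19 900 columns.
"""

from conncca import CohortSpec, assemble_edges, generate_cohort, group_average
from conncca.netmats import partial_netmat_ridge

cohort = generate_cohort(CohortSpec(seed=2, n_singles=30, n_mz_families=0,
                                    n_dz_families=0, n_sib_families=0))
netmats = [
    partial_netmat_ridge(cohort.timeseries[i], rho=0.01, subject_id=sid)
    for i, sid in enumerate(cohort.families["subject_id"])
]
edges = assemble_edges(netmats)
group = group_average(netmats)

n = cohort.spec.n_nodes
print(f"{len(netmats)} subjects, {n} nodes "
      f"-> edge matrix {edges.values.shape} (expected E = {n * (n - 1) // 2})")
print(f"edge 0 connects nodes {tuple(edges.edge_index[0])}")
print(f"group-average netmat: z range [{group.z.min():.2f}, {group.z.max():.2f}]")
# Off-diagonal z values are Fisher-transformed partial correlations; the
# group average is the element-wise mean across subjects.
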