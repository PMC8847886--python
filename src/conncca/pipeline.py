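"""End-to-end orchestration: simulate -> QC -> netmats -> prepare -> CCA ->
permutation inference -> post hoc -> cross-validation.

`run_pipeline` executes the whole analysis on a synthetic cohort under a
single config and seed, returning every intermediate object and writing
deterministic summary tables when an output directory is given.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca as cca_mod
from . import posthoc as ph
from .cohort import Cohort, CohortSpec, generate_cohort
from .connectome_prep import PreparedConnectome, prepare_connectome
from .crossval import CVReport, repeated_cv
from .netmats import (
    EdgeMatrix,
    assemble_edges,
    full_netmat,
    group_average,
    halfvec,
    partial_netmat_ridge,
)
from .permutation import NullDistributions, build_blocks, permutation_null
from .sm_prep import PreparedSM, build_confounds, prepare_sm, quantitative_filter

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run (desk-scale defaults)."""

    spec: CohortSpec = field(default_factory=CohortSpec)
    d: int = 30  # PCA / CCA dimensionality
    rho: float = 0.01  # ridge partial-correlation regularization
    n_perm: int = 500  # permutations for the main null
    cv_reps: int = 10
    cv_perms: int = 1000
    train_frac: float = 0.8
    top_k: int = 30
    n_clusters: int = 4
    alpha: float = 0.001
    held_out: tuple = ()  # SM names kept out of the CCA but on the axis
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    edge_matrix: EdgeMatrix
    sm_filter: pd.DataFrame
    confounds: np.ndarray
    prepared_sm: PreparedSM
    prepared_conn: PreparedConnectome
    cca: cca_mod.CCAResult
    null: NullDistributions
    variance_profile: cca_mod.VarianceProfile
    criteria: cca_mod.CriteriaReport
    axis: pd.DataFrame
    edge_weight_vector: np.ndarray
    top_edges: pd.DataFrame
    r_with_mean_connectome: float
    clusters: np.ndarray
    leaf_order: np.ndarray
    cv: CVReport
    modes_summary: pd.DataFrame


def _modes_summary(
    res: cca_mod.CCAResult,
    null: NullDistributions,
    vp: cca_mod.VarianceProfile,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mode": np.arange(1, res.n_modes + 1),
            "r": res.r,
            "p_fwe": null.p_fwe,
            "ve_connectome": vp.ve_connectome,
            "z_connectome": vp.z_connectome,
            "ve_sm": vp.ve_sm,
            "z_sm": vp.z_sm,
        }
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis under one config; identical config+seed gives
    identical outputs."""
    t0 = time.time()
    spec = config.spec
    if spec.seed != config.seed:
        from dataclasses import replace

        spec = replace(spec, seed=config.seed)
    cohort = generate_cohort(spec)
    families = cohort.families

    # connectome side: per-subject ridge partial netmats -> subjects x edges
    nms = [
        partial_netmat_ridge(cohort.timeseries[i], rho=config.rho, subject_id=sid)
        for i, sid in enumerate(families["subject_id"])
    ]
    edge_matrix = assemble_edges(nms)
    group_partial = group_average(nms)
    full_nms = [
        full_netmat(cohort.timeseries[i]) for i in range(len(families))
    ]
    group_full = group_average(full_nms)

    # SM side: quantitative filter, confound construction, staging
    ledger = quantitative_filter(cohort.sm)
    kept = [c for c in cohort.sm.columns if ledger.loc[c, "status"] == "kept"]
    cca_cols = [c for c in kept if c not in set(config.held_out)]
    confounds = build_confounds(
        cohort.confound_base, categorical=("site", "scanner")
    ).to_numpy()
    prepared_sm = prepare_sm(cohort.sm[cca_cols], confounds, d=config.d)
    prepared_conn = prepare_connectome(edge_matrix, confounds, d=config.d)

    # CCA and family-restricted permutation inference
    res = cca_mod.fit_cca(prepared_conn.n5, prepared_sm.s5)
    res = cca_mod.align_modes_to_sm(res, prepared_sm.s2)
    blocks = build_blocks(families)
    seq = np.random.SeedSequence(config.seed)
    rng_perm, rng_axis, rng_cv = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )
    null = permutation_null(
        prepared_conn.n5,
        prepared_sm.s5,
        blocks,
        n_perm=config.n_perm,
        rng=rng_perm,
        observed_r=res.r,
        n0=edge_matrix.values,
        s2=prepared_sm.s2,
        confounds=confounds,
    )
    ve_conn = cca_mod.mode_variance_explained(res.u, edge_matrix.values)
    ve_sm = cca_mod.mode_variance_explained(res.v, prepared_sm.s2)
    st_c = null.ve_stats(ve_conn, "connectome")
    st_s = null.ve_stats(ve_sm, "sm")
    vp = cca_mod.VarianceProfile(
        ve_connectome=ve_conn, ve_sm=ve_sm,
        z_connectome=st_c["z"], z_sm=st_s["z"],
        p5_connectome=st_c["p5"], p95_connectome=st_c["p95"],
        p5_sm=st_s["p5"], p95_sm=st_s["p95"],
    )
    criteria = cca_mod.evaluate_replication_criteria(
        vp, null.p_fwe, alpha=config.alpha
    )
    primary = criteria.primary_mode if criteria.primary_mode is not None else 0

    # post hoc: axis over deconfounded RAW SMs (CCA SMs + held-out ones)
    from .sm_prep import deconfound

    s8 = deconfound(cohort.sm[kept].to_numpy(dtype=float), confounds, warn_rank=False)
    axis = ph.positive_negative_axis(
        pd.DataFrame(s8, columns=kept),
        res.v[:, primary],
        held_out=config.held_out,
        blocks=blocks,
        n_perm=min(config.n_perm, 1000),
        rng=rng_axis,
        confounds=confounds,
    )
    a_f1 = ph.edge_weights(res.u[:, primary], edge_matrix.values)
    r_mean = ph.correlate_with_mean(a_f1, halfvec(group_partial))
    top = ph.top_edges(a_f1, edge_matrix.edge_index, k=config.top_k)
    labels, leaf_order, _ = ph.ward_clusters(group_full.z, k=config.n_clusters)

    # family-respecting cross-validation
    cv = repeated_cv(
        prepared_sm.s2,
        edge_matrix.values,
        confounds,
        families,
        reps=config.cv_reps,
        perms=config.cv_perms,
        train_frac=config.train_frac,
        d=config.d,
        rng=rng_cv,
    )

    summary = _modes_summary(res, null, vp)
    result = PipelineResult(
        config=config, cohort=cohort, edge_matrix=edge_matrix,
        sm_filter=ledger, confounds=confounds, prepared_sm=prepared_sm,
        prepared_conn=prepared_conn, cca=res, null=null, variance_profile=vp,
        criteria=criteria, axis=axis, edge_weight_vector=a_f1, top_edges=top,
        r_with_mean_connectome=r_mean, clusters=labels, leaf_order=leaf_order,
        cv=cv, modes_summary=summary,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir), elapsed=time.time() - t0)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, elapsed: float) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.modes_summary.to_csv(outdir / "modes_summary.csv", index=False)
    result.axis.to_csv(outdir / "axis.csv", index=False)
    result.top_edges.to_csv(outdir / "top_edges.csv", index=False)
    result.sm_filter.to_csv(outdir / "sm_filter_ledger.csv")
    pd.DataFrame(
        {"node": np.arange(result.clusters.size), "cluster": result.clusters}
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    cv = result.cv
    pd.DataFrame(
        {
            "rep": np.arange(1, cv.r_test.size + 1),
            "r_test": cv.r_test,
            "p": cv.p,
            "n_train": cv.n_train,
            "n_test": cv.n_test,
        }
    ).to_csv(outdir / "crossval.csv", index=False)
    result.cohort.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
    c = result.criteria
    manifest = {
        "seed": result.config.seed,
        "n_subjects": len(result.cohort.families),
        "n_nodes": result.config.spec.n_nodes,
        "n_edges": int(result.edge_matrix.values.shape[1]),
        "d": result.config.d,
        "n_perm": result.config.n_perm,
        "primary_mode": None if c.primary_mode is None else int(c.primary_mode) + 1,
        "criteria": [bool(c.criterion_1), bool(c.criterion_2), bool(c.criterion_3)],
        "cv_mean_r": cv.mean_r,
        "cv_sd_r": cv.sd_r,
        "elapsed_seconds": round(elapsed, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
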