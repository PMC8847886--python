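"""Synthetic family-structured cohorts with a planted cross-view latent mode.

Every downstream stage of the pipeline is exercised against cohorts generated
here, where the ground truth is known by construction:

* family structure with monozygotic (MZ) twin pairs, dizygotic (DZ) twin
  pairs, non-twin sibling groups and single children;
* per-subject latent scores whose within-family correlation decreases
  MZ > DZ > sibling, built from shared + unique Gaussian components
  (``score = sqrt(rho) * family + sqrt(1 - rho) * unique``), standard normal
  marginally;
* subject measures loading on the latent scores, contaminated by confound
  effects, Gaussian noise and missing-at-random entries, plus deliberately
  pathological columns that the quantitative filter must catch;
* per-subject node time series drawn from a Gaussian whose precision matrix
  is tilted by the latent score on a fixed sparse set of edges, so ridge
  partial correlation is the matched connectivity estimator;
* heavy-tailed per-run head-motion traces with occasional spike bursts and a
  configurable fraction of deliberately bad runs.

The real study this emulates is observational; all distributional choices
here are artifact decisions documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .qc import MotionRun, QCRecord

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "default_spec",
    "null_spec",
    "generate_family_structure",
    "generate_scores",
    "generate_confound_base",
    "generate_sm_matrix",
    "generate_node_timeseries",
    "generate_motion_table",
    "generate_cohort",
]

#: names of the deliberately pathological SM columns, in their fixed order
PATHOLOGICAL_COLUMNS = (
    "path_constant",
    "path_identical",
    "path_outlier",
    "path_missing",
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; same seed means bit-identical output."""

    n_mz_families: int = 25
    n_dz_families: int = 25
    n_sib_families: int = 25
    sibs_per_family: int = 2
    n_singles: int = 150
    n_nodes: int = 50
    n_timepoints: int = 750
    n_sms: int = 40
    n_modes: int = 1
    sm_loadings: np.ndarray | None = None  # (n_modes, n_sms)
    edge_loadings: list | None = None  # per mode: (n_nodes, n_nodes) symmetric
    rho_mz: float = 0.8
    rho_dz: float = 0.5
    rho_sib: float = 0.4
    sm_noise_sd: float = 0.7
    missing_rate: float = 0.02
    confound_effects: np.ndarray = field(
        default_factory=lambda: np.full(5, 0.2)
    )
    add_pathological: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_mz_families, self.n_dz_families, self.n_sib_families,
            self.sibs_per_family, self.n_singles, self.n_nodes,
            self.n_timepoints, self.n_sms, self.n_modes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        for r in (self.rho_mz, self.rho_dz, self.rho_sib):
            if not 0.0 <= r <= 1.0:
                raise ValueError("familial correlations must lie in [0, 1]")
        if not self.rho_mz >= self.rho_dz >= self.rho_sib:
            raise ValueError("need rho_mz >= rho_dz >= rho_sib")
        if self.sm_loadings is None and self.n_modes > 0:
            self.sm_loadings = _default_sm_loadings(self.n_modes, self.n_sms)
        if self.edge_loadings is None and self.n_modes > 0:
            self.edge_loadings = [
                _default_edge_loadings(self.n_nodes) for _ in range(self.n_modes)
            ]
        if self.edge_loadings:
            for lam in self.edge_loadings:
                lam = np.asarray(lam)
                if not np.allclose(lam, lam.T) or np.any(np.diag(lam) != 0):
                    raise ValueError(
                        "edge loadings must be symmetric with zero diagonal"
                    )

    @property
    def n_subjects(self) -> int:
        return (
            2 * self.n_mz_families
            + 2 * self.n_dz_families
            + self.sibs_per_family * self.n_sib_families
            + self.n_singles
        )


def _default_sm_loadings(n_modes: int, n_sms: int) -> np.ndarray:
    """Twelve informative SMs per mode, loading 0.7 with alternating sign."""
    load = np.zeros((n_modes, n_sms))
    per = min(12, n_sms)
    for k in range(n_modes):
        cols = (np.arange(per) + k * per) % n_sms
        load[k, cols] = 0.7 * (-1.0) ** np.arange(per)
    return load


def _default_edge_loadings(n_nodes: int, weight: float = 0.12) -> np.ndarray:
    """A sparse planted edge set: a perfect matching of adjacent node pairs
    plus a handful of extra cross-pair edges, all +-weight on the precision
    scale.  The matching keeps the spectral norm near ``weight``, so the
    tilted precision matrices stay comfortably positive definite."""
    lam = np.zeros((n_nodes, n_nodes))
    pairs = [(i, i + 1) for i in range(0, n_nodes - 1, 2)]
    extras = [(i, i + 2) for i in range(0, min(10, n_nodes - 2), 2)]
    for idx, (i, j) in enumerate(pairs + extras):
        w = weight * (-1.0) ** idx
        lam[i, j] = lam[j, i] = w
    return lam


@dataclass
class GroundTruth:
    """What the generator planted: per-subject latent scores and loadings."""

    subject_scores: np.ndarray  # subjects x n_modes
    true_sm_loadings: np.ndarray  # n_modes x n_sms
    true_edge_loadings: list  # per mode, n_nodes x n_nodes

    def planted_edge_ids(self, mode: int, edge_index: np.ndarray) -> np.ndarray:
        """Edge-matrix column ids carrying nonzero planted loading."""
        lam = np.asarray(self.true_edge_loadings[mode])
        return np.flatnonzero(lam[edge_index[:, 0], edge_index[:, 1]] != 0)


def generate_family_structure(spec: CohortSpec) -> pd.DataFrame:
    """Family table with columns subject_id, family_id, member_type."""
    rows = []
    fid = 0

    def _family(member_type: str, size: int) -> None:
        nonlocal fid
        for _ in range(size):
            rows.append((f"s{len(rows):05d}", f"f{fid:04d}", member_type))
        fid += 1

    for _ in range(spec.n_mz_families):
        _family("MZ", 2)
    for _ in range(spec.n_dz_families):
        _family("DZ", 2)
    for _ in range(spec.n_sib_families):
        _family("SIB", spec.sibs_per_family)
    for _ in range(spec.n_singles):
        _family("SINGLE", 1)
    return pd.DataFrame(rows, columns=["subject_id", "family_id", "member_type"])


_RHO_BY_TYPE = {"MZ": "rho_mz", "DZ": "rho_dz", "SIB": "rho_sib", "SINGLE": None}


def generate_scores(
    spec: CohortSpec, families: pd.DataFrame, rng: np.random.Generator
) -> GroundTruth:
    """Latent subject scores with the familial shared/unique construction."""
    n = len(families)
    scores = np.zeros((n, max(spec.n_modes, 1)))
    for _, grp in families.groupby("family_id", sort=False):
        mtype = grp["member_type"].iloc[0]
        attr = _RHO_BY_TYPE[mtype]
        rho = getattr(spec, attr) if attr else 0.0
        shared = rng.standard_normal(scores.shape[1])
        for idx in grp.index:
            unique = rng.standard_normal(scores.shape[1])
            scores[idx] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique
    if spec.n_modes == 0:
        return GroundTruth(
            subject_scores=np.zeros((n, 0)),
            true_sm_loadings=np.zeros((0, spec.n_sms)),
            true_edge_loadings=[],
        )
    return GroundTruth(
        subject_scores=scores[:, : spec.n_modes],
        true_sm_loadings=np.asarray(spec.sm_loadings, dtype=float),
        true_edge_loadings=[np.asarray(l, dtype=float) for l in spec.edge_loadings],
    )


def generate_confound_base(
    spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """The 7 base confounds: site, scanner, mean FD, weight, BMI and the
    cube-root brain/intracranial volumes."""
    n = spec.n_subjects
    return pd.DataFrame(
        {
            "site": rng.integers(0, 4, n),
            "scanner": rng.integers(0, 3, n),
            "mean_fd": rng.lognormal(mean=np.log(0.12), sigma=0.4, size=n),
            "weight": rng.normal(32.0, 6.0, n),
            "bmi": rng.normal(17.5, 2.5, n),
            "cbrt_brain_vol": np.cbrt(rng.normal(1.2e6, 1e5, n)),
            "cbrt_icv": np.cbrt(rng.normal(1.5e6, 1.2e5, n)),
        }
    )


def generate_sm_matrix(
    truth: GroundTruth,
    spec: CohortSpec,
    confound_base: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Subjects-by-SMs table (NaN = missing) plus per-column metadata flags.

    Each SM is ``loading . scores + confound effect + N(0, sm_noise_sd)``;
    a common confound component (standardized quantitative confounds weighted
    by ``confound_effects``) is added to every SM.  When
    ``spec.add_pathological`` is set, four deliberately pathological columns
    are appended in fixed trailing positions: a constant column, a
    nearly-constant column, an extreme-outlier column, and a mostly-missing
    column.
    """
    n = spec.n_subjects
    signal = truth.subject_scores @ truth.true_sm_loadings  # n x n_sms
    quant = confound_base[["mean_fd", "weight", "bmi", "cbrt_brain_vol", "cbrt_icv"]]
    q = quant.to_numpy(dtype=float)
    q = (q - q.mean(axis=0)) / q.std(axis=0)
    confound_term = q @ np.asarray(spec.confound_effects, dtype=float)
    values = (
        signal
        + confound_term[:, None]
        + spec.sm_noise_sd * rng.standard_normal((n, spec.n_sms))
    )
    if spec.missing_rate > 0:
        values[rng.random((n, spec.n_sms)) < spec.missing_rate] = np.nan
    sm = pd.DataFrame(values, columns=[f"sm{j:03d}" for j in range(spec.n_sms)])
    flags = {c: "signal" for c in sm.columns}
    if spec.add_pathological:
        sm["path_constant"] = 1.0
        ident = np.zeros(n)
        ident[: max(1, int(0.04 * n) - 1)] = 1.0  # >= 96% identical values
        sm["path_identical"] = ident
        outlier = rng.standard_normal(n)
        outlier[0] = 1e4  # max(Y) far beyond 100 * mean(Y)
        sm["path_outlier"] = outlier
        missing = rng.standard_normal(n)
        missing[rng.random(n) < 0.6] = np.nan
        sm["path_missing"] = missing
        for c in PATHOLOGICAL_COLUMNS:
            flags[c] = c
    return sm, flags


def _base_precision(n_nodes: int) -> np.ndarray:
    """Fixed baseline precision: identity plus a chain of -0.3 couplings on
    consecutive odd pairs, giving the group netmat nonzero structure."""
    omega = np.eye(n_nodes)
    for i in range(1, n_nodes - 1, 2):
        omega[i, i + 1] = omega[i + 1, i] = -0.3
    return omega


def generate_node_timeseries(
    truth: GroundTruth, spec: CohortSpec, rng: np.random.Generator,
    min_eigenvalue: float = 0.05,
) -> np.ndarray:
    """Per-subject node time series, shape (subjects, T, N).

    Subject i is sampled from a zero-mean Gaussian with precision
    ``Omega_i = Omega_base - sum_k score_ik * Lambda_k``.  If any subject's
    precision would dip below ``min_eigenvalue``, the whole loading set is
    scaled down until the margin holds for every subject (the applied scale is
    the same for all subjects so the planted mode stays linear in the score).
    """
    n = spec.n_subjects
    omega0 = _base_precision(spec.n_nodes)
    lams = [np.asarray(l, dtype=float) for l in truth.true_edge_loadings]
    scale = 1.0
    if lams:
        for _ in range(60):
            ok = True
            for i in range(n):
                tilt = sum(
                    truth.subject_scores[i, k] * lams[k] for k in range(len(lams))
                )
                w = np.linalg.eigvalsh(omega0 - scale * tilt)
                if w.min() <= min_eigenvalue:
                    ok = False
                    break
            if ok:
                break
            scale *= 0.8
        else:
            raise ValueError(
                f"subject {i}: precision matrix not positive definite even "
                "after scaling the edge loadings"
            )
    out = np.empty((n, spec.n_timepoints, spec.n_nodes))
    for i in range(n):
        tilt = sum(
            truth.subject_scores[i, k] * lams[k] for k in range(len(lams))
        ) if lams else 0.0
        omega = omega0 - scale * tilt
        chol = np.linalg.cholesky(omega)  # omega = L L^T, cov = L^-T L^-1
        z = rng.standard_normal((spec.n_timepoints, spec.n_nodes))
        out[i] = solve_triangular(chol.T, z.T, lower=False).T
    return out


def generate_motion_table(
    spec: CohortSpec,
    rng: np.random.Generator,
    families: pd.DataFrame,
    n_runs: int = 4,
    run_length: int = 380,
    baseline_median: float = 0.1,
    baseline_sigma: float = 0.3,
    spike_prob: float = 0.02,
    spike_scale: float = 0.5,
    bad_run_frac: float = 0.0,
) -> tuple[list[MotionRun], list[QCRecord]]:
    """Per-run framewise-displacement traces and anatomical QC flags.

    FD is a lognormal baseline plus sparse exponential spike bursts.  A
    ``bad_run_frac`` fraction of runs is deliberately degraded (shortened to
    150 points or given high mean FD) to exercise the run filter.
    """
    runs: list[MotionRun] = []
    qc: list[QCRecord] = []
    for sid in families["subject_id"]:
        for ridx in range(n_runs):
            length = run_length
            fd = rng.lognormal(np.log(baseline_median), baseline_sigma, length)
            spikes = rng.random(length) < spike_prob
            fd = fd + spikes * rng.exponential(spike_scale, length)
            if bad_run_frac > 0 and rng.random() < bad_run_frac:
                if rng.random() < 0.5:
                    fd = fd[:150]  # short run, fails length criterion
                else:
                    fd = fd + 0.4  # high mean FD
            runs.append(MotionRun(subject_id=sid, run_index=ridx, fd=fd))
        qc.append(QCRecord(subject_id=sid, t1_pass=True, n_rest_runs_pass=n_runs))
    return runs, qc


@dataclass
class Cohort:
    """A fully generated synthetic cohort."""

    spec: CohortSpec
    families: pd.DataFrame
    truth: GroundTruth
    sm: pd.DataFrame
    sm_flags: dict
    confound_base: pd.DataFrame
    timeseries: np.ndarray  # subjects x T x N
    motion_runs: list
    qc_records: list


def generate_cohort(spec: CohortSpec, with_motion: bool = False) -> Cohort:
    """Generate every view of a cohort from a single seeded RNG stream."""
    rng = np.random.default_rng(spec.seed)
    families = generate_family_structure(spec)
    truth = generate_scores(spec, families, rng)
    confound_base = generate_confound_base(spec, rng)
    sm, flags = generate_sm_matrix(truth, spec, confound_base, rng)
    ts = generate_node_timeseries(truth, spec, rng)
    runs: list[MotionRun] = []
    qc: list[QCRecord] = []
    if with_motion:
        runs, qc = generate_motion_table(spec, rng, families)
    return Cohort(
        spec=spec, families=families, truth=truth, sm=sm, sm_flags=flags,
        confound_base=confound_base, timeseries=ts, motion_runs=runs,
        qc_records=qc,
    )


def default_spec(**overrides) -> CohortSpec:
    """The desk-scale planted-mode cohort (300 subjects, 50 nodes)."""
    return CohortSpec(**overrides)


def null_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A cohort with no planted mode (negative control)."""
    overrides.setdefault("n_modes", 0)
    return CohortSpec(seed=seed, **overrides)
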