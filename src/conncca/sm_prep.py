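"""Subject-measure (SM) preparation: filtering, Gaussianization, confound
regression, missing-data covariance completion, and PCA reduction.

The staged matrices follow the naming S1..S5:

* S1 — raw selected SMs (subjects x SMs, NaN = missing);
* S2 — S1 after a rank-based inverse normal transformation per column;
* S3 — S2 with the confound matrix regressed out (per-column, observed rows);
* S4 — subjects-by-subjects covariance of S3 estimated pairwise over shared
  observations, completed to the nearest symmetric positive-definite matrix;
* S5 — subject scores of the top-d eigenpairs of S4 (column k = u_k sqrt(l_k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreparedSM",
    "quantitative_filter",
    "inverse_normal_transform",
    "build_confounds",
    "deconfound",
    "apply_deconfound",
    "pairwise_covariance",
    "nearest_spd",
    "pca_scores_from_spd",
    "sm_bookkeeping",
    "prepare_sm",
]


# ---------------------------------------------------------------------------
# quantitative SM filter

def quantitative_filter(
    sm: pd.DataFrame,
    min_present: float = 0.5,
    max_identical: float = 0.95,
    outlier_factor: float = 100.0,
) -> pd.DataFrame:
    """Classify each SM column as kept or dropped by the quantitative criteria.

    Criteria are applied in order; a column is attributed to the FIRST one it
    fails:

    1. ``dropped_c1`` — fewer than ``min_present`` of subjects have data;
    2. ``dropped_c2`` — at least ``max_identical`` of present values identical;
    3. ``dropped_c3`` — extreme outlier: with ``Y = (X - median(X))^2`` over
       present values, ``max(Y) > outlier_factor * mean(Y)``.

    Returns a ledger DataFrame indexed by SM name with columns
    ``status, frac_present, max_identical_frac, outlier_ratio``.
    """
    if sm.shape[0] < 1:
        raise ValueError("need at least one subject")
    rows = []
    for name in sm.columns:
        x = sm[name].to_numpy(dtype=float)
        present = ~np.isnan(x)
        frac_present = present.mean()
        xo = x[present]
        if xo.size:
            _, counts = np.unique(xo, return_counts=True)
            ident = counts.max() / xo.size
        else:
            ident = 1.0
        y = (xo - np.median(xo)) ** 2 if xo.size else np.array([0.0])
        mean_y = y.mean()
        ratio = y.max() / mean_y if mean_y > 0 else 0.0
        if frac_present < min_present:
            status = "dropped_c1"
        elif ident >= max_identical:
            status = "dropped_c2"
        elif ratio > outlier_factor:
            status = "dropped_c3"
        else:
            status = "kept"
        rows.append((name, status, frac_present, ident, ratio))
    return pd.DataFrame(
        rows,
        columns=["sm_name", "status", "frac_present", "max_identical_frac", "outlier_ratio"],
    ).set_index("sm_name")


# ---------------------------------------------------------------------------
# rank-based inverse normal transform

def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform of one column.

    Non-missing values are replaced by ``Phi^-1((rank - 3/8) / (m + 1/4))``
    with average ranks for ties (m = number of non-missing values); NaN stays
    NaN.  Raises on columns without at least two distinct observed values.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    xo = x[obs]
    if np.unique(xo).size < 2:
        raise ValueError("column has fewer than 2 distinct values; filter first")
    ranks = stats.rankdata(xo, method="average")
    out[obs] = stats.norm.ppf((ranks - 3.0 / 8.0) / (xo.size + 0.25))
    return out


# ---------------------------------------------------------------------------
# confounds

def build_confounds(
    base: pd.DataFrame, categorical: tuple[str, ...] | list[str] = ()
) -> pd.DataFrame:
    """Build the confound regressor matrix from the 7 base confounds.

    The documented base order is: site, scanner, mean FD, weight, BMI,
    cube-root brain volume, cube-root intracranial volume.  Each base column
    is demeaned and missing entries imputed as zero; the squares of the
    quantitative confounds in positions 3-7 are appended and demeaned again.
    With 7 quantitative columns this yields exactly 12 regressors.

    Columns named in ``categorical`` are expanded to one-of-K indicators
    (last level dropped, since deconfounding adds an intercept); a categorical
    block still counts as ONE logical confound and is never squared.
    """
    if base.shape[1] != 7:
        raise ValueError(f"expected 7 base confound columns, got {base.shape[1]}")
    cols: dict[str, np.ndarray] = {}
    quantitative: list[str] = []
    for pos, name in enumerate(base.columns):
        if name in categorical:
            levels = sorted(pd.unique(base[name].dropna()))
            for lev in levels[:-1]:
                cols[f"{name}={lev}"] = (base[name] == lev).to_numpy(dtype=float)
        else:
            cols[name] = base[name].to_numpy(dtype=float)
            if pos >= 2:  # positions 3-7 (1-based) get squared terms
                quantitative.append(name)

    def _demean_impute(v: np.ndarray) -> np.ndarray:
        v = v.astype(float).copy()
        obs = ~np.isnan(v)
        v[obs] -= v[obs].mean()
        v[~obs] = 0.0
        return v - v.mean()  # exact zero mean after imputation

    out = {k: _demean_impute(v) for k, v in cols.items()}
    for name in quantitative:
        sq = out[name] ** 2
        out[f"{name}^2"] = sq - sq.mean()
    return pd.DataFrame(out, index=base.index)


def deconfound(
    data: np.ndarray,
    confounds: np.ndarray,
    warn_rank: bool = True,
    return_betas: bool = False,
):
    """Regress ``[intercept, confounds]`` out of each data column.

    Columns may contain NaN: each column's projection is fitted on its own
    observed rows and residuals are written back there; NaN stays NaN.
    Rank-deficient designs fall back to the minimum-norm least-squares fit
    (equivalent to dropping dependent columns) with a warning.

    With ``return_betas=True`` also returns the (1 + p) x M coefficient
    matrix, usable with :func:`apply_deconfound` on held-out rows.
    """
    data = np.asarray(data, dtype=float)
    conf = np.asarray(confounds, dtype=float)
    if data.shape[0] != conf.shape[0]:
        raise ValueError("row counts of data and confounds differ")
    design = np.column_stack([np.ones(conf.shape[0]), conf])
    if warn_rank and np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("confound design is rank deficient; using min-norm fit", stacklevel=2)
    out = np.full(data.shape, np.nan)
    betas = np.zeros((design.shape[1], data.shape[1]))
    full = ~np.isnan(data).any(axis=0)
    if full.any():  # fast path: all-observed columns in one solve
        beta, *_ = np.linalg.lstsq(design, data[:, full], rcond=None)
        out[:, full] = data[:, full] - design @ beta
        betas[:, full] = beta
    for j in np.flatnonzero(~full):
        obs = ~np.isnan(data[:, j])
        beta, *_ = np.linalg.lstsq(design[obs], data[obs, j], rcond=None)
        out[obs, j] = data[obs, j] - design[obs] @ beta
        betas[:, j] = beta
    return (out, betas) if return_betas else out


def apply_deconfound(
    data: np.ndarray, confounds: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Subtract an already-fitted confound projection from new rows."""
    data = np.asarray(data, dtype=float)
    design = np.column_stack([np.ones(data.shape[0]), np.asarray(confounds, float)])
    return data - design @ betas


# ---------------------------------------------------------------------------
# missing-data covariance completion and PCA

def pairwise_covariance(s3: np.ndarray) -> np.ndarray:
    """Subjects-by-subjects covariance of S3, one SM at a time.

    Each SM column is demeaned over its observed entries; the (a, b) entry is
    the mean of products over SMs observed in BOTH subjects.  Raises if some
    subject pair shares no observed SM.
    """
    x = np.asarray(s3, dtype=float)
    mask = ~np.isnan(x)
    xc = x.copy()
    col_means = np.nanmean(x, axis=0)
    xc = xc - col_means
    xc[~mask] = 0.0
    counts = mask.astype(float) @ mask.T.astype(float)
    if np.any(counts == 0):
        a, b = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"subject pair ({a}, {b}) shares no observed SM; cannot form covariance"
        )
    cov = (xc @ xc.T) / counts
    return (cov + cov.T) / 2.0


def nearest_spd(a: np.ndarray, eps_scale: float = 1e-10) -> np.ndarray:
    """Nearest symmetric positive-definite completion by eigenvalue clipping.

    Eigenvalues below ``eps = eps_scale * max_eigenvalue`` are raised to eps
    (for symmetric input this is the Frobenius-nearest PSD matrix up to the
    floor); if Cholesky still fails by rounding, eps is doubled and re-applied
    until it succeeds.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite entries")
    sym = (a + a.T) / 2.0
    w, v = np.linalg.eigh(sym)
    eps = eps_scale * max(w.max(), np.finfo(float).tiny)
    while True:
        out = (v * np.maximum(w, eps)) @ v.T
        out = (out + out.T) / 2.0
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            eps *= 2.0


def pca_scores_from_spd(s4: np.ndarray, d: int = 70) -> np.ndarray:
    """Subject scores from the top-d eigenpairs of the SPD subject covariance.

    Column k is ``u_k * sqrt(lambda_k)`` with eigenvalues descending, so the
    Gram matrix of the scores approximates S4 at rank d.
    """
    s4 = np.asarray(s4, dtype=float)
    if d > s4.shape[0]:
        raise ValueError(f"d={d} exceeds matrix dimension {s4.shape[0]}")
    w, v = np.linalg.eigh(s4)
    order = np.argsort(w)[::-1][:d]
    w, v = w[order], v[:, order]
    return v * np.sqrt(np.maximum(w, 0.0))


# ---------------------------------------------------------------------------
# bookkeeping

@dataclass
class SMSelectionReport:
    n_matched: int
    n_confounds: int
    n_undesirable: int
    n_final: int
    flagged_subjects: list = field(default_factory=list)


def sm_bookkeeping(
    n_matched: int,
    n_confounds: int,
    n_undesirable: int,
    sm_values: np.ndarray | None = None,
    max_missing_frac: float = 0.5,
) -> SMSelectionReport:
    """Selection arithmetic: matched - confounds - undesirable = final count.

    If the final SM matrix is supplied, subjects missing more than
    ``max_missing_frac`` of the final SMs are flagged for removal.
    """
    n_final = n_matched - n_confounds - n_undesirable
    if n_final < 0:
        raise ValueError("more exclusions than matched SMs")
    flagged: list[int] = []
    if sm_values is not None:
        missing_frac = np.isnan(np.asarray(sm_values, dtype=float)).mean(axis=1)
        flagged = np.flatnonzero(missing_frac > max_missing_frac).tolist()
    return SMSelectionReport(n_matched, n_confounds, n_undesirable, n_final, flagged)


# ---------------------------------------------------------------------------
# staged pipeline

@dataclass
class PreparedSM:
    """The staged SM matrices with the parameters used to produce them."""

    s1: np.ndarray
    s2: np.ndarray
    s3: np.ndarray
    s4: np.ndarray
    s5: np.ndarray
    sm_names: list
    d: int


def prepare_sm(
    s1: pd.DataFrame | np.ndarray, confounds: np.ndarray, d: int = 70
) -> PreparedSM:
    """Run the S1 -> S5 staging on an already-filtered SM matrix."""
    if isinstance(s1, pd.DataFrame):
        names = list(s1.columns)
        s1v = s1.to_numpy(dtype=float)
    else:
        s1v = np.asarray(s1, dtype=float)
        names = [f"sm{j}" for j in range(s1v.shape[1])]
    s2 = np.column_stack([inverse_normal_transform(s1v[:, j]) for j in range(s1v.shape[1])])
    s3 = deconfound(s2, confounds)
    s4 = nearest_spd(pairwise_covariance(s3))
    s5 = pca_scores_from_spd(s4, d=d)
    return PreparedSM(s1=s1v, s2=s2, s3=s3, s4=s4, s5=s5, sm_names=names, d=d)
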