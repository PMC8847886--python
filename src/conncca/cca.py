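"""Canonical correlation analysis of the prepared connectome and SM views.

Given the d-dimensional score matrices N5 (connectome side) and S5 (SM side),
CCA finds demixing matrices A and B such that the canonical variate pairs
``U = N5c A`` and ``V = S5c B`` (centred inputs) are maximally correlated,
with successive pairs uncorrelated with earlier ones.  The fit is computed by
the whitened cross-covariance SVD, the same algorithm as the classical
``canoncorr``: orthonormalize each centred view, take the SVD of the product
of the orthonormal bases, and map the singular vectors back.

The module also provides variance-explained profiles (how much of an original
data matrix's total variance each mode's subject weights account for) and the
evaluation of the pre-registered replication criteria for a primary mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CCAResult",
    "VarianceProfile",
    "CriteriaReport",
    "fit_cca",
    "align_modes_to_sm",
    "mode_column_correlations",
    "mode_variance_explained",
    "evaluate_replication_criteria",
]

_RANK_TOL_FACTOR = 1e-10


@dataclass
class CCAResult:
    a: np.ndarray  # dx x d demixing, connectome side
    b: np.ndarray  # dy x d demixing, SM side
    u: np.ndarray  # n x d canonical variates, connectome side (unit variance)
    v: np.ndarray  # n x d canonical variates, SM side
    r: np.ndarray  # d canonical correlations, non-increasing
    x_mean: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)

    @property
    def n_modes(self) -> int:
        return self.r.size


def _whiten(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Centred SVD whitening: returns (orthonormal basis Q, back-map T, rank)
    with ``x_centred @ T = Q`` column-wise for the retained rank."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL_FACTOR * max(s[0], 1.0) * max(xc.shape)))
    t = vt[:rank].T / s[:rank]
    return u[:, :rank], t, rank


def fit_cca(x: np.ndarray, y: np.ndarray) -> CCAResult:
    """Fit a CCA between two subjects-by-features views.

    Both views are centred internally.  If a view is rank deficient after
    centring, the number of modes is reduced with a warning.  Canonical
    variates are scaled to unit variance; each mode's sign is fixed so that
    the largest-magnitude entry of its SM-side demixing column is positive
    (see :func:`align_modes_to_sm` for the data-anchored convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("views have different numbers of subjects")
    n = x.shape[0]
    qx, tx, rank_x = _whiten(x)
    qy, ty, rank_y = _whiten(y)
    d = min(rank_x, rank_y)
    if d == 0:
        raise ValueError("a view has rank zero after centring")
    if rank_x < x.shape[1] or rank_y < y.shape[1]:
        warnings.warn(
            f"rank-deficient views (ranks {rank_x}, {rank_y}); "
            f"fitting {d} modes",
            stacklevel=2,
        )
    w, s, zt = np.linalg.svd(qx.T @ qy, full_matrices=False)
    w, z = w[:, :d], zt[:d].T
    scale = np.sqrt(n - 1)
    a = tx @ w * scale
    b = ty @ z * scale
    u = qx @ w * scale
    v = qy @ z * scale
    # deterministic sign: largest-|entry| of each SM-side demixing column positive
    for k in range(d):
        j = np.argmax(np.abs(b[:, k]))
        if b[j, k] < 0:
            a[:, k] *= -1
            b[:, k] *= -1
            u[:, k] *= -1
            v[:, k] *= -1
    return CCAResult(
        a=a, b=b, u=u, v=v, r=np.clip(s[:d], 0.0, 1.0),
        x_mean=x.mean(axis=0), y_mean=y.mean(axis=0),
    )


def align_modes_to_sm(res: CCAResult, s2: np.ndarray) -> CCAResult:
    """Flip each mode so its strongest SM correlation is positive.

    Anchoring signs to the data (rather than to demixing coefficients) makes
    the positive-negative axis orientation reproducible across runs and
    cohorts.  Missing values in ``s2`` are ignored pairwise.
    """
    corr = mode_column_correlations(res.v, s2)  # SMs x modes
    for k in range(res.n_modes):
        j = np.nanargmax(np.abs(corr[:, k]))
        if corr[j, k] < 0:
            res.a[:, k] *= -1
            res.b[:, k] *= -1
            res.u[:, k] *= -1
            res.v[:, k] *= -1
    return res


def mode_column_correlations(weights: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Pearson correlation of each weight column with each data column.

    Missing data entries are skipped pairwise.  Returns (columns x modes).
    Zero-variance columns yield NaN correlations.
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(original, dtype=float)
    n = x.shape[0]
    mask = ~np.isnan(x)
    x0 = np.where(mask, x, 0.0)
    m = mask.astype(float)
    cnt = m.sum(axis=0)  # per column
    sx = x0.sum(axis=0)
    sxx = (x0 * x0).sum(axis=0)
    su = m.T @ w  # cols x modes: sum of weights over observed rows
    suu = m.T @ (w * w)
    sxu = x0.T @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxu - sx[:, None] * su / cnt[:, None]
        var_x = sxx - sx**2 / cnt
        var_u = suu - su**2 / cnt[:, None]
        corr = cov / np.sqrt(var_x[:, None] * var_u)
    corr[var_x <= 0] = np.nan
    return corr


def mode_variance_explained(
    weights: np.ndarray, original: np.ndarray
) -> np.ndarray:
    """Per-mode fraction of an original matrix's total variance explained.

    ``ve_k = sum_j r^2(weight_k, col_j) var(col_j) / sum_j var(col_j)`` with
    pairwise skipping of missing entries; equals the fraction of total
    variance captured by rank-1 regression of each column on the mode's
    subject weights.  Zero-variance columns are excluded with a warning.
    """
    x = np.asarray(original, dtype=float)
    mask = ~np.isnan(x)
    cnt = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.nanvar(x, axis=0)
    good = (cnt > 1) & (var > 0)
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} zero-variance or empty column(s) excluded "
            "from variance explained",
            stacklevel=2,
        )
    corr = mode_column_correlations(weights, x[:, good])
    return (np.nan_to_num(corr**2) * var[good][:, None]).sum(axis=0) / var[good].sum()


@dataclass
class VarianceProfile:
    """Observed and null-calibrated variance explained per mode, both views."""

    ve_connectome: np.ndarray
    ve_sm: np.ndarray
    z_connectome: np.ndarray
    z_sm: np.ndarray
    p5_connectome: np.ndarray
    p95_connectome: np.ndarray
    p5_sm: np.ndarray
    p95_sm: np.ndarray


@dataclass
class CriteriaReport:
    """Evaluation of the pre-registered primary-mode replication criteria."""

    primary_mode: int | None  # 0-based index, None if no mode passes criterion 1
    criterion_1: bool  # significant ve in BOTH views (above 95th null percentile)
    criterion_2: bool  # z ratios vs next-best mode >= the required factors
    criterion_3: bool  # FWE-corrected weight-correlation p < alpha
    z_ratio_connectome: float | None = None
    z_ratio_sm: float | None = None
    primary_p: float | None = None


def evaluate_replication_criteria(
    vp: VarianceProfile,
    pvals: np.ndarray,
    factors: dict | None = None,
    alpha: float = 0.001,
) -> CriteriaReport:
    """Evaluate the three primary-mode criteria against the permutation nulls.

    1. some mode's variance explained exceeds the 95th null percentile in BOTH
       views (the primary mode; ties broken by larger SM-side z);
    2. the primary mode's z is at least ``factors['conn']`` (default 2) and
       ``factors['sm']`` (default 3) times the next-largest z in each view;
    3. the primary mode's FWE-corrected weight-correlation p is < ``alpha``.
    """
    factors = {"conn": 2.0, "sm": 3.0, **(factors or {})}
    sig_both = (vp.ve_connectome > vp.p95_connectome) & (vp.ve_sm > vp.p95_sm)
    if not sig_both.any():
        return CriteriaReport(None, False, False, False)
    candidates = np.flatnonzero(sig_both)
    primary = int(candidates[np.argmax(vp.z_sm[candidates])])
    others = np.ones(vp.z_sm.size, dtype=bool)
    others[primary] = False

    def _ratio(z: np.ndarray) -> float:
        next_best = np.max(z[others])
        return float(z[primary] / next_best) if next_best > 0 else np.inf

    ratio_conn = _ratio(vp.z_connectome)
    ratio_sm = _ratio(vp.z_sm)
    c2 = ratio_conn >= factors["conn"] and ratio_sm >= factors["sm"]
    c3 = bool(pvals[primary] < alpha)
    return CriteriaReport(
        primary_mode=primary,
        criterion_1=True,
        criterion_2=bool(c2),
        criterion_3=c3,
        z_ratio_connectome=ratio_conn,
        z_ratio_sm=ratio_sm,
        primary_p=float(pvals[primary]),
    )
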