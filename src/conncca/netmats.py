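"""Subject-level network matrices (netmats) from parcellated node time series.

Each subject contributes a T x N node-time-series matrix.  Connectivity is
estimated either as the full Pearson correlation or as an L2-regularized
("ridge") partial correlation derived from the inverse of the rescaled sample
covariance.  All values are Fisher r-to-z transformed and half-vectorized
(upper triangle, row-major) into a subjects-by-edges matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Netmat",
    "EdgeMatrix",
    "partial_netmat_ridge",
    "full_netmat",
    "halfvec",
    "unhalfvec",
    "edge_index_pairs",
    "assemble_edges",
    "group_average",
]

_R_CAP = 1.0 - 1e-15


@dataclass
class Netmat:
    """Symmetric N x N matrix of Fisher-z connectivity values, zero diagonal."""

    z: np.ndarray
    kind: str  # "partial_ridge" or "full"
    rho: float | None = None
    subject_id: str | None = None


@dataclass
class EdgeMatrix:
    """Subjects-by-edges matrix; edge k is node pair ``edge_index[k]`` (i < j)."""

    values: np.ndarray  # subjects x E
    edge_index: np.ndarray  # E x 2 of (i, j), i < j, row-major order
    subject_ids: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.edge_index.max()) + 1


def _demean(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x N matrix")
    if ts.shape[0] <= ts.shape[1]:
        warnings.warn(
            f"T={ts.shape[0]} <= N={ts.shape[1]}: covariance is rank deficient",
            stacklevel=3,
        )
    return ts - ts.mean(axis=0)


def partial_netmat_ridge(ts: np.ndarray, rho: float = 0.01, subject_id: str | None = None) -> Netmat:
    """Ridge-regularized partial correlation netmat, Fisher transformed.

    The sample covariance is rescaled by its mean diagonal so ``rho`` is
    scale-free, ``rho * I`` is added, and partial correlations are read off
    the inverse: ``r_ij = -P_ij / sqrt(P_ii P_jj)``.

    Parameters
    ----------
    ts : (T, N) array
    rho : float
        Regularization weight; default 0.01.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    x = _demean(ts)
    t = x.shape[0]
    c = x.T @ x / (t - 1)
    c = c / np.mean(np.diag(c))
    try:
        p = np.linalg.inv(c + rho * np.eye(c.shape[0]))
    except np.linalg.LinAlgError as err:  # only reachable at rho == 0
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; use rho > 0"
        ) from err
    d = np.sqrt(np.diag(p))
    r = -p / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    r = np.clip((r + r.T) / 2.0, -_R_CAP, _R_CAP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return Netmat(z=z, kind="partial_ridge", rho=rho, subject_id=subject_id)


def full_netmat(ts: np.ndarray, subject_id: str | None = None) -> Netmat:
    """Full Pearson-correlation netmat, Fisher transformed, zero diagonal."""
    x = np.asarray(ts, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant node time series at node(s) {bad.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    if np.any(np.abs(r[~np.eye(r.shape[0], dtype=bool)]) >= 1.0):
        warnings.warn("|r| = 1 off-diagonal capped before Fisher transform", stacklevel=2)
    r = np.clip(r, -_R_CAP, _R_CAP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return Netmat(z=z, kind="full", subject_id=subject_id)


def edge_index_pairs(n_nodes: int) -> np.ndarray:
    """Upper-triangle (i < j) node pairs in row-major order, shape (E, 2)."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def halfvec(m: Netmat | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Half-vectorize a symmetric matrix: upper-triangle entries, row-major."""
    a = m.z if isinstance(m, Netmat) else np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(a, a.T, atol=atol):
        raise ValueError("input matrix is not symmetric")
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def unhalfvec(v: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`halfvec`: rebuild the zero-diagonal symmetric matrix."""
    v = np.asarray(v, dtype=float)
    e = n_nodes * (n_nodes - 1) // 2
    if v.shape != (e,):
        raise ValueError(f"expected edge vector of length {e}, got {v.shape}")
    m = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    m[iu] = v
    return m + m.T


def assemble_edges(nms: list[Netmat]) -> EdgeMatrix:
    """Stack per-subject half-vectorized netmats into a subjects-by-edges matrix."""
    if not nms:
        raise ValueError("no netmats given")
    n = nms[0].z.shape[0]
    if any(nm.z.shape[0] != n for nm in nms):
        raise ValueError("netmat dimensions differ across subjects")
    values = np.vstack([halfvec(nm) for nm in nms])
    ids = [nm.subject_id for nm in nms]
    return EdgeMatrix(
        values=values,
        edge_index=edge_index_pairs(n),
        subject_ids=None if any(i is None for i in ids) else ids,
    )


def group_average(nms: list[Netmat]) -> Netmat:
    """Element-wise mean of the Fisher-z netmats (the group connectome)."""
    if not nms:
        raise ValueError("no netmats given")
    n = nms[0].z.shape[0]
    if any(nm.z.shape[0] != n for nm in nms):
        raise ValueError("netmat dimensions differ across subjects")
    z = np.mean([nm.z for nm in nms], axis=0)
    return Netmat(z=z, kind=nms[0].kind, rho=nms[0].rho)
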