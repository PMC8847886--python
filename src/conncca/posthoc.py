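"""Post hoc analyses of the primary mode: the positive-negative axis,
edge-level mapping, and Ward clustering of the group connectome.

The positive-negative axis orders subject measures by their correlation with
the primary mode's SM-side subject weights; SMs with desirable connotations
land at one end and undesirable ones at the other.  The per-SM percent
variance uses the printed projection formula
``variance(V1 pinv(V1) s) / variance(s)``, which for demeaned vectors equals
the squared correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .permutation import ExchangeabilityBlocks, sample_permutation

__all__ = [
    "positive_negative_axis",
    "edge_weights",
    "correlate_with_mean",
    "top_edges",
    "ward_clusters",
]


def _pearson_obs(v1: np.ndarray, col: np.ndarray) -> tuple[float, np.ndarray]:
    obs = ~np.isnan(col)
    a = v1[obs] - v1[obs].mean()
    b = col[obs] - col[obs].mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return (float(a @ b / denom) if denom > 0 else np.nan), obs


def _projection_variance_pct(v1: np.ndarray, col: np.ndarray) -> float:
    """Percent variance via the projection formula with the pseudo-inverse."""
    obs = ~np.isnan(col)
    v = (v1[obs] - v1[obs].mean())[:, None]
    s = col[obs] - col[obs].mean()
    proj = v @ (np.linalg.pinv(v) @ s)
    var_s = s.var()
    return float(100.0 * proj.var() / var_s) if var_s > 0 else np.nan


def positive_negative_axis(
    s8: pd.DataFrame | np.ndarray,
    v1: np.ndarray,
    held_out: tuple[str, ...] | list[str] = (),
    blocks: ExchangeabilityBlocks | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    z_method: str = "permutation",
    confounds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlate every (deconfounded) SM column with the primary SM variate.

    Parameters
    ----------
    s8 : subjects x SMs matrix (NaN = missing), including any held-out SMs
        that were deconfounded but never entered the CCA.
    v1 : primary-mode SM-side subject weights.
    held_out : names of columns not included in the CCA (flagged in output).
    blocks, n_perm, rng : family-permutation machinery for the per-SM z
        (``z_method="permutation"``); ``z_method="fisher"`` uses the
        variance-stabilizing transform ``atanh(r) * sqrt(m - 3)`` instead.
    confounds : optional confound matrix; permuted weights are re-residualized
        against it so the permutation null matches the deconfounded space the
        observed correlation lives in.

    Returns a DataFrame (sm_name, r, pct_variance, z, included_in_cca)
    sorted by r descending.
    """
    if isinstance(s8, pd.DataFrame):
        names = list(s8.columns)
        x = s8.to_numpy(dtype=float)
    else:
        x = np.asarray(s8, dtype=float)
        names = [f"sm{j}" for j in range(x.shape[1])]
    v1 = np.asarray(v1, dtype=float)
    if z_method == "permutation":
        if blocks is None:
            raise ValueError("permutation z needs exchangeability blocks")
        rng = np.random.default_rng(rng)
        perms = np.stack([sample_permutation(blocks, rng) for _ in range(n_perm)])
        perm_v1 = v1[perms]  # n_perm x n
        if confounds is not None:
            qd, _ = np.linalg.qr(
                np.column_stack([np.ones(v1.size), np.asarray(confounds, float)])
            )
            perm_v1 = perm_v1 - (perm_v1 @ qd) @ qd.T

    rows = []
    for j, name in enumerate(names):
        col = x[:, j]
        obs = ~np.isnan(col)
        if np.nanvar(col) == 0:
            warnings.warn(f"zero-variance SM {name!r} excluded from axis", stacklevel=2)
            continue
        r, _ = _pearson_obs(v1, col)
        pct = _projection_variance_pct(v1, col)
        if z_method == "permutation":
            null_r = np.array(
                [_pearson_obs(pv, col)[0] for pv in perm_v1]
            )
            sd = null_r.std(ddof=1)
            z = (r - null_r.mean()) / sd if sd > 0 else np.nan
        else:
            m = int(obs.sum())
            z = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(m - 3))
        rows.append((name, r, pct, z, name not in set(held_out)))
    out = pd.DataFrame(
        rows, columns=["sm_name", "r", "pct_variance", "z", "included_in_cca"]
    )
    return out.sort_values("r", ascending=False, ignore_index=True)


def edge_weights(u1: np.ndarray, n0: np.ndarray) -> np.ndarray:
    """Correlate the primary connectome variate with every raw edge column.

    Returns the full-length edge weight vector (one Pearson r per edge),
    mapping the primary mode back onto the original connectome matrix.
    """
    u = np.asarray(u1, dtype=float)
    x = np.asarray(n0, dtype=float)
    uc = u - u.mean()
    xc = x - x.mean(axis=0)
    denom = np.linalg.norm(uc) * np.linalg.norm(xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc.T @ uc) / denom


def correlate_with_mean(a_f1: np.ndarray, mean_edges: np.ndarray) -> float:
    """Pearson r between the edge weight vector and the half-vectorized
    population-mean connectome."""
    return float(np.corrcoef(a_f1, mean_edges)[0, 1])


def top_edges(
    a_f1: np.ndarray, edge_index: np.ndarray, k: int = 30
) -> pd.DataFrame:
    """The K edges most strongly related to the primary mode.

    Sorted by |weight| descending with deterministic ties broken by edge id.
    Returns (rank, edge_id, node_i, node_j, weight, sign).
    """
    a = np.asarray(a_f1, dtype=float)
    if k > a.size:
        raise ValueError(f"K={k} exceeds number of edges {a.size}")
    order = np.lexsort((np.arange(a.size), -np.abs(a)))[:k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "edge_id": order,
            "node_i": edge_index[order, 0],
            "node_j": edge_index[order, 1],
            "weight": a[order],
            "sign": np.sign(a[order]).astype(int),
        }
    )


def ward_clusters(
    netmat: np.ndarray, k: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ward agglomerative clustering of connectome nodes.

    Nodes are clustered by Euclidean distance between the rows of the group
    (full-correlation) netmat; the linkage is optimally leaf-ordered for
    deterministic display.  Returns ``(labels, leaf_order, linkage)`` with
    labels in 1..k.
    """
    m = np.asarray(netmat, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("netmat must be square")
    if k > m.shape[0]:
        raise ValueError(f"k={k} exceeds number of nodes {m.shape[0]}")
    dist = pdist(m, metric="euclidean")
    link = hierarchy.optimal_leaf_ordering(hierarchy.ward(dist), dist)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(link)
    return labels, leaf_order, link
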