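"""Connectome feature preparation: the N0 -> N5 staging.

From the subjects-by-edges matrix N0 two normalized copies are built: N1 is
column-demeaned and globally variance-normalized; N2 rescales each column by
the magnitude of its mean (dropping near-zero-mean columns) before the same
demeaning and global normalization, emphasizing proportional rather than
additive edge variation.  Their horizontal concatenation N3 is deconfounded
into N4 and reduced by truncated SVD into the d-dimensional score matrix N5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netmats import EdgeMatrix
from .sm_prep import deconfound

__all__ = ["PreparedConnectome", "prepare_edge_features", "pca_scores_svd", "prepare_connectome"]


@dataclass
class PreparedConnectome:
    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    n4: np.ndarray | None
    n5: np.ndarray | None
    dropped_columns: np.ndarray  # edge ids dropped from the N2 block
    svd_vt: np.ndarray | None = None  # right singular vectors of N4 (d x width)
    d: int | None = None
    # normalization constants, kept so held-out subjects can be staged
    # identically ("strict" cross-validation mode)
    n1_center: np.ndarray | None = None
    n1_scale: float | None = None
    n2_center: np.ndarray | None = None
    n2_scale: float | None = None


def _demean_global_norm(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    center = x.mean(axis=0)
    x = x - center
    sd = x.std()
    if sd == 0:
        raise ValueError("block has zero global variance")
    return x / sd, center, float(sd)


def prepare_edge_features(
    n0: EdgeMatrix | np.ndarray, low_mean_threshold: float = 0.1
) -> PreparedConnectome:
    """Build N1, N2 and their concatenation N3 from the raw edge matrix N0.

    N2 divides each column by the absolute value of its mean and drops columns
    with ``|mean| < low_mean_threshold`` (division by a near-zero signed mean
    is unstable and z-valued edges can be negative).  Both blocks end
    column-demeaned with global standard deviation 1.
    """
    x = n0.values if isinstance(n0, EdgeMatrix) else np.asarray(n0, dtype=float)
    if x.shape[1] < 1:
        raise ValueError("edge matrix has no columns")
    n1, n1_center, n1_scale = _demean_global_norm(x.copy())
    means = x.mean(axis=0)
    keep = np.abs(means) >= low_mean_threshold
    if not keep.any():
        raise ValueError("all columns dropped by the low-mean rule; no N2 block")
    n2, n2_center, n2_scale = _demean_global_norm(x[:, keep] / np.abs(means[keep]))
    n3 = np.hstack([n1, n2])
    return PreparedConnectome(
        n0=x, n1=n1, n2=n2, n3=n3, n4=None, n5=None,
        dropped_columns=np.flatnonzero(~keep),
        n1_center=n1_center, n1_scale=n1_scale,
        n2_center=n2_center, n2_scale=n2_scale,
    )


def pca_scores_svd(n4: np.ndarray, d: int = 70) -> tuple[np.ndarray, np.ndarray]:
    """Rank-d SVD scores of N4: returns (U_d * S_d, Vt_d).

    ``N5 = U_d S_d`` spans the best rank-d approximation of N4; ``Vt_d`` is
    kept so held-out subjects can be projected (``N5_new = N4_new @ Vt_d.T``).
    """
    n4 = np.asarray(n4, dtype=float)
    if d > min(n4.shape):
        raise ValueError(f"d={d} exceeds min(N4 shape)={min(n4.shape)}")
    u, s, vt = np.linalg.svd(n4, full_matrices=False)
    return u[:, :d] * s[:d], vt[:d]


def prepare_connectome(
    n0: EdgeMatrix | np.ndarray,
    confounds: np.ndarray,
    d: int = 70,
    low_mean_threshold: float = 0.1,
) -> PreparedConnectome:
    """Full N0 -> N5 staging: normalize, concatenate, deconfound, reduce."""
    prep = prepare_edge_features(n0, low_mean_threshold=low_mean_threshold)
    prep.n4 = deconfound(prep.n3, confounds)
    prep.n5, prep.svd_vt = pca_scores_svd(prep.n4, d=d)
    prep.d = d
    return prep
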