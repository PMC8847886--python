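"""Restricted permutations that respect twin/sibling family structure.

The permutation group is generated by (i) within-family exchanges of subjects
holding the same role (MZ co-twins, DZ co-twins, non-twin siblings) and
(ii) whole-family exchanges between families whose role multiset ("signature")
is identical.  Singles are one-member families sharing the SINGLE signature,
so they permute freely among themselves.  Every valid permutation factors
uniquely into these two layers, so sampling each layer uniformly and
independently samples the whole group uniformly.

The permutation null for the CCA re-fits the analysis with the SM-side rows
permuted and records canonical correlations and per-mode variance explained,
yielding familywise-error p-values via the max-statistic (first canonical
correlation) distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import fit_cca, mode_variance_explained

__all__ = [
    "ExchangeabilityBlocks",
    "NullDistributions",
    "build_blocks",
    "sample_permutation",
    "enumerate_permutations",
    "count_permutations",
    "permutation_null",
]

_ROLE_ORDER = {"MZ": 0, "DZ": 1, "SIB": 2, "SINGLE": 3}


@dataclass
class _Family:
    family_id: str
    # role -> subject row indices, each list in canonical (input) order
    members: dict

    @property
    def signature(self) -> tuple:
        return tuple(
            sorted((role, len(idx)) for role, idx in self.members.items())
        )

    @property
    def slots(self) -> dict:
        """Same structure as members; positions to be filled on permutation."""
        return self.members


@dataclass
class ExchangeabilityBlocks:
    n_subjects: int
    families: list = field(default_factory=list)
    # signature -> list of indices into `families`
    signature_groups: dict = field(default_factory=dict)


def build_blocks(families: pd.DataFrame) -> ExchangeabilityBlocks:
    """Build exchangeability blocks from a family table.

    ``families`` must have columns ``subject_id, family_id, member_type``
    (member_type in MZ/DZ/SIB/SINGLE); row order defines subject indices.
    An MZ or DZ member without a same-type co-twin in its family is treated
    as a non-twin sibling, with a warning.
    """
    required = {"subject_id", "family_id", "member_type"}
    if not required.issubset(families.columns):
        raise ValueError(f"family table needs columns {sorted(required)}")
    fams: list[_Family] = []
    for fid, grp in families.groupby("family_id", sort=False):
        members: dict[str, list[int]] = {}
        for role in ("MZ", "DZ"):
            idx = grp.index[grp["member_type"] == role].tolist()
            if len(idx) == 1:
                warnings.warn(
                    f"family {fid!r}: lone {role} twin treated as non-twin sibling",
                    stacklevel=2,
                )
                members.setdefault("SIB", []).extend(idx)
            elif idx:
                members[role] = idx
        sibs = grp.index[grp["member_type"] == "SIB"].tolist()
        if sibs:
            members.setdefault("SIB", []).extend(sibs)
        singles = grp.index[grp["member_type"] == "SINGLE"].tolist()
        if singles:
            members["SINGLE"] = singles
        fams.append(_Family(family_id=str(fid), members=members))
    groups: dict[tuple, list[int]] = {}
    for i, f in enumerate(fams):
        groups.setdefault(f.signature, []).append(i)
    return ExchangeabilityBlocks(
        n_subjects=len(families), families=fams, signature_groups=groups
    )


def sample_permutation(
    blocks: ExchangeabilityBlocks, rng: np.random.Generator
) -> np.ndarray:
    """Sample one structure-preserving permutation, uniformly over the group.

    Returns an index array ``perm`` so that ``data[perm]`` is the permuted
    data: position i receives the subject originally at ``perm[i]``.
    """
    perm = np.empty(blocks.n_subjects, dtype=int)
    for group in blocks.signature_groups.values():
        order = rng.permutation(len(group))
        for dst_pos, src_pos in enumerate(order):
            dst = blocks.families[group[dst_pos]]
            src = blocks.families[group[src_pos]]
            for role, dst_idx in dst.slots.items():
                src_idx = src.members[role]
                shuffled = [src_idx[k] for k in rng.permutation(len(src_idx))]
                for slot, subj in zip(dst_idx, shuffled):
                    perm[slot] = subj
    return perm


def count_permutations(blocks: ExchangeabilityBlocks) -> int:
    """Size of the restricted permutation group (exact integer)."""
    from math import factorial

    total = 1
    for sig, group in blocks.signature_groups.items():
        total *= factorial(len(group))
        for _, count in sig:
            total *= factorial(count) ** len(group)
    return total


def enumerate_permutations(blocks: ExchangeabilityBlocks, limit: int = 100_000):
    """Brute-force enumeration of every valid permutation (small instances).

    Yields index arrays as produced by :func:`sample_permutation`.  Raises if
    the group exceeds ``limit`` elements.
    """
    if count_permutations(blocks) > limit:
        raise ValueError("permutation group too large to enumerate")

    group_choices = []
    for group in blocks.signature_groups.values():
        per_group = []
        for assignment in itertools.permutations(range(len(group))):
            # for each destination family, enumerate within-role arrangements
            per_family_opts = []
            for dst_pos, src_pos in enumerate(assignment):
                dst = blocks.families[group[dst_pos]]
                src = blocks.families[group[src_pos]]
                role_opts = []
                for role, dst_idx in dst.slots.items():
                    src_idx = src.members[role]
                    role_opts.append(
                        [list(zip(dst_idx, p)) for p in itertools.permutations(src_idx)]
                    )
                per_family_opts.append(
                    [sum(combo, []) for combo in itertools.product(*role_opts)]
                )
            per_group.extend(
                [sum(combo, []) for combo in itertools.product(*per_family_opts)]
            )
        group_choices.append(per_group)

    for combo in itertools.product(*group_choices):
        perm = np.empty(blocks.n_subjects, dtype=int)
        for pairs in combo:
            for slot, subj in pairs:
                perm[slot] = subj
        yield perm


@dataclass
class NullDistributions:
    """Permutation null draws and the statistics derived from them."""

    perm_r: np.ndarray  # P x d canonical correlations per permutation
    p_fwe: np.ndarray  # per-mode familywise p from the max-statistic null
    perm_ve_conn: np.ndarray | None = None  # P x d
    perm_ve_sm: np.ndarray | None = None

    def ve_stats(self, observed: np.ndarray, side: str) -> dict:
        """z-scores and 5th/95th percentile bands for observed per-mode ve."""
        draws = self.perm_ve_conn if side == "connectome" else self.perm_ve_sm
        if draws is None:
            raise ValueError(f"no variance-explained null for side {side!r}")
        mean, sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (observed - mean) / sd
        p5, p95 = np.percentile(draws, [5, 95], axis=0)
        return {"z": z, "p5": p5, "p95": p95, "null_mean": mean, "null_sd": sd}


def permutation_null(
    n5: np.ndarray,
    s5: np.ndarray,
    blocks: ExchangeabilityBlocks,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
    observed_r: np.ndarray | None = None,
    n0: np.ndarray | None = None,
    s2: np.ndarray | None = None,
    confounds: np.ndarray | None = None,
) -> NullDistributions:
    """Permutation null of the CCA, permuting the SM-side rows only.

    For each permutation the SM view's rows are permuted within the
    exchangeability structure and the CCA is re-fit; canonical correlations
    are always recorded, and per-mode variance explained against ``n0``
    (connectome side) and ``s2`` (SM side, rows co-permuted) when those
    matrices are given.  The FWE p-value of mode k is
    ``(1 + #{perm max-r >= r_k}) / (1 + P)``.

    When ``confounds`` is given, the confound projection (the deconfounding
    step of the preparation pipeline) is re-applied to the permuted SM-side
    scores before the re-fit.  Both prepared views are orthogonal to the
    confound subspace; a plainly row-permuted view is not, which biases the
    null canonical correlations downward and inflates the type-I error when
    the confound count is not negligible against the sample size.  Passing
    the confounds restores an exact-calibration null (a Freedman-Lane-style
    re-residualization of each permuted SM matrix).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(rng)
    obs = fit_cca(n5, s5)
    if observed_r is None:
        observed_r = obs.r
    d = obs.n_modes
    n = n5.shape[0]
    # whitened orthonormal bases; permuting rows of the centred view permutes
    # its basis rows identically, so each permutation needs only a small SVD
    from .cca import _whiten

    qx, _, _ = _whiten(n5)
    qy, _, _ = _whiten(s5)
    qd = None
    if confounds is not None:
        design = np.column_stack([np.ones(n), np.asarray(confounds, float)])
        qd, _ = np.linalg.qr(design)
    scale = np.sqrt(n - 1)
    perm_r = np.empty((n_perm, d))
    want_ve = n0 is not None or s2 is not None
    ve_conn = np.zeros((n_perm, d)) if n0 is not None else None
    ve_sm = np.zeros((n_perm, d)) if s2 is not None else None
    for b in range(n_perm):
        p = sample_permutation(blocks, rng)
        qyp = qy[p]
        if qd is not None:
            qyp = qyp - qd @ (qd.T @ qyp)
            qyp, _ = np.linalg.qr(qyp)
        if want_ve:
            w, s, zt = np.linalg.svd(qx.T @ qyp)
            k = min(d, s.size)
            perm_r[b] = np.clip(s[:d], 0.0, 1.0)
            if n0 is not None:
                u = qx @ w[:, :k] * scale
                ve_conn[b, :k] = mode_variance_explained(u, n0)
            if s2 is not None:
                v = qyp @ zt[:k].T * scale
                ve_sm[b, :k] = mode_variance_explained(v, s2[p])
        else:
            s = np.linalg.svd(qx.T @ qyp, compute_uv=False)
            perm_r[b] = np.clip(s[:d], 0.0, 1.0)
    max_null = perm_r[:, 0]
    p_fwe = (1 + (max_null[:, None] >= observed_r[None, :]).sum(axis=0)) / (1 + n_perm)
    return NullDistributions(
        perm_r=perm_r, p_fwe=p_fwe, perm_ve_conn=ve_conn, perm_ve_sm=ve_sm
    )
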