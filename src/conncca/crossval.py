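"""Family-respecting 80-20 train/test validation of the CCA.

Families are never split across the train and test sets.  The training CCA
is fitted on the training subjects' prepared views, and the held-out
subjects' first-mode weights are obtained by projecting test-side score
matrices through the training demixing matrices,
``U_test = N5_test A_train`` and ``V_test = S5_test B_train``.  Significance
of ``corr(U_test1, V_test1)`` is assessed against permutations of the test
SM rows within the test set's own family structure.

Two test-side preprocessing conventions are supported:

* ``"reestimate"`` (default, the literal published procedure): the test
  subjects' deconfounding and PCA are re-estimated on the test subset.
  Because a subset's principal components carry arbitrary signs, each test
  component is sign-aligned to its training counterpart through feature
  space before projection.
* ``"strict"``: training betas, normalization constants and bases are
  applied unchanged to the test rows (the cleaner generalization contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import CCAResult, fit_cca
from .connectome_prep import PreparedConnectome, pca_scores_svd, prepare_edge_features
from .permutation import build_blocks, sample_permutation
from .sm_prep import PreparedSM, apply_deconfound, deconfound, prepare_sm

__all__ = ["SplitResult", "CVReport", "family_split", "train_test_cca", "repeated_cv"]


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    achieved_train_frac: float


@dataclass
class CVReport:
    r_test: np.ndarray  # per repetition
    p: np.ndarray
    n_train: np.ndarray
    n_test: np.ndarray
    null_mean_r: float
    mean_r: float = field(init=False)
    sd_r: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_r = float(np.mean(self.r_test))
        self.sd_r = float(np.std(self.r_test, ddof=1)) if self.r_test.size > 1 else 0.0


def family_split(
    families: pd.DataFrame,
    train_frac: float = 0.8,
    rng: np.random.Generator | None = None,
) -> SplitResult:
    """Assign whole families to train/test, greedily filling the train set.

    Families are taken largest first (randomized among equal sizes) and
    placed in the train set while it still fits under the target count, so
    the achieved fraction is within one family of the target.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(rng)
    sizes = families.groupby("family_id", sort=False).size()
    if len(sizes) < 2:
        raise ValueError("cannot split a single-family cohort")
    n = len(families)
    target = int(round(train_frac * n))
    fam_ids = np.array(sizes.index)
    order = rng.permutation(len(fam_ids))
    fam_ids, fam_sizes = fam_ids[order], sizes.to_numpy()[order]
    order = np.argsort(-fam_sizes, kind="stable")  # largest first, random ties
    train_fams, count = set(), 0
    for i in order:
        if count + fam_sizes[i] <= target:
            train_fams.add(fam_ids[i])
            count += int(fam_sizes[i])
    in_train = families["family_id"].isin(train_fams)
    return SplitResult(
        train_ids=families.loc[in_train, "subject_id"].tolist(),
        test_ids=families.loc[~in_train, "subject_id"].tolist(),
        achieved_train_frac=count / n,
    )


def _sign_align_sm(train_prep: PreparedSM, test_prep: PreparedSM) -> np.ndarray:
    """Align test SM-side PCA component signs to the training components via
    their SM-space loadings (subject-space eigenvector signs are arbitrary)."""

    def _loadings(p: PreparedSM) -> np.ndarray:
        s3 = np.nan_to_num(p.s3 - np.nanmean(p.s3, axis=0))
        return s3.T @ p.s5  # SMs x d

    lt, le = _loadings(train_prep), _loadings(test_prep)
    signs = np.sign(np.sum(lt * le, axis=0))
    signs[signs == 0] = 1.0
    return test_prep.s5 * signs


def _sign_align_conn(
    train_prep: PreparedConnectome, test_prep: PreparedConnectome
) -> np.ndarray:
    """Align test connectome PCA signs to training via the shared N1 block of
    the right singular vectors (the N2 block widths can differ by drops)."""
    e = train_prep.n1.shape[1]
    signs = np.sign(np.sum(train_prep.svd_vt[:, :e] * test_prep.svd_vt[:, :e], axis=1))
    signs[signs == 0] = 1.0
    return test_prep.n5 * signs


@dataclass
class _TrainedPipeline:
    sm_prep: PreparedSM
    conn_prep: PreparedConnectome
    cca: CCAResult
    sm_betas: np.ndarray
    conn_betas: np.ndarray
    sm_feature_basis: np.ndarray  # SMs x d map used by strict mode


def _fit_train(
    s2_train: np.ndarray, n0_train: np.ndarray, conf_train: np.ndarray, d: int
) -> _TrainedPipeline:
    s3, sm_betas = deconfound(s2_train, conf_train, return_betas=True)
    from .sm_prep import nearest_spd, pairwise_covariance, pca_scores_from_spd

    s4 = nearest_spd(pairwise_covariance(s3))
    s5 = pca_scores_from_spd(s4, d=d)
    smp = PreparedSM(s1=s2_train, s2=s2_train, s3=s3, s4=s4, s5=s5,
                     sm_names=None, d=d)
    conn = prepare_edge_features(n0_train)
    conn.n4, conn_betas = deconfound(conn.n3, conf_train, return_betas=True)
    conn.n5, conn.svd_vt = pca_scores_svd(conn.n4, d=d)
    conn.d = d
    cca = fit_cca(conn.n5, smp.s5)
    basis, *_ = np.linalg.lstsq(np.nan_to_num(s3), s5, rcond=None)
    return _TrainedPipeline(smp, conn, cca, sm_betas, conn_betas, basis)


def train_test_cca(
    s2: np.ndarray,
    n0: np.ndarray,
    confounds: np.ndarray,
    families: pd.DataFrame,
    split: SplitResult,
    d: int = 30,
    mode: str = "reestimate",
) -> tuple[float, np.ndarray, np.ndarray, _TrainedPipeline]:
    """Train the CCA on the training subjects and score the held-out set.

    Returns ``(r_test, u_test1, v_test1, trained)`` where ``r_test`` is the
    Pearson correlation of the held-out first-mode weights.
    """
    sid = families["subject_id"]
    tr = sid.isin(set(split.train_ids)).to_numpy()
    te = sid.isin(set(split.test_ids)).to_numpy()
    if te.sum() <= d:
        raise ValueError(
            f"test set of {int(te.sum())} subjects cannot support d={d}; reduce d"
        )
    trained = _fit_train(s2[tr], n0[tr], confounds[tr], d)
    if mode == "reestimate":
        s3_te = deconfound(s2[te], confounds[te], warn_rank=False)
        from .sm_prep import nearest_spd, pairwise_covariance, pca_scores_from_spd

        s4_te = nearest_spd(pairwise_covariance(s3_te))
        s5_te = pca_scores_from_spd(s4_te, d=d)
        smp_te = PreparedSM(s1=s2[te], s2=s2[te], s3=s3_te, s4=s4_te,
                            s5=s5_te, sm_names=None, d=d)
        s5_test = _sign_align_sm(trained.sm_prep, smp_te)
        conn_te = prepare_edge_features(n0[te])
        conn_te.n4 = deconfound(conn_te.n3, confounds[te], warn_rank=False)
        conn_te.n5, conn_te.svd_vt = pca_scores_svd(conn_te.n4, d=d)
        n5_test = _sign_align_conn(trained.conn_prep, conn_te)
    elif mode == "strict":
        s3_te = apply_deconfound(s2[te], confounds[te], trained.sm_betas)
        s5_test = np.nan_to_num(s3_te) @ trained.sm_feature_basis
        tr_conn = trained.conn_prep
        x = n0[te]
        n1 = (x - tr_conn.n1_center) / tr_conn.n1_scale
        keep = np.setdiff1d(np.arange(x.shape[1]), tr_conn.dropped_columns)
        x2 = x[:, keep] / np.abs(tr_conn.n1_center[keep])
        n2 = (x2 - tr_conn.n2_center) / tr_conn.n2_scale
        n4 = apply_deconfound(np.hstack([n1, n2]), confounds[te], trained.conn_betas)
        n5_test = n4 @ tr_conn.svd_vt.T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    u_test = n5_test @ trained.cca.a
    v_test = s5_test @ trained.cca.b
    u1 = u_test[:, 0] - u_test[:, 0].mean()
    v1 = v_test[:, 0] - v_test[:, 0].mean()
    r = float(u1 @ v1 / (np.linalg.norm(u1) * np.linalg.norm(v1)))
    return r, u_test[:, 0], v_test[:, 0], trained


def repeated_cv(
    s2: np.ndarray,
    n0: np.ndarray,
    confounds: np.ndarray,
    families: pd.DataFrame,
    reps: int = 10,
    perms: int = 1000,
    train_frac: float = 0.8,
    d: int = 30,
    mode: str = "reestimate",
    rng: np.random.Generator | None = None,
) -> CVReport:
    """Repeat the family-respecting split, training CCA and held-out test.

    Each repetition draws its own split, computes the held-out first-mode
    correlation, and calibrates it against ``perms`` permutations of the test
    subjects' SM-side weights within the test set's family structure
    (two-sided: ``p = (1 + #{|r_perm| >= |r|}) / (1 + perms)``).
    """
    if reps < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(rng)
    r_all, p_all, ntr, nte, null_means = [], [], [], [], []
    for _ in range(reps):
        split = family_split(families, train_frac=train_frac, rng=rng)
        r, u1, v1, _ = train_test_cca(
            s2, n0, confounds, families, split, d=d, mode=mode
        )
        te = families["subject_id"].isin(set(split.test_ids)).to_numpy()
        test_fams = families[te]
        blocks = build_blocks(test_fams.reset_index(drop=True))
        u1c = u1 - u1.mean()
        # permuted weights are re-residualized against the test confounds so
        # the null lives in the same constrained space as the observed pair
        qd, _ = np.linalg.qr(
            np.column_stack([np.ones(int(te.sum())), confounds[te]])
        )
        null_r = np.empty(perms)
        for b in range(perms):
            vp = v1[sample_permutation(blocks, rng)]
            vp = vp - qd @ (qd.T @ vp)
            vpc = vp - vp.mean()
            null_r[b] = u1c @ vpc / (np.linalg.norm(u1c) * np.linalg.norm(vpc))
        p = (1 + np.sum(np.abs(null_r) >= abs(r))) / (1 + perms)
        r_all.append(r)
        p_all.append(p)
        ntr.append(len(split.train_ids))
        nte.append(len(split.test_ids))
        null_means.append(null_r.mean())
    return CVReport(
        r_test=np.array(r_all),
        p=np.array(p_all),
        n_train=np.array(ntr),
        n_test=np.array(nte),
        null_mean_r=float(np.mean(null_means)),
    )
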