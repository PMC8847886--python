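"""Imaging-side quality control: framewise-displacement censoring and subject selection.

Resting-state runs are summarized by a per-time-point framewise displacement
(FD) trace in millimetres.  Time points moving more than ``fd_threshold`` are
flagged for removal, and any surviving run of consecutive low-motion points
shorter than ``min_segment`` is removed as well.  Subjects enter the analysis
only if they have enough good runs, enough post-censoring scan time, a usable
anatomical scan, and a mean FD that is not anomalous within the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MotionRun",
    "QCRecord",
    "censor_timepoints",
    "run_is_good",
    "select_subjects",
    "truncate_concatenate",
]

#: order in which exclusion criteria are attributed (first failure wins)
EXCLUSION_ORDER = ("good_runs", "post_censor", "t1_qc", "mean_fd_trim")


@dataclass
class MotionRun:
    """One resting-state run's head-motion trace.

    Parameters
    ----------
    subject_id : str
    run_index : int
        Acquisition order of the run within the subject's session.
    fd : ndarray
        Framewise displacement per time point, in mm (non-negative).
    expected_length : int
        Nominal number of time points of a complete run.
    """

    subject_id: str
    run_index: int
    fd: np.ndarray
    expected_length: int = 380

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ValueError("fd must be a 1-D vector")
        if np.any(self.fd < 0):
            raise ValueError("fd values must be non-negative")


@dataclass
class QCRecord:
    """Anatomical / protocol QC summary for one subject."""

    subject_id: str
    t1_pass: bool = True
    n_rest_runs_pass: int = field(default=4)


def censor_timepoints(
    fd: np.ndarray, fd_threshold: float = 0.3, min_segment: int = 5
) -> np.ndarray:
    """Boolean keep-mask for a framewise-displacement trace.

    Points with ``fd > fd_threshold`` (strict) are removed; surviving maximal
    runs of consecutive kept points shorter than ``min_segment`` are removed
    too, so every kept segment has length >= ``min_segment``.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("fd trace is empty")
    keep = fd <= fd_threshold
    # remove kept segments shorter than min_segment
    padded = np.concatenate([[False], keep, [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = changes[0::2], changes[1::2]
    for s, e in zip(starts, ends):
        if e - s < min_segment:
            keep[s:e] = False
    return keep


def run_is_good(
    run: MotionRun, fd_threshold: float = 0.3, min_frac: float = 0.5
) -> bool:
    """A run is 'good' iff mean FD < threshold (strict) and its pre-censoring
    length is at least ``ceil(min_frac * expected_length)`` time points."""
    min_len = int(np.ceil(min_frac * run.expected_length))
    return bool(np.mean(run.fd) < fd_threshold and run.fd.size >= min_len)


def _post_censor_points(
    runs: list[MotionRun], fd_threshold: float, min_segment: int
) -> int:
    return int(
        sum(censor_timepoints(r.fd, fd_threshold, min_segment).sum() for r in runs)
    )


def select_subjects(
    runs: list[MotionRun],
    qc: list[QCRecord],
    min_good_runs: int = 2,
    min_post_censor: int = 750,
    trim_frac: float = 0.0025,
    fd_threshold: float = 0.3,
    min_segment: int = 5,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the subject inclusion criteria in order and ledger exclusions.

    Criteria, attributed first-failure-first:

    1. ``good_runs``      — at least ``min_good_runs`` runs pass :func:`run_is_good`;
    2. ``post_censor``    — total censored-retained points across good runs
       >= ``min_post_censor``;
    3. ``t1_qc``          — anatomical QC pass;
    4. ``mean_fd_trim``   — subject mean FD (over good runs) strictly beyond the
       ``trim_frac`` / ``1 - trim_frac`` quantiles of the distribution over
       subjects surviving criteria 1-2.

    Returns the included subject ids (input order) and an exclusion ledger
    with one row per excluded subject (``subject_id``, ``reason``).
    """
    by_subject: dict[str, list[MotionRun]] = {}
    for r in runs:
        by_subject.setdefault(r.subject_id, []).append(r)
    qc_by_subject: dict[str, QCRecord] = {}
    for rec in qc:
        if rec.subject_id in qc_by_subject:
            raise ValueError(f"duplicate QC record for subject {rec.subject_id!r}")
        qc_by_subject[rec.subject_id] = rec

    subject_ids = list(by_subject)
    fail: dict[str, str] = {}
    mean_fd: dict[str, float] = {}
    survivors_12: list[str] = []
    for sid in subject_ids:
        good = [r for r in by_subject[sid] if run_is_good(r, fd_threshold)]
        if len(good) < min_good_runs:
            fail[sid] = "good_runs"
            continue
        if _post_censor_points(good, fd_threshold, min_segment) < min_post_censor:
            fail[sid] = "post_censor"
            continue
        survivors_12.append(sid)
        mean_fd[sid] = float(np.mean(np.concatenate([r.fd for r in good])))

    # FD trim bounds are computed over subjects surviving criteria 1-2
    if survivors_12 and trim_frac > 0:
        fds = np.array([mean_fd[s] for s in survivors_12])
        lo, hi = np.quantile(fds, [trim_frac, 1.0 - trim_frac])
    else:
        lo, hi = -np.inf, np.inf

    included: list[str] = []
    for sid in survivors_12:
        rec = qc_by_subject.get(sid)
        if rec is None or not rec.t1_pass:
            fail[sid] = "t1_qc"
        elif mean_fd[sid] < lo or mean_fd[sid] > hi:
            fail[sid] = "mean_fd_trim"
        else:
            included.append(sid)

    ledger = pd.DataFrame(
        [(sid, reason) for sid, reason in fail.items()],
        columns=["subject_id", "reason"],
    )
    assert len(included) + len(ledger) == len(subject_ids)
    return included, ledger


def truncate_concatenate(
    runs: list[MotionRun],
    masks: list[np.ndarray] | None = None,
    target_points: int = 750,
    fd_threshold: float = 0.3,
    min_segment: int = 5,
) -> np.ndarray:
    """Indices (run, time point) of the first ``target_points`` surviving frames.

    Runs are censored, concatenated in acquisition order, and truncated to
    exactly ``target_points``.  Returns an integer array of shape
    ``(target_points, 2)`` with (run position, within-run index) so callers can
    slice the matching imaging data.  Raises if fewer points survive.
    """
    runs = sorted(runs, key=lambda r: r.run_index)
    if masks is None:
        masks = [censor_timepoints(r.fd, fd_threshold, min_segment) for r in runs]
    pairs = [
        (pos, t)
        for pos, (r, m) in enumerate(zip(runs, masks))
        for t in np.flatnonzero(m)
    ]
    if len(pairs) < target_points:
        raise ValueError(
            f"only {len(pairs)} post-censor points available, "
            f"need {target_points}; subject should have been excluded"
        )
    return np.array(pairs[:target_points], dtype=int)
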