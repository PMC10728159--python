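"""Motion censoring, participant inclusion, run concatenation, rescaling.

Frames are censored when framewise displacement exceeds a threshold
(default 0.2 mm) or the global mean signal is a ±3 SD outlier; participants
with too few surviving frames (default 600) are excluded; runs are
concatenated in time; and each vertex's time course is shifted/scaled into
[0, 1] as non-negative matrix factorization requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CensorMask",
    "censor_frames",
    "apply_inclusion_filter",
    "concatenate_runs",
    "rescale_nonnegative",
    "EmptyCohortError",
]


class EmptyCohortError(RuntimeError):
    """Raised when inclusion filtering removes every participant."""


@dataclass(frozen=True)
class CensorMask:
    keep: np.ndarray        # (T,) bool
    fd_threshold: float     # mm
    outlier_sd: float

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))


def censor_frames(
    ts: np.ndarray,
    fd: np.ndarray,
    fd_threshold: float = 0.2,
    outlier_sd: float = 3.0,
) -> tuple[np.ndarray, CensorMask]:
    """Drop high-motion and global-signal-outlier frames.

    A frame is removed when its FD exceeds ``fd_threshold`` or the
    z-scored per-frame global mean signal lies beyond ``outlier_sd``
    standard deviations. Remaining frames keep their original order.
    """
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.shape[0]:
        raise ValueError("fd length must equal number of frames")
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be > 0")
    gms = ts.mean(axis=1)
    sd = gms.std()
    z = (gms - gms.mean()) / sd if sd > 0 else np.zeros_like(gms)
    keep = (fd <= fd_threshold) & (np.abs(z) <= outlier_sd)
    mask = CensorMask(keep=keep, fd_threshold=fd_threshold, outlier_sd=outlier_sd)
    return ts[keep], mask


def apply_inclusion_filter(
    cohort: list,
    masks: list[CensorMask],
    min_frames: int = 600,
) -> tuple[list, list[str]]:
    """Retain subjects with at least ``min_frames`` surviving frames.

    Returns ``(included, excluded_ids)``; raises :class:`EmptyCohortError`
    rather than returning silently when nobody survives.
    """
    if len(cohort) != len(masks):
        raise ValueError("one censor mask per subject required")
    included, excluded = [], []
    for subject, mask in zip(cohort, masks):
        if mask.n_kept >= min_frames:
            included.append(subject)
        else:
            excluded.append(getattr(subject, "subject_id", str(subject)))
    if cohort and not included:
        raise EmptyCohortError(
            f"all {len(cohort)} subjects fell below {min_frames} retained frames")
    return included, excluded


def concatenate_runs(runs: list[np.ndarray]) -> np.ndarray:
    """Row-stack runs in order; all runs must share the vertex dimension."""
    if not runs:
        raise ValueError("no runs to concatenate")
    n_cols = {r.shape[1] for r in runs}
    if len(n_cols) != 1:
        raise ValueError(f"runs disagree on vertex count: {sorted(n_cols)}")
    return np.vstack(runs)


def rescale_nonnegative(ts: np.ndarray) -> np.ndarray:
    """Shift and max-normalize each vertex's time course into [0, 1].

    Per vertex: subtract the minimum, divide by the maximum of the shifted
    course. Constant (zero-range) vertices map to all-zeros.
    """
    ts = np.asarray(ts, dtype=float)
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    shifted = ts - ts.min(axis=0, keepdims=True)
    peak = shifted.max(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(peak > 0, shifted / np.where(peak > 0, peak, 1.0), 0.0)
    return out
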