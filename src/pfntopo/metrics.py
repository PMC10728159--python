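"""Scalar summaries of personalized network topography.

Total cortical representation (sum of a network's loadings over all
vertices), hard-parcel sizes, per-network mean sensorimotor-association
axis rank, and split-half reliability of the loadings as ICC(2,1).
"""

from __future__ import annotations

import numpy as np

from .decomposition import UNASSIGNED

__all__ = [
    "total_cortical_representation",
    "mean_sa_rank",
    "zscore_ranks",
    "network_size",
    "split_half_icc",
]


def total_cortical_representation(V: np.ndarray) -> np.ndarray:
    """Per-network sum of loadings over all vertices (soft parcellation)."""
    return V.sum(axis=1)


def mean_sa_rank(labels: np.ndarray, sa_map: np.ndarray,
                 K: int | None = None) -> np.ndarray:
    """Average axis rank over each network's hard parcel.

    Unassigned vertices and medial-wall (NaN-ranked) vertices are excluded;
    an empty parcel yields NaN rather than an error.
    """
    if labels.shape != sa_map.shape:
        raise ValueError("labels and rank map must share the mesh")
    if K is None:
        K = int(labels.max()) + 1
    out = np.full(K, np.nan)
    valid = (labels != UNASSIGNED) & np.isfinite(sa_map)
    for k in range(K):
        sel = valid & (labels == k)
        if sel.any():
            out[k] = sa_map[sel].mean()
    return out


def zscore_ranks(mean_ranks: np.ndarray) -> np.ndarray:
    """Z-score the per-network mean ranks (NaN-aware), for display."""
    mu = np.nanmean(mean_ranks)
    sd = np.nanstd(mean_ranks)
    if sd == 0:
        return np.zeros_like(mean_ranks)
    return (mean_ranks - mu) / sd


def network_size(labels: np.ndarray, K: int | None = None) -> np.ndarray:
    """Vertex count of each hard parcel; unassigned vertices excluded."""
    if K is None:
        K = int(labels.max()) + 1
    assigned = labels[labels != UNASSIGNED]
    return np.bincount(assigned, minlength=K)[:K]


def _icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Targets are vertices, raters are the two halves. Computed from the
    two-way ANOVA mean squares.
    """
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    if n < 2:
        return np.nan
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def split_half_icc(V_a: np.ndarray, V_b: np.ndarray) -> np.ndarray:
    """Per-network split-half reliability of loadings, as ICC(2,1).

    ``V_a`` and ``V_b`` are K × N loading matrices estimated from the two
    halves of a subject's data. Networks with zero variance in both halves
    yield NaN.
    """
    if V_a.shape != V_b.shape:
        raise ValueError("split halves must share dimensions")
    return np.array([_icc_2_1(V_a[k], V_b[k]) for k in range(V_a.shape[0])])
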