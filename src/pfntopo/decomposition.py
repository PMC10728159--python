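"""Personalized functional networks by regularized non-negative matrix
factorization.

Each subject's rescaled vertex × time data ``X`` (stored here as T × N) is
factorized as ``X ≈ U V`` with nonnegative temporal weights ``U`` (T × K)
and network loadings ``V`` (K × N). Two penalties shape the loadings:

* a **group-consensus** term ``α‖V − V^g‖²_F`` pulling every subject's
  loadings toward a shared atlas ``V^g``, preserving network
  correspondence across people;
* a **data-locality** term ``β·tr(V L Vᵀ)`` with the graph Laplacian
  ``L = D − W`` of a mesh-adjacency graph weighted by clipped temporal
  correlation, encouraging spatially adjacent, temporally coherent
  vertices to receive similar loadings.

The objective

    F(U, V) = ‖X − U V‖²_F + α‖V − V^g‖²_F + β·tr(V L Vᵀ)

is minimized by multiplicative updates that keep every iterate nonnegative
and the objective non-increasing:

    U ← U ∘ (X Vᵀ) ⊘ (U V Vᵀ + ε)
    V ← V ∘ (Uᵀ X + α V^g + β V W) ⊘ (Uᵀ U V + α V + β V D + ε)

The group atlas itself is derived by repeated unregularized NMF on random
participant subsets, pooling all components, clustering them by
normalized-cuts spectral clustering on spatial correlation, and keeping
each cluster's most central exemplar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import nnls

from .synthetic import SurfaceMesh

__all__ = [
    "DecompositionConfig",
    "FitTrace",
    "build_locality_graph",
    "decomposition_objective",
    "fit_individual",
    "derive_group_atlas",
    "hard_parcellation",
    "match_networks",
    "UNASSIGNED",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class DecompositionConfig:
    alpha: float = 1.0        # group-consensus weight
    beta: float = 300.0       # data-locality weight
    max_iter: int = 1000
    rel_tol: float = 1e-6
    eps: float = 1e-10
    K: int = 17

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0 or self.eps <= 0:
            raise ValueError("rel_tol and eps must be > 0")


@dataclass
class FitTrace:
    objective: np.ndarray
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# locality graph


def build_locality_graph(mesh: SurfaceMesh, ts: np.ndarray) -> sp.csr_matrix:
    """Locality weights: clipped Pearson correlation on mesh-adjacent pairs.

    Returns a symmetric nonnegative sparse matrix W supported on the mesh
    adjacency, with negatives clipped to zero (keeping L = D − W positive
    semidefinite) and medial-wall vertices isolated.
    """
    if ts.shape[1] != mesh.n_vertices:
        raise ValueError("time series columns must match mesh vertices")
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 frames to correlate")
    z = ts - ts.mean(axis=0)
    sd = z.std(axis=0)
    ok = sd > 0
    z[:, ok] /= sd[ok]
    coo = sp.triu(mesh.adjacency, k=1).tocoo()
    r, c = coo.row, coo.col
    w = np.einsum("ij,ij->j", z[:, r], z[:, c]) / ts.shape[0]
    w[~(ok[r] & ok[c])] = 0.0
    w = np.clip(w, 0.0, 1.0)
    medial = mesh.medial_wall
    w[medial[r] | medial[c]] = 0.0
    W = sp.csr_matrix((np.concatenate([w, w]),
                       (np.concatenate([r, c]), np.concatenate([c, r]))),
                      shape=mesh.adjacency.shape)
    W.eliminate_zeros()
    return W


def graph_degree(W: sp.spmatrix) -> np.ndarray:
    return np.asarray(W.sum(axis=1)).ravel()


# ---------------------------------------------------------------------------
# objective


def decomposition_objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    Vg: np.ndarray | None = None,
    W: sp.spmatrix | None = None,
    alpha: float = 0.0,
    beta: float = 0.0,
) -> float:
    """F = ‖X − U V‖² + α‖V − V^g‖² + β·tr(V L Vᵀ), L = D − W."""
    if U.shape[0] != X.shape[0] or V.shape[1] != X.shape[1] or U.shape[1] != V.shape[0]:
        raise ValueError("inconsistent factor dimensions")
    obj = float(np.linalg.norm(X - U @ V, "fro") ** 2)
    if alpha > 0:
        if Vg is None or Vg.shape != V.shape:
            raise ValueError("consensus term requires Vg of matching shape")
        obj += alpha * float(np.linalg.norm(V - Vg, "fro") ** 2)
    if beta > 0:
        if W is None:
            raise ValueError("locality term requires graph weights")
        D = graph_degree(W)
        # tr(V L V^T) = sum_k v_k^T (D - W) v_k
        obj += beta * float(np.sum(V * (V * D) - V * (W @ V.T).T))
    return obj


# ---------------------------------------------------------------------------
# individual fit


def _nnls_rows(X: np.ndarray, Vg: np.ndarray) -> np.ndarray:
    """U init: per-frame nonnegative least squares of X onto the atlas rows."""
    A = Vg.T  # (N, K)
    U = np.empty((X.shape[0], Vg.shape[0]))
    for t in range(X.shape[0]):
        U[t], _ = nnls(A, X[t])
    return U


def fit_individual(
    X: np.ndarray,
    Vg: np.ndarray,
    W: sp.spmatrix,
    config: DecompositionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, FitTrace]:
    """Fit one subject's personalized loadings against the group atlas.

    ``X`` must be rescaled into [0, 1] (see
    :func:`pfntopo.qc.rescale_nonnegative`); ``V`` is initialized at the
    atlas and ``U`` by nonnegative projection of ``X`` onto it. Returns
    ``(U, V, trace)``.
    """
    if config is None:
        config = DecompositionConfig(K=Vg.shape[0])
    if X.min() < 0:
        raise ValueError("X must be nonnegative (rescale first)")
    if Vg.shape[1] != X.shape[1]:
        raise ValueError("atlas width must match X columns")
    if W.shape[0] != X.shape[1]:
        raise ValueError("graph size must match X columns")

    alpha, beta, eps = config.alpha, config.beta, config.eps
    V = Vg.copy()
    U = _nnls_rows(X, Vg)
    D = graph_degree(W)

    objs = [decomposition_objective(X, U, V, Vg, W, alpha, beta)]
    converged = False
    for _ in range(config.max_iter):
        # U update (plain NMF rule; U is untouched by the penalties)
        VVt = V @ V.T
        U *= (X @ V.T) / (U @ VVt + eps)
        # V update with consensus + locality terms
        num = U.T @ X
        den = (U.T @ U) @ V
        if alpha > 0:
            num += alpha * Vg
            den += alpha * V
        if beta > 0:
            num += beta * (W @ V.T).T
            den += beta * V * D
        V *= num / (den + eps)
        objs.append(decomposition_objective(X, U, V, Vg, W, alpha, beta))
        prev, cur = objs[-2], objs[-1]
        if prev > 0 and (prev - cur) / prev < config.rel_tol:
            converged = True
            break
    trace = FitTrace(objective=np.array(objs), n_iterations=len(objs) - 1,
                     converged=converged)
    return U, V, trace


# ---------------------------------------------------------------------------
# group atlas derivation


def _plain_nmf(X: np.ndarray, K: int, rng: np.random.Generator,
               max_iter: int = 200, rel_tol: float = 1e-5,
               eps: float = 1e-10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical multiplicative-update NMF with random uniform init.

    Returns (U, V, objective trajectory). With alpha=beta=0 the regularized
    updates in :func:`fit_individual` reduce to exactly these rules.
    """
    T, N = X.shape
    scale = np.sqrt(X.mean() / K) if X.mean() > 0 else 1.0
    U = rng.uniform(0.1, 1.0, size=(T, K)) * scale
    V = rng.uniform(0.1, 1.0, size=(K, N)) * scale
    objs = [float(np.linalg.norm(X - U @ V, "fro") ** 2)]
    for _ in range(max_iter):
        U *= (X @ V.T) / (U @ (V @ V.T) + eps)
        V *= (U.T @ X) / ((U.T @ U) @ V + eps)
        objs.append(float(np.linalg.norm(X - U @ V, "fro") ** 2))
        if objs[-2] > 0 and (objs[-2] - objs[-1]) / objs[-2] < rel_tol:
            break
    return U, V, np.array(objs)


def derive_group_atlas(
    subjects: list[np.ndarray],
    config: DecompositionConfig | None = None,
    n_runs: int = 5,
    seed: int = 0,
    subset_fraction: float = 0.5,
) -> np.ndarray:
    """Consensus group atlas by multi-run NMF fusion.

    Each run draws a random participant subset, row-stacks their rescaled
    data and runs unregularized NMF with a fresh random initialization. The
    pooled ``n_runs × K`` components are grouped into K clusters by
    normalized-cuts spectral clustering on their pairwise spatial
    correlation, and each cluster contributes its most central component
    (highest mean within-cluster similarity).
    """
    from sklearn.cluster import SpectralClustering

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config is None:
        config = DecompositionConfig()
    K = config.K
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(round(subset_fraction * len(subjects))))
    components = []
    for _ in range(n_runs):
        idx = rng.choice(len(subjects), size=n_sub, replace=False)
        stacked = np.vstack([subjects[i] for i in idx])
        _, V, _ = _plain_nmf(stacked, K, rng)
        components.append(V)
    if n_runs == 1:
        return components[0]
    pool = np.vstack(components)          # (n_runs*K, N)
    C = np.corrcoef(pool)
    np.nan_to_num(C, copy=False)
    affinity = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(affinity, 1.0)
    clust = SpectralClustering(n_clusters=K, affinity="precomputed",
                               assign_labels="discretize",
                               random_state=int(rng.integers(2**31)))
    labels = clust.fit_predict(affinity)
    reps = []
    for k in range(K):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            raise RuntimeError(f"component cluster {k} is empty; "
                               "networks not separable at this K")
        sub = C[np.ix_(members, members)]
        reps.append(pool[members[int(np.argmax(sub.mean(axis=1)))]])
    return np.vstack(reps)


# ---------------------------------------------------------------------------
# hard parcellation and matching


def hard_parcellation(V: np.ndarray) -> np.ndarray:
    """Label each vertex by its highest-loading network.

    Ties break toward the lowest network index; all-zero columns (medial
    wall included) get :data:`UNASSIGNED` (−1).
    """
    labels = np.argmax(V, axis=0).astype(np.int64)
    labels[V.max(axis=0) <= 0] = UNASSIGNED
    return labels


def match_networks(V_est: np.ndarray, V_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Best one-to-one matching of estimated to true networks.

    Hungarian assignment maximizing row-wise spatial correlation; returns
    (permutation mapping true index -> estimated index, mean matched
    correlation).
    """
    from scipy.optimize import linear_sum_assignment

    K = V_true.shape[0]
    C = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = V_est[i], V_true[j]
            sa, sb = a.std(), b.std()
            C[i, j] = 0.0 if sa == 0 or sb == 0 else float(np.corrcoef(a, b)[0, 1])
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return perm, float(C[rows, cols].mean())
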