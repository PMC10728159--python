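"""Synthetic cortical cohorts with known ground truth.

Every downstream stage of the pipeline (QC, NMF decomposition, topography
metrics, harmonization, prediction, spin testing) is exercised on cohorts
generated here: spherical icosphere meshes standing in for the cortical
surface, a group atlas of smooth nonnegative network maps, per-subject
topography deviations, nonnegative network time courses, framewise
displacement traces, and a cognition outcome with planted network,
covariate, site, and family effects.

The generator is a pure function of its configuration and seed: identical
inputs yield byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = [
    "SurfaceMesh",
    "CohortConfig",
    "GroundTruth",
    "SubjectRecord",
    "make_sphere_mesh",
    "make_group_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_sa_axis",
]

# AR(1) coefficient for network time courses; nonnegative innovations keep
# the temporal factor in NMF's admissible cone.
AR1_COEF = 0.4
# Framewise-displacement law: lognormal body with occasional spike frames,
# sized so that the 0.2 mm censoring threshold and the minimum-frame
# inclusion rule both bind on realistic cohorts.
FD_LOG_MU = np.log(0.08)
FD_LOG_SIGMA = 0.6
FD_SPIKE_FRACTION = 0.05
FD_SPIKE_FACTOR = 4.0


@dataclass(frozen=True)
class SurfaceMesh:
    """Spherical cortical surface mesh.

    Vertices lie on the unit sphere; ``hemisphere`` is 0 for left and 1 for
    right; ``medial_wall`` flags vertices excluded from cortical analysis.
    ``adjacency`` is the symmetric, irreflexive edge relation induced by
    shared triangle edges (boolean CSR matrix).
    """

    coords: np.ndarray          # (N, 3) unit vectors
    faces: np.ndarray           # (F, 3) vertex index triples
    hemisphere: np.ndarray      # (N,) int8, 0=left, 1=right
    medial_wall: np.ndarray     # (N,) bool
    adjacency: sp.csr_matrix    # (N, N) bool

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def cortex(self) -> np.ndarray:
        """Indices of non-medial-wall vertices."""
        return np.flatnonzero(~self.medial_wall)

    def validate(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("mesh vertices must have unit norm")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValueError("face indices out of range")
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must be irreflexive")


@dataclass(frozen=True)
class CohortConfig:
    """Generative configuration for a synthetic cohort.

    ``cognition_weights`` couples the outcome to each network's *true*
    total cortical representation; ``topography_jitter`` is the geodesic
    scale (radians) of per-subject network-seed displacement.
    """

    n_subjects: int = 200
    K: int = 8
    T: int = 150
    mesh_subdivisions: int = 3
    noise_sd: float = 0.1
    topography_jitter: float = 0.15
    cognition_weights: tuple[float, ...] | None = None
    covariate_effects: tuple[float, float, float] = (0.002, 0.1, -0.5)
    n_sites: int = 3
    site_effect_sd: float = 0.2
    family_fraction: float = 0.2
    family_sd: float = 0.3
    outcome_noise_sd: float = 0.5
    network_width_sd: float = 0.3
    concentration: float = 5.0
    medial_wall_fraction: float = 0.05
    seed: int = 0
    include_timeseries: bool = True

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.K, self.T, self.n_sites) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("noise_sd", "topography_jitter", "site_effect_sd",
                     "family_sd", "outcome_noise_sd", "network_width_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cognition_weights is not None and len(self.cognition_weights) != self.K:
            raise ValueError("cognition_weights must have length K")

    def weights_vector(self) -> np.ndarray:
        if self.cognition_weights is None:
            # default planted effect: outcome loads on the first network only,
            # sized so cognition correlates ~0.6 with that network's true TCR
            w = np.zeros(self.K)
            w[0] = 0.2
            return w
        return np.asarray(self.cognition_weights, dtype=float)


@dataclass
class SubjectRecord:
    """One participant: data, motion trace and covariates."""

    subject_id: str
    time_series: np.ndarray | None    # (T, N)
    fd_trace: np.ndarray              # (T,) mm
    age_months: float
    sex: int                          # 0/1
    site_id: str
    family_id: str
    cognition: np.ndarray             # (3,) general, exec fn, learning/memory

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd_trace))


@dataclass
class GroundTruth:
    """Generative ground truth for one cohort."""

    group_atlas: np.ndarray                 # (K, N)
    true_loadings: list[np.ndarray]         # per subject (K, N)
    true_temporal: list[np.ndarray]         # per subject (T, K)
    cognition_weights: np.ndarray           # (K,)
    covariate_effects: np.ndarray           # (3,) age, sex, mean FD
    site_offsets: dict[str, float]          # additive outcome offsets
    site_gains: dict[str, float]            # multiplicative loading gains
    family_intercepts: dict[str, float]

    def true_tcr(self) -> np.ndarray:
        """Subjects × K matrix of true total cortical representation."""
        return np.array([V.sum(axis=1) for V in self.true_loadings])


# ---------------------------------------------------------------------------
# mesh


def make_sphere_mesh(
    subdivisions: int = 3,
    two_hemispheres: bool = True,
    medial_wall_fraction: float = 0.05,
    seed: int = 0,
) -> SurfaceMesh:
    """Build an icosphere mesh (one per hemisphere) with a medial-wall cap.

    The right hemisphere mirrors the left across the sagittal (x = 0)
    plane. A contiguous polar cap of roughly ``medial_wall_fraction`` of
    each hemisphere's vertices is flagged as medial wall. ``seed`` is
    accepted for interface symmetry; the construction is deterministic.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if not 0 <= medial_wall_fraction < 0.5:
        raise ValueError("medial_wall_fraction must be in [0, 0.5)")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    coords_l = np.asarray(ico.vertices, dtype=float)
    coords_l /= np.linalg.norm(coords_l, axis=1, keepdims=True)
    faces_l = np.asarray(ico.faces, dtype=np.int64)
    n = coords_l.shape[0]

    if two_hemispheres:
        coords_r = coords_l.copy()
        coords_r[:, 0] *= -1.0
        coords = np.vstack([coords_l, coords_r])
        # mirroring reverses orientation; flip winding to keep outward normals
        faces_r = faces_l[:, ::-1] + n
        faces = np.vstack([faces_l, faces_r])
        hemisphere = np.repeat(np.array([0, 1], dtype=np.int8), n)
    else:
        coords = coords_l
        faces = faces_l
        hemisphere = np.zeros(n, dtype=np.int8)

    # medial wall: cap of nearest vertices around the -z pole of each hemisphere
    n_wall = int(round(medial_wall_fraction * n))
    medial = np.zeros(coords.shape[0], dtype=bool)
    if n_wall > 0:
        for h in np.unique(hemisphere):
            idx = np.flatnonzero(hemisphere == h)
            order = np.argsort(coords[idx, 2])  # most negative z first
            medial[idx[order[:n_wall]]] = True

    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adjacency = sp.csr_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)),
        shape=(coords.shape[0], coords.shape[0]),
    )
    adjacency.setdiag(False)
    adjacency.eliminate_zeros()

    mesh = SurfaceMesh(coords=coords, faces=faces, hemisphere=hemisphere,
                       medial_wall=medial, adjacency=adjacency)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# group atlas


def _bump_maps(mesh: SurfaceMesh, seed_points: np.ndarray,
               concentration: float) -> np.ndarray:
    """Geodesic bump per seed point: exp(c · (cosθ − 1)), zero on medial wall.

    θ is angular distance on the common unit sphere, so networks may span
    both hemispheres near the sagittal plane, as cortical networks do.
    """
    cosang = np.clip(seed_points @ mesh.coords.T, -1.0, 1.0)
    V = np.exp(concentration * (cosang - 1.0))
    V[:, mesh.medial_wall] = 0.0
    return V


def make_group_atlas(
    mesh: SurfaceMesh,
    K: int,
    concentration: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Group consensus atlas: K smooth geodesic bumps over the cortex.

    Seeds are chosen by farthest-point sampling from a random start so the
    networks tile the sphere; each row's maximum sits at its seed vertex,
    and in the large-``concentration`` limit rows approach one-hot seed
    indicators.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    cortex = mesh.cortex
    if K > cortex.size:
        raise ValueError("K exceeds number of non-medial vertices")
    rng = np.random.default_rng(seed)
    seeds = [cortex[rng.integers(cortex.size)]]
    # farthest-point sampling on chordal distance (monotone in geodesic)
    d = np.linalg.norm(mesh.coords[cortex] - mesh.coords[seeds[0]], axis=1)
    while len(seeds) < K:
        nxt = cortex[int(np.argmax(d))]
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(mesh.coords[cortex] - mesh.coords[nxt], axis=1))
    return _bump_maps(mesh, mesh.coords[np.array(seeds)], concentration)


def atlas_seed_points(mesh: SurfaceMesh, atlas: np.ndarray) -> np.ndarray:
    """Seed point of each network: the coordinates of its peak vertex."""
    return mesh.coords[np.argmax(atlas, axis=1)]


# ---------------------------------------------------------------------------
# subjects


def _displace_on_sphere(points: np.ndarray, angles: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Move each unit vector along a random tangent great circle by its angle."""
    out = np.empty_like(points)
    for i, (p, ang) in enumerate(zip(points, angles)):
        t = rng.standard_normal(3)
        t -= (t @ p) * p
        nrm = np.linalg.norm(t)
        if nrm < 1e-12:
            out[i] = p
            continue
        t /= nrm
        out[i] = np.cos(ang) * p + np.sin(ang) * t
    return out


def _ar1_nonneg(T: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative lag-1 autocorrelated network time courses."""
    innov = np.abs(rng.standard_normal((T, K)))
    U = np.empty((T, K))
    U[0] = innov[0]
    for t in range(1, T):
        U[t] = AR1_COEF * U[t - 1] + (1.0 - AR1_COEF) * innov[t]
    return U


def _fd_trace(T: int, rng: np.random.Generator) -> np.ndarray:
    fd = rng.lognormal(FD_LOG_MU, FD_LOG_SIGMA, size=T)
    spikes = rng.random(T) < FD_SPIKE_FRACTION
    fd[spikes] *= FD_SPIKE_FACTOR
    return fd


def simulate_subject(
    mesh: SurfaceMesh,
    group_atlas: np.ndarray,
    config: CohortConfig,
    subject_seed: int,
    *,
    site_gain: float = 1.0,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Simulate one subject's topography and signal.

    Returns ``(V_true, U_true, fd_trace)`` where ``V_true`` is the (K, N)
    personalized loading matrix obtained by jittering each network seed
    along a random geodesic, varying each network's spatial extent
    (a lognormal width multiplier of scale ``network_width_sd``, the main
    driver of between-subject total-representation differences), and
    regenerating its bump. ``U_true`` is the (T, K) nonnegative temporal
    factor (``None`` when the config skips time-series synthesis). The
    observed time series is ``U_true @ V_true + noise``; see
    :func:`subject_time_series`.
    """
    if group_atlas.shape[1] != mesh.n_vertices:
        raise ValueError("atlas does not match mesh")
    rng = np.random.default_rng(subject_seed)
    K = group_atlas.shape[0]
    seeds = atlas_seed_points(mesh, group_atlas)
    if config.topography_jitter > 0:
        angles = np.abs(rng.standard_normal(K)) * config.topography_jitter
        seeds = _displace_on_sphere(seeds, angles, rng)
    else:
        rng.standard_normal(K)  # keep stream aligned
    widths = np.exp(config.network_width_sd * rng.standard_normal(K))
    conc = config.concentration * widths
    V = np.vstack([_bump_maps(mesh, seeds[k:k + 1], conc[k]) for k in range(K)])
    V *= site_gain
    U = _ar1_nonneg(config.T, group_atlas.shape[0], rng) if config.include_timeseries else None
    fd = _fd_trace(config.T, rng)
    return V, U, fd


def subject_time_series(V: np.ndarray, U: np.ndarray, noise_sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    ts = U @ V
    if noise_sd > 0:
        ts = ts + noise_sd * rng.standard_normal(ts.shape)
    return ts


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(
    config: CohortConfig,
    mesh: SurfaceMesh | None = None,
) -> tuple[list[SubjectRecord], GroundTruth, SurfaceMesh]:
    """Simulate a full cohort with planted effect structure.

    The outcome model is::

        cognition_i = Σ_k w_k · TCR_k(V*_i) + b·(age, sex, meanFD)_i
                      + site offset + family intercept + noise

    Executive-function and learning/memory scores share the same network
    coupling attenuated by 0.7 and 0.5 with independent noise. Site effects
    enter both the outcome (additive offset) and the loadings (a small
    multiplicative gain), so harmonization has something real to remove.
    Sibling pairs share a family identifier and intercept.
    """
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_subjects + 2)
    rng = np.random.default_rng(child[0])

    if mesh is None:
        mesh = make_sphere_mesh(config.mesh_subdivisions,
                                medial_wall_fraction=config.medial_wall_fraction)
    atlas = make_group_atlas(mesh, config.K, config.concentration,
                             seed=int(rng.integers(2**31)))

    site_ids = [f"site{j:02d}" for j in range(config.n_sites)]
    site_offsets = {s: config.site_effect_sd * rng.standard_normal() for s in site_ids}
    site_gains = {s: float(np.exp(0.5 * config.site_effect_sd * rng.standard_normal()))
                  for s in site_ids}

    # family structure: a fraction of subjects are paired as siblings
    n = config.n_subjects
    n_pairs = int(config.family_fraction * n / 2)
    family_of = {}
    fam = 0
    perm = rng.permutation(n)
    for p in range(n_pairs):
        family_of[perm[2 * p]] = f"fam{fam:04d}"
        family_of[perm[2 * p + 1]] = f"fam{fam:04d}"
        fam += 1
    for i in range(n):
        if i not in family_of:
            family_of[i] = f"fam{fam:04d}"
            fam += 1
    family_ids = sorted(set(family_of.values()))
    family_intercepts = {f: config.family_sd * rng.standard_normal() for f in family_ids}

    weights = config.weights_vector()
    cov_eff = np.asarray(config.covariate_effects, dtype=float)
    domain_scale = np.array([1.0, 0.7, 0.5])

    subjects: list[SubjectRecord] = []
    true_V: list[np.ndarray] = []
    true_U: list[np.ndarray] = []
    for i in range(n):
        srng = np.random.default_rng(child[i + 2])
        site = site_ids[int(srng.integers(config.n_sites))]
        V, U, fd = simulate_subject(mesh, atlas, config,
                                    subject_seed=int(srng.integers(2**31)),
                                    site_gain=site_gains[site])
        ts = None
        if config.include_timeseries:
            ts = subject_time_series(V, U, config.noise_sd, srng)
        age = float(srng.uniform(108, 132))  # 9-11 years in months
        sex = int(srng.integers(2))
        mean_fd = float(np.mean(fd))
        tcr = V.sum(axis=1)
        base = weights @ tcr + cov_eff @ np.array([age, sex, mean_fd])
        base += site_offsets[site] + family_intercepts[family_of[i]]
        cognition = (domain_scale * base
                     + config.outcome_noise_sd * srng.standard_normal(3))
        subjects.append(SubjectRecord(
            subject_id=f"sub{i:04d}", time_series=ts, fd_trace=fd,
            age_months=age, sex=sex, site_id=site, family_id=family_of[i],
            cognition=cognition))
        true_V.append(V)
        true_U.append(U if U is not None else np.empty((0, config.K)))

    truth = GroundTruth(
        group_atlas=atlas, true_loadings=true_V, true_temporal=true_U,
        cognition_weights=weights, covariate_effects=cov_eff,
        site_offsets=site_offsets, site_gains=site_gains,
        family_intercepts=family_intercepts)
    return subjects, truth, mesh


# ---------------------------------------------------------------------------
# sensorimotor-association axis


def simulate_sa_axis(mesh: SurfaceMesh, seed: int = 0) -> np.ndarray:
    """Synthetic sensorimotor-association axis: a smooth rank map.

    A random low-order spherical-harmonic mixture (degrees 1-3) is
    evaluated at each vertex and converted to ranks 1..M over the M
    non-medial vertices; medial-wall vertices are NaN (unranked).
    """
    from scipy.special import sph_harm_y

    rng = np.random.default_rng(seed)
    x, y, z = mesh.coords.T
    theta = np.arccos(np.clip(z, -1, 1))       # polar angle
    phi = np.arctan2(y, x)                     # azimuth
    fieldv = np.zeros(mesh.n_vertices)
    for ell in range(1, 4):
        for m in range(-ell, ell + 1):
            c = rng.standard_normal() / ell
            Y = sph_harm_y(ell, abs(m), theta, phi)
            fieldv += c * (Y.real if m >= 0 else Y.imag)
    ranks = np.full(mesh.n_vertices, np.nan)
    cortex = mesh.cortex
    order = np.argsort(fieldv[cortex], kind="stable")
    ranks[cortex[order]] = np.arange(1, cortex.size + 1, dtype=float)
    return ranks
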