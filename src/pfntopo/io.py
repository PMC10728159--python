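"""Cohort, mesh and loading-matrix storage.

Native containers are HDF5 (time series, FD traces, mesh, loadings) plus a
TSV covariate table; both round-trip losslessly. GIFTI surfaces and CIFTI
dense time series can be imported when such files exist (nibabel), but the
pipeline never requires them.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .synthetic import SubjectRecord, SurfaceMesh

__all__ = [
    "COVARIATE_COLUMNS",
    "write_cohort",
    "read_cohort",
    "write_mesh",
    "read_mesh",
    "write_loadings",
    "read_loadings",
    "write_covariates",
    "read_covariates",
    "load_gifti_surface",
    "load_cifti_timeseries",
]

COVARIATE_COLUMNS = [
    "subject_id", "age_months", "sex", "site_id", "family_id", "mean_fd",
    "cog_general", "cog_execfn", "cog_learnmem",
]


def write_mesh(group: h5py.Group, mesh: SurfaceMesh) -> None:
    group.create_dataset("coords", data=mesh.coords)
    group.create_dataset("faces", data=mesh.faces)
    group.create_dataset("hemisphere", data=mesh.hemisphere)
    group.create_dataset("medial_wall", data=mesh.medial_wall)


def read_mesh(group: h5py.Group) -> SurfaceMesh:
    coords = group["coords"][()]
    faces = group["faces"][()]
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adjacency = sp.csr_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)),
        shape=(coords.shape[0], coords.shape[0]))
    adjacency.setdiag(False)
    adjacency.eliminate_zeros()
    return SurfaceMesh(coords=coords, faces=faces,
                       hemisphere=group["hemisphere"][()],
                       medial_wall=group["medial_wall"][()].astype(bool),
                       adjacency=adjacency)


def covariate_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": s.subject_id,
        "age_months": s.age_months,
        "sex": s.sex,
        "site_id": s.site_id,
        "family_id": s.family_id,
        "mean_fd": s.mean_fd,
        "cog_general": s.cognition[0],
        "cog_execfn": s.cognition[1],
        "cog_learnmem": s.cognition[2],
    } for s in subjects])


def write_covariates(path: str | Path, subjects: list[SubjectRecord]) -> None:
    covariate_frame(subjects).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing required columns: {missing}")
    return df


def write_cohort(path: str | Path, subjects: list[SubjectRecord],
                 mesh: SurfaceMesh, seed: int | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        f.attrs["n_subjects"] = len(subjects)
        write_mesh(f.create_group("mesh"), mesh)
        g_ts = f.create_group("timeseries")
        g_fd = f.create_group("fd")
        for s in subjects:
            if s.time_series is not None:
                d = g_ts.create_dataset(s.subject_id, data=s.time_series)
                d.attrs["T"], d.attrs["N"] = s.time_series.shape
            g_fd.create_dataset(s.subject_id, data=s.fd_trace)
    write_covariates(path.with_suffix(".covariates.tsv"), subjects)


def read_cohort(path: str | Path) -> tuple[list[SubjectRecord], SurfaceMesh]:
    path = Path(path)
    cov = read_covariates(path.with_suffix(".covariates.tsv")).set_index("subject_id")
    subjects = []
    with h5py.File(path, "r") as f:
        mesh = read_mesh(f["mesh"])
        for sid in f["fd"]:
            ts = None
            if "timeseries" in f and sid in f["timeseries"]:
                d = f["timeseries"][sid]
                ts = d[()]
                if ts.shape != (d.attrs["T"], d.attrs["N"]):
                    raise ValueError(f"dimension attributes disagree for {sid}")
            row = cov.loc[sid]
            subjects.append(SubjectRecord(
                subject_id=sid, time_series=ts, fd_trace=f["fd"][sid][()],
                age_months=float(row["age_months"]), sex=int(row["sex"]),
                site_id=str(row["site_id"]), family_id=str(row["family_id"]),
                cognition=np.array([row["cog_general"], row["cog_execfn"],
                                    row["cog_learnmem"]], dtype=float)))
    return subjects, mesh


def write_loadings(path: str | Path, atlas: np.ndarray | None = None,
                   subjects: dict[str, dict[str, np.ndarray]] | None = None,
                   seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        if atlas is not None:
            d = f.create_dataset("atlas/V", data=atlas)
            d.attrs["K"], d.attrs["N"] = atlas.shape
        for sid, mats in (subjects or {}).items():
            for name, M in mats.items():
                d = f.create_dataset(f"subjects/{sid}/{name}", data=M)


def read_loadings(path: str | Path) -> tuple[np.ndarray | None,
                                             dict[str, dict[str, np.ndarray]]]:
    with h5py.File(path, "r") as f:
        atlas = f["atlas/V"][()] if "atlas" in f else None
        subjects: dict[str, dict[str, np.ndarray]] = {}
        if "subjects" in f:
            for sid in f["subjects"]:
                subjects[sid] = {name: f["subjects"][sid][name][()]
                                 for name in f["subjects"][sid]}
    return atlas, subjects


def load_gifti_surface(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates and faces from a GIFTI surface file."""
    import nibabel as nib

    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return np.asarray(coords, float), np.asarray(faces, np.int64)


def load_cifti_timeseries(path: str | Path) -> np.ndarray:
    """Dense time-series matrix (T × grayordinates) from a CIFTI dtseries."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), float)
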