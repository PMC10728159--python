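"""End-to-end pipeline orchestration.

Runs simulate → QC → group atlas → per-subject decomposition → topography
metrics → harmonization → mixed-model association → ridge prediction →
spin test on one synthetic cohort, writing every stage artifact plus a
manifest (seed, config hash, per-stage checksums) into a run directory.
Re-running with ``resume=True`` skips stages whose outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition as dec
from . import harmonize as hz
from . import metrics as mt
from . import prediction as pred
from . import qc
from . import spin as sp_test
from .io import (covariate_frame, read_cohort, read_loadings, write_cohort,
                 write_loadings)
from .synthetic import CohortConfig, simulate_cohort, simulate_sa_axis

logger = logging.getLogger("pfntopo")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    decomposition: dec.DecompositionConfig = field(
        default_factory=lambda: dec.DecompositionConfig(K=8, max_iter=200))
    prediction: pred.PredictionConfig = field(
        default_factory=lambda: pred.PredictionConfig(n_repeats=5, n_perm=50))
    spin: sp_test.SpinConfig = field(
        default_factory=lambda: sp_test.SpinConfig(n_spins=200))
    fd_threshold: float = 0.2
    outlier_sd: float = 3.0
    min_frames: int = 30        # desk-scale analogue of the 600-TR rule
    atlas_runs: int = 3
    outcome: str = "cog_general"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 resume: bool = False) -> dict:
    """Execute the full analysis on a synthetic cohort; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "stages": {}}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in
                   ("cohort", "atlas", "sa", "predict", "spin")}

    def stage(name: str, outputs: list[Path], fn):
        if resume and outputs and all(p.exists() for p in outputs):
            logger.info("stage %s: resumed from existing outputs", name)
        else:
            logger.info("stage %s: running", name)
            try:
                fn()
            except Exception as e:
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
        manifest["stages"][name] = {
            "outputs": {p.name: _checksum(p) for p in outputs}}

    # --- simulate -----------------------------------------------------------
    cohort_h5 = out / "cohort.h5"
    cc = CohortConfig(**{**asdict(config.cohort), "seed": stage_seeds["cohort"]})

    def _simulate():
        subjects, truth, mesh = simulate_cohort(cc)
        write_cohort(cohort_h5, subjects, mesh, seed=cc.seed)
        np.save(out / "true_tcr.npy", truth.true_tcr())
        write_loadings(out / "true_loadings.h5", atlas=truth.group_atlas,
                       subjects={s.subject_id: {"V": V} for s, V in
                                 zip(subjects, truth.true_loadings)},
                       seed=cc.seed)
    stage("simulate", [cohort_h5, out / "true_loadings.h5"], _simulate)
    subjects, mesh = read_cohort(cohort_h5)

    # --- qc -----------------------------------------------------------------
    qc_tsv = out / "qc_report.tsv"

    def _qc():
        rows, masks = [], []
        for s in subjects:
            ts, mask = qc.censor_frames(s.time_series, s.fd_trace,
                                        config.fd_threshold, config.outlier_sd)
            s.time_series = qc.rescale_nonnegative(ts)
            masks.append(mask)
            rows.append({"subject_id": s.subject_id,
                         "n_frames_pre": mask.keep.size,
                         "n_frames_post": mask.n_kept,
                         "included": mask.n_kept >= config.min_frames})
        included, _ = qc.apply_inclusion_filter(subjects, masks,
                                                config.min_frames)
        pd.DataFrame(rows).to_csv(qc_tsv, sep="\t", index=False)
        _qc.included = included
    _qc.included = None
    stage("qc", [qc_tsv], _qc)
    if _qc.included is None:  # resumed: re-derive in memory
        _qc()
    kept = _qc.included

    # --- decomposition ------------------------------------------------------
    loadings_h5 = out / "loadings.h5"

    def _fit():
        data = [s.time_series for s in kept]
        atlas = dec.derive_group_atlas(data, config.decomposition,
                                       n_runs=config.atlas_runs,
                                       seed=stage_seeds["atlas"])
        per_subject = {}
        for s in kept:
            W = dec.build_locality_graph(mesh, s.time_series)
            U, V, _ = dec.fit_individual(s.time_series, atlas, W,
                                         config.decomposition)
            per_subject[s.subject_id] = {"V": V, "U": U}
        write_loadings(loadings_h5, atlas=atlas, subjects=per_subject,
                       seed=stage_seeds["atlas"])
    stage("fit", [loadings_h5], _fit)
    atlas, per_subject = read_loadings(loadings_h5)
    V_by_id = {sid: mats["V"] for sid, mats in per_subject.items()}

    # --- metrics ------------------------------------------------------------
    sa_map = simulate_sa_axis(mesh, seed=stage_seeds["sa"])
    metrics_tsv = out / "metrics.tsv"

    def _metrics():
        rows = []
        for s in kept:
            V = V_by_id[s.subject_id]
            labels = dec.hard_parcellation(V)
            tcr = mt.total_cortical_representation(V)
            sizes = mt.network_size(labels, V.shape[0])
            ranks = mt.mean_sa_rank(labels, sa_map, V.shape[0])
            for k in range(V.shape[0]):
                rows.append({"subject_id": s.subject_id, "network_id": k,
                             "total_representation": tcr[k],
                             "parcel_size": sizes[k],
                             "mean_sa_rank": ranks[k]})
        pd.DataFrame(rows).to_csv(metrics_tsv, sep="\t", index=False)
    stage("metrics", [metrics_tsv], _metrics)
    metrics_df = pd.read_csv(metrics_tsv, sep="\t")

    # --- harmonize + associate ---------------------------------------------
    cov = covariate_frame(kept)
    tcr_wide = metrics_df.pivot(index="subject_id", columns="network_id",
                                values="total_representation").loc[cov["subject_id"]]
    assoc_tsv = out / "associations.tsv"

    def _associate():
        protected = np.column_stack([
            cov["age_months"].to_numpy(float), cov["sex"].to_numpy(float),
            hz.family_protect_design(cov["family_id"].to_numpy())])
        harmonized, _ = hz.combat_harmonize(tcr_wide.to_numpy(),
                                            cov["site_id"].to_numpy(),
                                            protected, parametric_eb=True)
        rows = []
        for k in range(harmonized.shape[1]):
            res = hz.fit_total_representation_model(
                harmonized[:, k], cov[config.outcome].to_numpy(float),
                cov["age_months"].to_numpy(float), cov["sex"].to_numpy(float),
                cov["mean_fd"].to_numpy(float), cov["family_id"].to_numpy(),
                n_comparisons=harmonized.shape[1])
            row = res.table.loc["cognition"].to_dict()
            row["network_id"] = k
            row["group_var"] = res.group_var
            rows.append(row)
        pd.DataFrame(rows).to_csv(assoc_tsv, sep="\t", index=False)
    stage("associate", [assoc_tsv], _associate)

    # --- predict (all networks + per network) -------------------------------
    predict_json = out / "prediction.json"
    loadings_list = [V_by_id[s.subject_id] for s in kept]
    y = cov[config.outcome].to_numpy(float)
    covd = pred.encode_covariates(cov["age_months"], cov["sex"],
                                  cov["site_id"], cov["mean_fd"])

    def _predict():
        rng_p = np.random.default_rng(stage_seeds["predict"])
        n = len(kept)
        perm = rng_p.permutation(n)
        a, b = perm[: n // 2], perm[n // 2:]
        X = pred.prepare_features(loadings_list)
        cfg = config.prediction
        ra, rb = pred.run_nested_2fcv(X[a], y[a], X[b], y[b], cfg,
                                      covd[a], covd[b],
                                      seed=int(rng_p.integers(2**31)))
        null = pred.permutation_null(X[a], y[a], X[b], y[b], cfg,
                                     covd[a], covd[b])
        per_net = pred.per_network_accuracy(
            [loadings_list[i] for i in a], y[a],
            [loadings_list[i] for i in b], y[b], cfg, covd[a], covd[b])
        report = {
            "seed": config.seed,
            "all_networks": {"r_ab": ra.r, "r_ba": rb.r,
                             "mae_ab": ra.mae, "mae_ba": rb.mae,
                             "lambda_ab": ra.chosen_lambda,
                             "lambda_ba": rb.chosen_lambda,
                             "perm_p": null.p_value},
            "per_network_r": [0.5 * (x.r + z.r) for x, z in per_net],
        }
        predict_json.write_text(json.dumps(report, indent=2))
    stage("predict", [predict_json], _predict)
    report = json.loads(predict_json.read_text())

    # --- spin ----------------------------------------------------------------
    spin_json = out / "spin.json"

    def _spin():
        group_labels = dec.hard_parcellation(atlas)
        res = sp_test.spin_spearman_test(
            np.asarray(report["per_network_r"]), sa_map, group_labels, mesh,
            sp_test.SpinConfig(n_spins=config.spin.n_spins,
                               seed=stage_seeds["spin"]))
        spin_json.write_text(json.dumps({
            "seed": config.seed, "rho_observed": res.rho_observed,
            "p_spin": res.p_spin, "n_valid_spins": res.n_valid_spins,
            "null_rhos": res.null_rhos.tolist()}, indent=2))
    stage("spin", [spin_json], _spin)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
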