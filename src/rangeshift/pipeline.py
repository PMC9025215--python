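"""Config-driven orchestration of the full workflow.

``run_pipeline`` executes: cleaning -> study area -> thinning (geographic
and, optionally, environmental) -> predictor derivation and collinearity
screening -> background sampling -> spatial blocks -> per-algorithm fitting
and evaluation -> TSS gating -> ensembles -> threshold selection ->
per-scenario projection with clamping/uncertainty masks -> range-change,
centroid and altitude statistics. A JSON manifest records the config hash,
per-stage record counts and artifact paths, so identical config + seed
reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rangeshift import __version__, evaluation, models, occurrence_prep, predictors, range_dynamics, synthetic_data
from rangeshift.ensemble_projection import (
    ENSEMBLE_METHODS,
    EnsembleSpec,
    Member,
    apply_clamping,
    apply_uncertainty,
    choose_best_ensemble,
    clamping_mask,
    combine,
    gate_members,
    uncertainty_mask,
)
from rangeshift.grid import KM_PER_DEGREE

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "synthetic"
    seed: int = 0
    grid_shape: tuple[int, int] = (80, 80)
    cellsize: float = 0.1
    n_raw_occurrences: int = 700
    contamination: dict = dataclasses.field(
        default_factory=lambda: {"pre1970": 0.05, "high_uncertainty": 0.05, "duplicate": 0.05}
    )
    min_year: int = 1970
    max_uncertainty_km: float = 9.25
    alpha: float = 2.0
    buffer_km: float = 250.0
    thin_dist_km: float | None = None  # default: one cell diagonal
    thin_reps: int = 5
    n_env_bins: int = 25
    thinning: tuple[str, ...] = ("geo", "env")
    corr_max: float = 0.7
    vif_max: float = 10.0
    n_background: int = 3000
    algorithms: tuple[str, ...] = ("maxent", "RF", "BRT", "bagged_trees")
    tss_min: float = 0.6
    ensemble_methods: tuple[str, ...] = ENSEMBLE_METHODS
    threshold_rule: str = "maxSSS"  # or "maxSorensen"
    maxent_combos: tuple[tuple[str, ...], ...] = (("L", "Q"), ("L", "Q", "H"))
    maxent_reg_mults: tuple[float, ...] = (1.0, 2.0, 5.0)
    nperm: int = 10
    uncertainty_quantile: float = 0.90
    layer_menu: tuple[str, ...] | None = None  # None -> predictors.DEFAULT_LAYER_MENU
    scenarios: list[dict] | None = None  # None -> synthetic_data.default_scenarios()
    write_maps: bool = False
    outdir: str = "runs/latest"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in doc:
            doc["grid_shape"] = tuple(doc["grid_shape"])
        for key in ("thinning", "algorithms", "ensemble_methods", "maxent_reg_mults"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "maxent_combos" in doc:
            doc["maxent_combos"] = tuple(tuple(c) for c in doc["maxent_combos"])
        return cls(**doc)


def _fit_algorithm(algo: str, cfg: RunConfig, Xp, Xb, pres_folds, bg_folds, names, seed: int):
    """Returns (full-data model, fit closure for CV)."""
    if algo == "maxent":
        fc, rm, board = models.tune_maxent(
            Xp, Xb, pres_folds, bg_folds,
            feature_combos=cfg.maxent_combos,
            reg_mults=np.asarray(cfg.maxent_reg_mults),
            variable_names=names,
        )
        logger.info("maxent tuning winner: %s @ %.1f", "".join(fc), rm)

        def fit_fn(Xp_, Xb_):
            return models.fit_maxent(Xp_, Xb_, feature_classes=fc, reg_mult=rm, variable_names=names)

        model = fit_fn(Xp, Xb)
        model.importance = models.permutation_importance(model, Xp, Xb, nperm=cfg.nperm, seed=seed)
        return model, fit_fn, {"feature_classes": "".join(fc), "reg_mult": rm, "n_candidates": len(board)}
    if algo in ("RF", "BRT"):
        model = models.fit_tree_model(
            algo, Xp, Xb, pres_folds, bg_folds, variable_names=names, nperm=cfg.nperm, seed=seed
        )

        def fit_fn(Xp_, Xb_, model=model):
            idx = model.variable_index
            est = models._fit_est(algo, model.hyperparams, Xp_[:, idx], Xb_[:, idx], seed)
            return models.TreeModel(est, model.variable_names, idx, algorithm=algo)

        return model, fit_fn, {"hyperparams": model.hyperparams, "variables": model.variable_names}
    if algo == "bagged_trees":
        def fit_fn(Xp_, Xb_):
            return models.fit_bootstrap_ensemble(Xp_, Xb_, variable_names=names, seed=seed)

        model = fit_fn(Xp, Xb)
        model.importance = models.permutation_importance(model, Xp, Xb, nperm=cfg.nperm, seed=seed)
        return model, fit_fn, {}
    raise ValueError(f"unknown algorithm {algo!r}")


def _member_fold_scores(fit_fn, Xp, Xb, pres_folds, bg_folds):
    """Per-fold held-out (presence scores, background scores)."""
    out = {}
    for k in np.unique(pres_folds):
        m = fit_fn(Xp[pres_folds != k], Xb[bg_folds != k])
        out[int(k)] = (m.predict(Xp[pres_folds == k]), m.predict(Xb[bg_folds == k]))
    return out


def _evaluate_ensemble_cv(method, member_fold_scores, member_tss, member_thresholds, folds):
    per_fold = []
    for k in folds:
        pres_stack = [member_fold_scores[i][k][0] for i in range(len(member_fold_scores))]
        bg_stack = [member_fold_scores[i][k][1] for i in range(len(member_fold_scores))]
        pres = combine(pres_stack, method, weights=member_tss, thresholds=member_thresholds)
        bg = combine(bg_stack, method, weights=member_tss, thresholds=member_thresholds)
        per_fold.append(evaluation.score_predictions(pres, bg))
    return evaluation.build_report(per_fold)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written to disk)."""
    cfg = config
    if cfg.mode != "synthetic":
        raise NotImplementedError("only synthetic mode is wired in this build")
    if cfg.tss_min > 1.0:
        raise ValueError(f"gate tss_min={cfg.tss_min} can never be met (TSS <= 1)")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stage_counts": {},
        "artifacts": {},
        "stages": {},
    }
    counts = manifest["stage_counts"]

    # --- synthetic inputs -------------------------------------------------
    grid = synthetic_data.default_grid(cfg.grid_shape, cfg.cellsize)
    elevation = synthetic_data.gen_elevation(cfg.seed, cfg.grid_shape, grid=grid)
    current = synthetic_data.gen_climate(cfg.seed, cfg.grid_shape, grid=grid, elevation=elevation)
    scen_params = (
        [synthetic_data.ScenarioParams(**s) for s in cfg.scenarios]
        if cfg.scenarios is not None
        else synthetic_data.default_scenarios()
    )
    truth = synthetic_data.true_suitability(current)
    contamination = synthetic_data.Contamination(**cfg.contamination)
    raw = synthetic_data.sample_occurrences(truth, cfg.n_raw_occurrences, cfg.seed + 1, contamination)
    counts["raw"] = len(raw)

    # --- cleaning and study area -----------------------------------------
    filtered = occurrence_prep.filter_records(raw, cfg.min_year, cfg.max_uncertainty_km)
    counts["filtered"] = len(filtered)
    deduped = occurrence_prep.dedupe_by_cell(filtered, grid)
    counts["deduped"] = len(deduped)
    study_area = occurrence_prep.alpha_hull_eoo(deduped, alpha=cfg.alpha, buffer_km=cfg.buffer_km)
    thin_dist = cfg.thin_dist_km if cfg.thin_dist_km is not None else cfg.cellsize * np.sqrt(2) * KM_PER_DEGREE
    geothin = occurrence_prep.spatial_thin(deduped, thin_dist, n_reps=cfg.thin_reps, seed=cfg.seed + 2)
    counts["geothin"] = len(geothin)

    # --- predictors -------------------------------------------------------
    terrain = predictors.terrain_vars(elevation)
    menu = cfg.layer_menu if cfg.layer_menu is not None else predictors.DEFAULT_LAYER_MENU
    cur_stack = predictors.build_stack(current, elevation, terrain, layer_menu=menu)
    import shapely as _shp

    lon_mesh, lat_mesh = grid.lonlat_mesh()
    area_mask = _shp.contains_xy(study_area.polygon, lon_mesh.ravel(), lat_mesh.ravel()).reshape(grid.shape)
    cur_stack.record_training_range(area_mask)

    background = models.make_background(study_area, grid, n=cfg.n_background, seed=cfg.seed + 3)
    sample_pts = pd.concat([geothin[["lon", "lat"]], background], ignore_index=True)
    retained = predictors.vifcor_select(cur_stack, sample_pts, cfg.corr_max, cfg.vif_max)
    manifest["stages"]["retained_predictors"] = retained
    logger.info("retained %d/%d predictors: %s", len(retained), len(cur_stack.names), retained)

    datasets = {"geo": geothin}
    if "env" in cfg.thinning:
        env_at_records = cur_stack.subset(retained).extract(
            geothin["lon"].to_numpy(), geothin["lat"].to_numpy()
        )
        envthin = occurrence_prep.env_thin(
            geothin, env_at_records, n_bins_per_var=cfg.n_env_bins, seed=cfg.seed + 4
        )
        counts["envthin"] = len(envthin)
        datasets["env"] = envthin
    datasets = {k: v for k, v in datasets.items() if k in cfg.thinning}

    Xb = cur_stack.subset(retained).extract(
        background["lon"].to_numpy(), background["lat"].to_numpy()
    ).to_numpy()
    bg_ok = np.all(np.isfinite(Xb), axis=1)
    Xb = Xb[bg_ok]
    background = background.loc[bg_ok].reset_index(drop=True)

    grid_matrix = cur_stack.subset(retained).matrix(retained)
    grid_valid = np.all(np.isfinite(grid_matrix), axis=1) & area_mask.ravel()

    with open(outdir / "study_area.geojson", "w") as fh:
        json.dump(occurrence_prep.study_area_to_geojson(study_area), fh)
    manifest["artifacts"]["study_area"] = str(outdir / "study_area.geojson")

    results: dict[str, dict] = {}
    for branch, records in datasets.items():
        branch_out = _run_branch(
            cfg, branch, records, retained, cur_stack, grid, grid_matrix, grid_valid,
            background, Xb, elevation, terrain, current, scen_params, outdir, manifest,
        )
        results[branch] = branch_out

    manifest["branches"] = {k: v["summary"] for k, v in results.items()}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest


def _run_branch(cfg, branch, records, retained, cur_stack, grid, grid_matrix, grid_valid,
                background, Xb, elevation, terrain, current, scen_params, outdir, manifest):
    """Model fitting, ensembling and projection for one thinning branch."""
    Xp = cur_stack.subset(retained).extract(
        records["lon"].to_numpy(), records["lat"].to_numpy()
    ).to_numpy()
    ok = np.all(np.isfinite(Xp), axis=1)
    records = records.loc[ok]
    Xp = Xp[ok]
    pres_folds, bg_folds = models.spatial_blocks(records, background)

    members_all: list[Member] = []
    fold_scores_all = []
    algo_meta = {}
    for algo in cfg.algorithms:
        model, fit_fn, meta = _fit_algorithm(
            algo, cfg, Xp, Xb, pres_folds, bg_folds, retained, cfg.seed + 10
        )
        report = models.evaluate_model_cv(fit_fn, Xp, Xb, pres_folds, bg_folds)
        members_all.append(Member(model=model, evaluation=report))
        fold_scores_all.append(_member_fold_scores(fit_fn, Xp, Xb, pres_folds, bg_folds))
        meta["tss"] = report.tss
        meta["importance"] = model.importance
        algo_meta[algo] = meta
        logger.info("[%s] %s: CV TSS=%.3f AUC=%.3f", branch, algo, report.tss, report.auc)

    gated = gate_members(members_all, cfg.tss_min)
    if not gated:
        raise RuntimeError(
            f"ensemble gate: no member model reached TSS >= {cfg.tss_min} "
            f"(best was {max(m.tss for m in members_all):.3f})"
        )
    gated_idx = [i for i, m in enumerate(members_all) if m in gated]
    fold_scores = [fold_scores_all[i] for i in gated_idx]
    member_tss = [m.tss for m in gated]
    member_thr = [m.maxsss_threshold for m in gated]
    folds = sorted(fold_scores[0])

    candidates = []
    for method in cfg.ensemble_methods:
        rep = _evaluate_ensemble_cv(method, fold_scores, member_tss, member_thr, folds)
        candidates.append((EnsembleSpec(method, gated_idx, member_tss, cfg.tss_min), rep))
    best_spec, best_rep = choose_best_ensemble(candidates)
    logger.info("[%s] best ensemble: %s (TSS=%.3f)", branch, best_spec.method, best_rep.tss)

    # full-data member maps on the current grid
    def project(matrix, valid):
        maps = []
        for m in gated:
            vals = np.full(matrix.shape[0], np.nan)
            vals[valid] = m.model.predict(matrix[valid])
            maps.append(vals.reshape(grid.shape))
        return maps

    member_maps = project(grid_matrix, grid_valid)
    ens_current = combine(member_maps, best_spec.method, weights=member_tss, thresholds=member_thr)

    ens_pres = np.concatenate([m.model.predict(Xp)[None] for m in gated]).T
    ens_bg = np.concatenate([m.model.predict(Xb)[None] for m in gated]).T
    pres_scores = combine(list(ens_pres.T), best_spec.method, weights=member_tss, thresholds=member_thr)
    bg_scores = combine(list(ens_bg.T), best_spec.method, weights=member_tss, thresholds=member_thr)
    obs = np.concatenate([np.ones(len(pres_scores), int), np.zeros(len(bg_scores), int)])
    scores = np.concatenate([pres_scores, bg_scores])
    thresholds = {
        "maxSSS": evaluation.threshold_maxSSS(obs, scores),
        "maxSorensen": evaluation.threshold_maxSorensen(obs, scores),
    }
    threshold = thresholds[cfg.threshold_rule]
    current_bmap = range_dynamics.binarize(ens_current, threshold, grid=grid, scenario="current")

    # --- scenario projections --------------------------------------------
    reports = []
    centroids = {"current": range_dynamics.median_centroid(current_bmap)}
    alt_groups_by_time: dict[str, dict[str, np.ndarray]] = {}
    cur_alt = range_dynamics.altitude_samples(current_bmap, elevation)
    rows = []
    for sp in scen_params:
        scen = synthetic_data.gen_climate(cfg.seed, cfg.grid_shape, scenario_params=sp, grid=grid, elevation=elevation)
        scen_stack = predictors.build_stack(scen, elevation, terrain).subset(
            [n for n in retained]
        )
        clamp = clamping_mask(scen_stack, cur_stack.training_range, names=retained)
        scen_matrix = scen_stack.matrix(retained)
        scen_valid = np.all(np.isfinite(scen_matrix), axis=1) & grid_valid
        scen_maps = project(scen_matrix, scen_valid)
        ens_future = combine(scen_maps, best_spec.method, weights=member_tss, thresholds=member_thr)
        ens_future = apply_clamping(ens_future, clamp)
        unc_members = [m for m in gated if m.model.uncertainty(np.zeros((1, len(retained)))) is not None]
        if unc_members:
            unc = np.full(scen_matrix.shape[0], np.nan)
            unc[scen_valid] = np.mean(
                [m.model.uncertainty(scen_matrix[scen_valid]) for m in unc_members], axis=0
            )
            umask = uncertainty_mask(unc.reshape(grid.shape), cfg.uncertainty_quantile)
            ens_future = apply_uncertainty(ens_future, umask)
        fut_bmap = range_dynamics.binarize(ens_future, threshold, grid=grid, scenario=sp.name)
        rep = range_dynamics.range_change(current_bmap, fut_bmap)
        rep.occ_lost_pct = range_dynamics.occurrences_lost(records, fut_bmap, current_bmap)
        rep.centroid = range_dynamics.median_centroid(fut_bmap)
        rep.mean_altitude_m = range_dynamics.mean_altitude(fut_bmap, elevation)
        reports.append(rep)
        centroids[sp.name] = rep.centroid
        alt_groups_by_time.setdefault(sp.time_slice, {})[f"{sp.gcm}_{sp.ssp}"] = (
            range_dynamics.altitude_samples(fut_bmap, elevation)
        )
        row = rep.to_row()
        row.update({"gcm": sp.gcm, "ssp": sp.ssp, "time_slice": sp.time_slice})
        rows.append(row)
        if cfg.write_maps:
            range_dynamics.transition_map(current_bmap, fut_bmap).write_ascii(
                outdir / f"{branch}_transition_{sp.name}.asc"
            )

    table = pd.DataFrame(rows)
    agg = range_dynamics.aggregate_scenarios(table)
    dist = range_dynamics.centroid_distance_matrix(centroids)
    shift_results = {}
    for ts, groups in alt_groups_by_time.items():
        res = range_dynamics.shift_tests({"current": cur_alt, **groups})
        shift_results[ts] = {"kw_stat": res.kw_stat, "kw_df": res.kw_df, "kw_p": res.kw_p}

    table_path = outdir / f"{branch}_range_change.csv"
    table.to_csv(table_path, index=False)
    agg.to_csv(outdir / f"{branch}_range_change_means.csv", index=False)
    dist.to_csv(outdir / f"{branch}_centroid_distances_km.csv")

    summary = {
        "n_records": int(len(records)),
        "algorithms": algo_meta,
        "gated": [m.model.algorithm for m in gated],
        "best_ensemble": best_spec.method,
        "ensemble_tss": best_rep.tss,
        "thresholds": thresholds,
        "mean_altitude_current_m": float(np.mean(cur_alt)),
        "centroid_current": centroids["current"],
        "shift_tests": shift_results,
        "tables": {"range_change": str(table_path)},
    }
    return {"summary": summary, "table": table, "aggregate": agg, "centroids": centroids,
            "distance_matrix": dist, "current_map": current_bmap}
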