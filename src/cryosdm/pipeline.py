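"""End-to-end analysis orchestration.

The analysis proceeds: crop and reproject environmental stacks onto the
polar equal-area grid -> build the coastal study mask -> resolve
occurrences to presence cells -> pool the target-group background -> VIF
covariate screening -> per-species MaxEnt fit (optionally tuned by
cross-validation) -> evaluation (spatial-block AUC and Boyce,
cross-validated max-SSS threshold) -> projection onto every scenario ->
category stacks and change maps -> area tables by latitude cut.

`run_analysis` works on in-memory objects; `run_pipeline` drives it from a
YAML config and raster/CSV files and writes every artifact (models, eval
reports, rasters, area tables, manifest) to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import env_grid, evaluation, maxent, projection, synthetic
from .covariates import CovariateMatrix, VifReport, extract, vif_select
from .errors import CryosdmError, FoldError, ValidationError
from .grid import EnvLayer, ScenarioStack, StudyMask
from .maxent import FeatureSpec, MaxEntModel
from .occurrences import (
    BackgroundCells,
    PresenceCells,
    dedup_to_cells,
    presence_table,
    read_occurrences,
    target_group_background,
)
from .raster_io import write_ascii_grid

log = logging.getLogger(__name__)


def species_seed(master_seed: int, species: str) -> int:
    """Stable per-species seed derived by hashing the species name."""
    return int((zlib.crc32(species.encode()) ^ (master_seed * 2654435761)) % 2**31)


@dataclass
class ModelSettings:
    """Per-run modelling choices (defaults mirror the package defaults)."""

    covariates: tuple[str, ...] = synthetic.LAYER_NAMES
    vif_threshold: float = 10.0
    tune: bool = False
    spec_grid: tuple[FeatureSpec, ...] = maxent.DEFAULT_SPEC_GRID
    beta_grid: tuple[float, ...] = maxent.DEFAULT_BETA_GRID
    default_spec: FeatureSpec = field(default_factory=FeatureSpec)
    default_beta: float = 1.0
    cv_folds: int = 5
    block_size_km: float = 300.0
    eval_cv: bool = True
    boyce_windows: int = 101
    boyce_window_frac: float = 0.1
    output_transform: str = "logistic"
    lat_cutoffs: tuple[float, ...] = projection.DEFAULT_LAT_CUTOFFS


@dataclass
class SpeciesResult:
    presences: PresenceCells
    model: MaxEntModel
    tuning: maxent.TuningResult | None
    report: evaluation.EvalReport
    contributions: dict[str, float]


@dataclass
class AnalysisResult:
    mask: StudyMask
    lats: np.ndarray
    background: BackgroundCells
    vif: VifReport
    retained_covariates: list[str]
    species: dict[str, SpeciesResult]
    categories: dict[str, str]
    projections: dict[tuple[str, str], projection.RangeProjection]
    stacked: dict[tuple[str, str], projection.StackedProjection]
    area_thresholded: pd.DataFrame
    area_probabilistic: pd.DataFrame
    prepared_stacks: dict[str, ScenarioStack] = field(default_factory=dict)

    def stacked_area(self, category: str, scenario_id: str, cutoff: float = 30) -> float:
        t = self.area_thresholded
        row = t[
            (t["name"] == f"stacked_{category}")
            & (t["scenario_id"] == scenario_id)
            & (t["lat_cutoff_deg"] == cutoff)
        ]
        return float(row["area_km2"].iloc[0])


def _model_cells(stack: ScenarioStack, mask: StudyMask, covs) -> np.ndarray:
    """Masked cells valid in every retained covariate, row-major order."""
    ok = mask.included & stack.joint_valid_mask(list(covs))
    return np.argwhere(ok)


def _evaluate_species(
    presence: CovariateMatrix,
    background: CovariateMatrix,
    landscape: CovariateMatrix,
    spec: FeatureSpec,
    beta: float,
    full_model: MaxEntModel,
    mask_grid,
    settings: ModelSettings,
    seed: int,
) -> evaluation.EvalReport:
    """Spatial-block CV for AUC/Boyce; random CV for the max-SSS threshold.

    AUC compares held-out presences with the target-group background; the
    Boyce index compares them with predictions over the whole masked
    landscape.
    """
    k = min(settings.cv_folds, presence.n)
    fold_auc: list[float] = []
    fold_boyce: list[float] = []
    if settings.eval_cv:
        try:
            folds = evaluation.spatial_block_folds(
                presence.cells, mask_grid, settings.block_size_km, k=k, seed=seed
            )
        except FoldError as exc:
            log.warning("spatial blocks unusable (%s); falling back to random folds", exc)
            folds = evaluation.random_folds(presence.cells, k=k, seed=seed)
        for i in range(1, folds.k + 1):
            tr = folds.fold != i
            m = maxent.train_maxent(
                CovariateMatrix(presence.cells[tr], presence.names, presence.values[tr]),
                background, spec=spec, beta=beta,
            )
            held = CovariateMatrix(
                presence.cells[~tr], presence.names, presence.values[~tr]
            )
            pred_h = maxent.predict(m, held)
            pred_b = maxent.predict(m, background)
            fold_auc.append(evaluation.auc(pred_h, pred_b))
            try:
                fold_boyce.append(
                    evaluation.boyce_index(
                        pred_h, maxent.predict(m, landscape),
                        n_windows=settings.boyce_windows,
                        window_frac=settings.boyce_window_frac,
                    )
                )
            except CryosdmError as exc:
                log.warning("Boyce undefined on a fold: %s", exc)

    # threshold: mean of per-fold max-SSS thresholds on held-out predictions
    rfolds = evaluation.random_folds(presence.cells, k=k, seed=seed + 1)
    fold_thresholds: list[float] = []
    for i in range(1, k + 1):
        tr = rfolds.fold != i
        m = maxent.train_maxent(
            CovariateMatrix(presence.cells[tr], presence.names, presence.values[tr]),
            background, spec=spec, beta=beta,
        )
        t, _, _ = evaluation.max_sss_threshold(
            maxent.predict(m, CovariateMatrix(
                presence.cells[~tr], presence.names, presence.values[~tr]
            ), settings.output_transform),
            maxent.predict(m, background, settings.output_transform),
        )
        fold_thresholds.append(t)
    threshold = float(np.mean(fold_thresholds))
    pred_p = maxent.predict(full_model, presence, settings.output_transform)
    pred_b = maxent.predict(full_model, background, settings.output_transform)
    sens = float(np.mean(pred_p >= threshold))
    spec_ = float(np.mean(pred_b < threshold))
    return evaluation.EvalReport(
        auc_mean=float(np.mean(fold_auc)) if fold_auc else float("nan"),
        auc_sd=float(np.std(fold_auc)) if fold_auc else float("nan"),
        boyce_mean=float(np.mean(fold_boyce)) if fold_boyce else float("nan"),
        boyce_sd=float(np.std(fold_boyce)) if fold_boyce else float("nan"),
        threshold=threshold,
        sens_at_threshold=sens,
        spec_at_threshold=spec_,
        fold_auc=[float(a) for a in fold_auc],
        fold_boyce=[float(b) for b in fold_boyce],
        fold_thresholds=fold_thresholds,
    )


def run_analysis(
    stacks: dict[str, ScenarioStack],
    aux: tuple[EnvLayer, EnvLayer, EnvLayer],
    records_by_species: dict[str, list],
    categories: dict[str, str],
    settings: ModelSettings = ModelSettings(),
    master_seed: int = 0,
    mask_params: dict | None = None,
    reproject: bool = True,
    resolution_km: float = 50.0,
    lat_min_deg: float = 30.0,
) -> AnalysisResult:
    """Run the full stacked-model analysis on in-memory inputs.

    ``stacks`` must contain a ``"present"`` entry plus future scenarios on
    the same grid; ``aux`` is (depth, dist_to_shore, substrate).
    """
    if "present" not in stacks:
        raise ValidationError("a 'present' scenario stack is required")
    mask_params = dict(mask_params or {})
    mask_params.setdefault("lat_min_deg", lat_min_deg)

    aux_stack = ScenarioStack("aux", [aux[0], aux[1], aux[2]])
    prepared: dict[str, ScenarioStack] = {}
    for sid, stack in stacks.items():
        s = env_grid.crop_north(stack, lat_min_deg)
        if reproject:
            s = env_grid.reproject_equal_area(s, resolution_km=resolution_km)
        prepared[sid] = s
    aux_p = env_grid.crop_north(aux_stack, lat_min_deg)
    if reproject:
        aux_p = env_grid.reproject_equal_area(aux_p, resolution_km=resolution_km)
    grid = prepared["present"].grid
    grid.require_compatible(aux_p.grid, "auxiliary stack")
    lats = env_grid.cell_centre_latitudes(grid)
    mask = env_grid.build_study_mask(
        aux_p["depth"], aux_p["dist_to_shore"], aux_p["substrate"], lats, **mask_params
    )

    presence_cells: dict[str, PresenceCells] = {}
    for name, recs in sorted(records_by_species.items()):
        presence_cells[name] = dedup_to_cells(recs, grid, mask)
    background = target_group_background(list(presence_cells.values()))

    present = prepared["present"]
    bg_all = extract(present, list(settings.covariates), background.cells)
    vif = vif_select(bg_all, threshold=settings.vif_threshold)
    covs = vif.retained
    bg_cov = CovariateMatrix(
        bg_all.cells, covs, bg_all.values[:, [bg_all.names.index(c) for c in covs]]
    )

    scenario_cov: dict[str, CovariateMatrix] = {}
    for sid, stack in prepared.items():
        scenario_cov[sid] = extract(stack, covs, _model_cells(stack, mask, covs))

    species_results: dict[str, SpeciesResult] = {}
    projections: dict[tuple[str, str], projection.RangeProjection] = {}
    for name, pc in presence_cells.items():
        seed = species_seed(master_seed, name)
        pres_cov = extract(present, covs, pc.cells)
        tuning = None
        if settings.tune:
            tuning = maxent.tune(
                pres_cov, bg_cov,
                spec_grid=settings.spec_grid, beta_grid=settings.beta_grid,
                k=min(settings.cv_folds, pres_cov.n), seed=seed,
            )
            model = tuning.model
            beta, spec = tuning.best
        else:
            spec, beta = settings.default_spec, settings.default_beta
            model = maxent.train_maxent(pres_cov, bg_cov, spec=spec, beta=beta)
        report = _evaluate_species(
            pres_cov, bg_cov, scenario_cov["present"], spec, beta, model,
            grid, settings, seed,
        )
        contributions = maxent.variable_contribution(model, pres_cov, bg_cov, seed=seed)
        species_results[name] = SpeciesResult(
            presences=pc, model=model, tuning=tuning,
            report=report, contributions=contributions,
        )
        for sid, cov in scenario_cov.items():
            cells = cov.cells
            pred = maxent.predict(model, cov, settings.output_transform)
            suit = np.zeros(grid.shape)
            suit[cells[:, 0], cells[:, 1]] = pred
            binary = projection.apply_threshold(suit, report.threshold, mask)
            projections[(name, sid)] = projection.RangeProjection(
                species=name, scenario_id=sid, suitability=suit,
                binary=binary, threshold=report.threshold,
            )

    stacked: dict[tuple[str, str], projection.StackedProjection] = {}
    for cat in ("cryophilic", "cryotolerant"):
        members = [n for n, c in categories.items() if c == cat and n in presence_cells]
        if not members:
            continue
        for sid in prepared:
            stacked[(cat, sid)] = projection.StackedProjection(
                category=cat, scenario_id=sid,
                binary=projection.stack_binary(
                    [projections[(n, sid)].binary for n in members]
                ),
            )

    area_thr = projection.summarise(
        projections, categories, lats, grid.cell_area_km2,
        lat_cutoffs=settings.lat_cutoffs,
    )
    area_prob = projection.summarise(
        projections, categories, lats, grid.cell_area_km2,
        lat_cutoffs=settings.lat_cutoffs, probabilistic=True,
    )
    return AnalysisResult(
        mask=mask, lats=lats, background=background, vif=vif,
        retained_covariates=covs, species=species_results, categories=categories,
        projections=projections, stacked=stacked,
        area_thresholded=area_thr, area_probabilistic=area_prob,
        prepared_stacks=prepared,
    )


# --------------------------------------------------------------------------
# config-file driven runs


REQUIRED_CONFIG_KEYS = ("occurrences", "aux", "scenarios", "species", "output_dir")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["_config_dir"] = str(Path(path).parent)
    return cfg


def _resolve(cfg: dict, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else Path(cfg.get("_config_dir", ".")) / p


def validate_config(cfg: dict) -> list[str]:
    """Return a list of problems (empty means runnable); never raises."""
    issues: list[str] = []
    for key in REQUIRED_CONFIG_KEYS:
        if key not in cfg:
            issues.append(f"missing config key: {key}")
    if issues:
        return issues
    for aux_key in ("depth", "dist_to_shore", "substrate"):
        p = cfg["aux"].get(aux_key)
        if p is None:
            issues.append(f"aux.{aux_key}: missing")
        elif not _resolve(cfg, p).exists():
            issues.append(f"aux.{aux_key}: file not found: {p}")
    scenarios = cfg["scenarios"]
    if "present" not in scenarios:
        issues.append("scenarios: a 'present' entry is required")
    layer_sets = {sid: set(layers) for sid, layers in scenarios.items()}
    ref = layer_sets.get("present", set())
    for sid, names in layer_sets.items():
        if names != ref:
            issues.append(
                f"scenarios.{sid}: layer names {sorted(names)} differ from "
                f"present {sorted(ref)}"
            )
        for lname, p in scenarios[sid].items():
            if not _resolve(cfg, p).exists():
                issues.append(f"scenarios.{sid}.{lname}: file not found: {p}")
    for sp in cfg["species"]:
        if "name" not in sp:
            issues.append(f"species entry without name: {sp}")
        elif sp.get("category") not in synthetic.CATEGORIES:
            issues.append(
                f"species.{sp['name']}: category must be one of {synthetic.CATEGORIES}"
            )
    occ = _resolve(cfg, cfg["occurrences"])
    if not occ.exists():
        issues.append(f"occurrences: file not found: {cfg['occurrences']}")
    else:
        k = int(cfg.get("evaluation", {}).get("k", 5))
        try:
            counts = pd.read_csv(occ)["species"].value_counts()
            for sp in cfg["species"]:
                n = int(counts.get(sp.get("name"), 0))
                if n < k:
                    issues.append(
                        f"species.{sp.get('name')}: only {n} records for k={k} "
                        "folds; reduce k or drop the species"
                    )
        except (KeyError, pd.errors.ParserError) as exc:
            issues.append(f"occurrences: unreadable ({exc})")
    return issues


def _settings_from_config(cfg: dict) -> ModelSettings:
    tuning = cfg.get("tuning", {})
    ev = cfg.get("evaluation", {})
    kw: dict = {}
    if "covariates" in cfg:
        kw["covariates"] = tuple(cfg["covariates"])
    if "vif_threshold" in cfg:
        kw["vif_threshold"] = float(cfg["vif_threshold"])
    kw["tune"] = bool(tuning.get("enabled", False))
    if "beta_grid" in tuning:
        kw["beta_grid"] = tuple(float(b) for b in tuning["beta_grid"])
    if "feature_grids" in tuning:
        kw["spec_grid"] = tuple(
            FeatureSpec(classes=tuple(c)) for c in tuning["feature_grids"]
        )
    kw["cv_folds"] = int(ev.get("k", 5))
    kw["block_size_km"] = float(ev.get("block_size_km", 300.0))
    kw["eval_cv"] = bool(ev.get("eval_cv", True))
    kw["boyce_windows"] = int(ev.get("boyce_windows", 101))
    kw["boyce_window_frac"] = float(ev.get("boyce_window_frac", 0.1))
    if "output_transform" in cfg:
        kw["output_transform"] = cfg["output_transform"]
    return ModelSettings(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, out_dir=None) -> dict:
    """File-driven run: load inputs per the config, analyse, write outputs.

    Returns the run manifest (also written to ``manifest.json``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    issues = validate_config(cfg)
    if issues:
        raise ValidationError("config invalid:\n  " + "\n  ".join(issues))
    out = Path(out_dir or _resolve(cfg, cfg["output_dir"]))
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    settings = _settings_from_config(cfg)
    master_seed = int(cfg.get("master_seed", 0))

    stacks = {}
    checksums = {}
    for sid, layers in cfg["scenarios"].items():
        names = sorted(layers)
        paths = [_resolve(cfg, layers[n]) for n in names]
        stacks[sid] = env_grid.load_stack(paths, names, scenario_id=sid)
        for n, p in zip(names, paths):
            checksums[f"{sid}/{n}"] = _sha256(p)
    aux_paths = {k: _resolve(cfg, cfg["aux"][k]) for k in ("depth", "dist_to_shore", "substrate")}
    aux_stack = env_grid.load_stack(
        [aux_paths["depth"], aux_paths["dist_to_shore"], aux_paths["substrate"]],
        ["depth", "dist_to_shore", "substrate"],
    )
    for k, p in aux_paths.items():
        checksums[f"aux/{k}"] = _sha256(p)
    occ_path = _resolve(cfg, cfg["occurrences"])
    checksums["occurrences"] = _sha256(occ_path)
    records = read_occurrences(occ_path, min_year=cfg.get("min_year"))
    categories = {sp["name"]: sp["category"] for sp in cfg["species"]}
    by_species: dict[str, list] = {sp["name"]: [] for sp in cfg["species"]}
    for r in records:
        if r.species in by_species:
            by_species[r.species].append(r)

    mask_cfg = cfg.get("mask", {})
    result = run_analysis(
        stacks,
        (aux_stack["depth"], aux_stack["dist_to_shore"], aux_stack["substrate"]),
        by_species,
        categories,
        settings=settings,
        master_seed=master_seed,
        mask_params={
            k: float(mask_cfg[k])
            for k in ("depth_max_m", "shore_km")
            if k in mask_cfg
        },
        resolution_km=float(cfg.get("grid", {}).get("resolution_km", 50.0)),
        lat_min_deg=float(mask_cfg.get("lat_min_deg", 30.0)),
    )
    _write_outputs(result, out, master_seed)
    manifest = {
        "master_seed": master_seed,
        "input_checksums": checksums,
        "species_seeds": {n: species_seed(master_seed, n) for n in categories},
        "retained_covariates": result.retained_covariates,
        "n_background": result.background.n,
        "runtime_s": round(time.time() - t0, 2),
        "stages": [
            "load", "crop", "reproject", "mask", "dedup", "background",
            "vif", "fit", "evaluate", "project", "stack", "summarise",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_outputs(result: AnalysisResult, out: Path, master_seed: int) -> None:
    grid = result.mask.grid
    (out / "models").mkdir(exist_ok=True)
    (out / "eval").mkdir(exist_ok=True)
    (out / "rasters").mkdir(exist_ok=True)
    (out / "presences").mkdir(exist_ok=True)
    (out / "vif_report.json").write_text(result.vif.to_json())
    for name, sr in result.species.items():
        (out / "models" / f"{name}.json").write_text(sr.model.to_json())
        payload = sr.report.to_dict()
        payload["variable_contributions_pct"] = sr.contributions
        payload["n_presence_cells"] = sr.presences.n
        payload["n_raw_records"] = sr.presences.n_raw
        if sr.tuning is not None:
            payload["tuning"] = sr.tuning.summary()
        (out / "eval" / f"{name}.json").write_text(json.dumps(payload, indent=2))
        presence_table(sr.presences, grid).to_csv(
            out / "presences" / f"{name}.csv", index=False
        )
    for (name, sid), proj in result.projections.items():
        for kind, vals in (("suitability", proj.suitability), ("binary", proj.binary)):
            lyr = EnvLayer(
                name=f"{name}_{sid}_{kind}",
                values=np.where(result.mask.included, vals, grid.nodata_sentinel),
                valid_mask=result.mask.included,
                grid=grid,
            )
            write_ascii_grid(lyr, out / "rasters" / f"{name}_{sid}_{kind}.asc")
    for (cat, sid), st in result.stacked.items():
        lyr = EnvLayer(
            name=f"stacked_{cat}_{sid}",
            values=np.where(result.mask.included, st.binary, grid.nodata_sentinel),
            valid_mask=result.mask.included,
            grid=grid,
        )
        write_ascii_grid(lyr, out / "rasters" / f"stacked_{cat}_{sid}.asc")
        if sid != "present":
            change = projection.change_classification(
                result.stacked[(cat, "present")].binary, st.binary
            )
            lyr = EnvLayer(
                name=f"stacked_{cat}_{sid}_change",
                values=np.where(result.mask.included, change, grid.nodata_sentinel),
                valid_mask=result.mask.included,
                grid=grid,
            )
            write_ascii_grid(lyr, out / "rasters" / f"stacked_{cat}_{sid}_change.asc")
    # thresholded areas are the primary table; probabilistic alongside
    result.area_thresholded.to_csv(out / "area_thresholded.csv", index=False)
    result.area_probabilistic.to_csv(out / "area_probabilistic.csv", index=False)


def make_fixtures(
    out_dir,
    master_seed: int = 0,
    n_rows: int = 60,
    n_cols: int = 360,
    scenario_ids: tuple[str, ...] = tuple(synthetic.DEFAULT_SCENARIOS),
) -> Path:
    """Materialise a complete synthetic study directory and its config.

    Writes one ``.asc`` raster per layer per scenario, the auxiliary
    rasters, the pooled occurrence CSV, and ``config.yaml``; returns the
    config path.
    """
    out = Path(out_dir)
    (out / "layers").mkdir(parents=True, exist_ok=True)
    world = synthetic.build_synthetic_world(
        master_seed, n_rows=n_rows, n_cols=n_cols, scenario_ids=scenario_ids
    )
    scen_cfg: dict[str, dict[str, str]] = {}
    for sid, stack in world.stacks.items():
        scen_cfg[sid] = {}
        for lyr in stack:
            rel = f"layers/{sid}_{lyr.name}.asc"
            write_ascii_grid(lyr, out / rel)
            scen_cfg[sid][lyr.name] = rel
    aux_cfg = {}
    for key, lyr in (
        ("depth", world.seascape.depth),
        ("dist_to_shore", world.seascape.dist_to_shore),
        ("substrate", world.seascape.substrate),
    ):
        rel = f"layers/aux_{key}.asc"
        write_ascii_grid(lyr, out / rel)
        aux_cfg[key] = rel
    rows = []
    for name, recs in world.records.items():
        for r in recs:
            rows.append(
                {"species": name, "longitude": r.lon, "latitude": r.lat,
                 "year": r.year, "source": "synthetic"}
            )
    pd.DataFrame(rows).to_csv(out / "occurrences.csv", index=False)
    cfg = {
        "master_seed": master_seed,
        "output_dir": "results",
        "occurrences": "occurrences.csv",
        "aux": aux_cfg,
        "scenarios": scen_cfg,
        "species": [
            {"name": vs.name, "category": vs.category} for vs in world.species
        ],
        "covariates": list(synthetic.LAYER_NAMES),
        "grid": {"resolution_km": 50.0},
        "mask": {"depth_max_m": 100.0, "shore_km": 10.0, "lat_min_deg": 30.0},
        "evaluation": {"k": 5, "block_size_km": 300.0},
        "tuning": {"enabled": False},
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path


def run_synthetic_experiment(
    master_seed: int,
    n_rows: int = 60,
    n_cols: int = 360,
    scenario_ids: tuple[str, ...] = ("rcp85_2100",),
    settings: ModelSettings | None = None,
    resolution_km: float = 50.0,
):
    """Generate a synthetic world and analyse it in memory.

    Returns (world, AnalysisResult).  This is the entry point used by the
    validation suite: the generated truth (virtual species' suitability and
    ranges) travels alongside the fitted results.
    """
    world = synthetic.build_synthetic_world(
        master_seed, n_rows=n_rows, n_cols=n_cols, scenario_ids=scenario_ids
    )
    if settings is None:
        settings = ModelSettings(eval_cv=False)
    result = run_analysis(
        world.stacks,
        (world.seascape.depth, world.seascape.dist_to_shore, world.seascape.substrate),
        world.records,
        world.categories,
        settings=settings,
        master_seed=master_seed,
        resolution_km=resolution_km,
    )
    return world, result
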