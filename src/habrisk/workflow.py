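"""Config-driven end-to-end workflow.

Chains occurrence cleaning, background generation (both schemes),
predictor harmonization and screening, model fitting with
cross-validation and gates, thresholding, ensembles, MESS, permutation
importance, and management-unit risk summaries, writing a reproducible
artifact bundle.  Every stage receives a deterministic seed derived
from the master seed, and the manifest records enough to replay the run
identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from . import (
    background as bg,
    evaluation,
    occurrences as occ,
    predictors as pred,
    risk_assessment as risk,
    sdm_models as sdm,
    thresholds_ensemble as thr,
)
from .raster import RasterGrid, RasterStack

log = logging.getLogger("habrisk")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunConfig:
    species_name: str
    occurrences_path: str
    predictor_paths: dict  # name -> ascii-grid path
    output_dir: str
    seed: int = 0
    # occurrence cleaning
    min_year: int = 1980
    max_uncertainty_m: float = 30.0
    allowed_types: list = field(default_factory=lambda: ["observation", "specimen"])
    centroid_points: list = field(default_factory=list)
    centroid_tol_m: float = 100.0
    snap_cell_m: Optional[float] = None  # default: predictor cell size
    # background
    background_methods: list = field(default_factory=lambda: ["kde", "target"])
    n_background: int = 10000
    kde_bandwidth: str | float = "auto"
    isopleth_mass: float = 0.99
    buffer_mode: str = "max_range"
    target_occurrences_path: Optional[str] = None
    lifeform: Optional[str] = None
    # predictors
    candidate_variables: list = field(default_factory=list)
    variable_priority: str | list = "auto"
    correlation_threshold: float = 0.7
    # models
    algorithms: list = field(default_factory=lambda: list(sdm.ALGORITHMS))
    algorithm_settings: dict = field(default_factory=dict)  # algorithm -> overrides
    cv_folds: int = 10
    overfit_gap: float = 0.05
    min_cv_auc: float = 0.7
    # outputs
    threshold_rules: list = field(default_factory=lambda: list(thr.RULE_KINDS))
    risk_rule: str = "pct1"
    min_agreement: Optional[int] = None
    units_path: Optional[str] = None
    independent_points_path: Optional[str] = None
    write_mess: bool = True

    def validate(self) -> None:
        paths = [self.occurrences_path, *self.predictor_paths.values()]
        if self.target_occurrences_path:
            paths.append(self.target_occurrences_path)
        if self.units_path:
            paths.append(self.units_path)
        if self.independent_points_path:
            paths.append(self.independent_points_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        if "target" in self.background_methods and not (
            self.target_occurrences_path and self.lifeform
        ):
            raise ValueError(
                "target background requires target_occurrences_path and lifeform"
            )
        for rule in self.threshold_rules:
            if rule not in thr.RULE_KINDS:
                raise ValueError(f"unknown threshold rule {rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_units(path) -> list[risk.ManagementUnit]:
    with open(path) as fh:
        payload = json.load(fh)
    feats = payload["features"] if payload.get("type") == "FeatureCollection" else [
        payload
    ]
    units = []
    for i, feat in enumerate(feats):
        name = feat.get("properties", {}).get("name", f"unit_{i}")
        units.append(risk.ManagementUnit(name=name, polygon=shape(feat["geometry"])))
    return units


def run_workflow(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {},
        "stages": {},
        "models": {},
        "notes": [],
    }

    def seeded(stage: str) -> int:
        s = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = s
        return s

    # ---- occurrences ----
    try:
        raw = occ.load_occurrences(config.occurrences_path)
        filtered = occ.filter_occurrences(
            raw,
            min_year=config.min_year,
            max_uncertainty_m=config.max_uncertainty_m,
            allowed_types=config.allowed_types,
        )
        # snap cell defaults to the predictor cell size, resolved below
        template_probe = RasterGrid.read_ascii(
            next(iter(config.predictor_paths.values()))
        )
        snap = config.snap_cell_m or template_probe.cell_size
        cleaned = occ.deduplicate_and_flag(
            filtered,
            centroid_points=[tuple(c) for c in config.centroid_points],
            centroid_tol_m=config.centroid_tol_m,
            snap_cell_m=snap,
        )
        cleaned.write_csv(out / "occurrences_clean.csv")
        cleaned.write_filter_log(out / "occurrence_filter_log.json")
        manifest["stages"]["occurrences"] = {
            "input": len(raw),
            "retained": len(cleaned),
            "filter_log": cleaned.filter_log,
        }
    except Exception as exc:
        raise StageFailure("occurrences", exc) from exc

    # ---- predictors ----
    try:
        grids = {
            name: RasterGrid.read_ascii(path)
            for name, path in config.predictor_paths.items()
        }
        names = list(grids)
        template = grids[names[0]]
        stack = RasterStack(
            {name: pred.parc_harmonize(g, template) for name, g in grids.items()}
        )
        candidates = config.candidate_variables or names
        manifest["stages"]["predictors"] = {
            "layers": names,
            "candidates": candidates,
            "cell_size": template.cell_size,
        }
    except Exception as exc:
        raise StageFailure("predictors", exc) from exc

    # ---- backgrounds ----
    backgrounds: dict[str, bg.BackgroundSet] = {}
    try:
        pres_xy = cleaned.xy
        kde = bg.fit_kde(pres_xy, bandwidth=config.kde_bandwidth)
        if "kde" in config.background_methods:
            extent = bg.buffered_mcp(pres_xy, buffer_mode=config.buffer_mode)
            backgrounds["kde"] = bg.sample_kde_background(
                kde,
                extent,
                n=config.n_background,
                seed=seeded("background:kde"),
                template=template,
            )
            extent.write_geojson(out / "extent_kde.geojson")
        if "target" in config.background_methods:
            region = bg.kde_isopleth(kde, config.isopleth_mass, template)
            targets = occ.load_occurrences(config.target_occurrences_path)
            backgrounds["target"] = bg.sample_target_background(
                targets,
                config.lifeform,
                region,
                n=config.n_background,
                seed=seeded("background:target"),
            )
            region.write_geojson(out / "extent_target.geojson")
        for method, bset in backgrounds.items():
            bset.write_csv(out / f"background_{method}.csv")
        manifest["stages"]["background"] = {
            m: {"n": b.n, "seed": b.seed} for m, b in backgrounds.items()
        }
    except Exception as exc:
        raise StageFailure("background", exc) from exc

    # ---- design tables + screening (per background method) ----
    tables: dict[str, pred.DesignTable] = {}
    screens: dict[str, pred.CorrelationScreen] = {}
    try:
        for method, bset in backgrounds.items():
            t = pred.extract_design_table(stack, cleaned, bset, candidates)
            screen = pred.select_uncorrelated(
                pred.max_correlation_matrix(
                    t, candidates, threshold=config.correlation_threshold
                ),
                priority=config.variable_priority,
            )
            screen.write_csv(
                out / f"correlation_matrix_{method}.csv",
                out / f"correlation_removals_{method}.csv",
            )
            tables[method] = t.subset_variables(screen.retained)
            screens[method] = screen
        manifest["stages"]["screening"] = {
            m: {"retained": s.retained, "removed": s.removed}
            for m, s in screens.items()
        }
    except Exception as exc:
        raise StageFailure("screening", exc) from exc

    # ---- model fitting, CV, gates ----
    models: dict[str, sdm.FittedModel] = {}
    fold_rows = []
    metric_rows = []
    try:
        for method in backgrounds:
            t = tables[method]
            for algorithm in config.algorithms:
                name = f"{algorithm}_{method}"
                spec = sdm.ModelSpec(
                    algorithm=algorithm,
                    background_method=method,
                    settings=dict(config.algorithm_settings.get(algorithm, {})),
                    seed=seeded(f"fit:{name}"),
                )
                cv_seed = seeded(f"cv:{name}")
                model = sdm.fit_model(spec, t)
                cvres = evaluation.cross_validate(
                    spec, t, k=config.cv_folds, seed=cv_seed
                )
                model.cv_auc = cvres.cv_mean.auc_roc
                model = sdm.apply_gates(
                    model, config.overfit_gap, config.min_cv_auc, retuned=False
                )
                if model.gates["overfit_flag"] and not model.gates["dropped"]:
                    spec2 = sdm.retune_spec(spec)
                    model2 = sdm.fit_model(spec2, t)
                    cvres2 = evaluation.cross_validate(
                        spec2, t, k=config.cv_folds, seed=cv_seed
                    )
                    model2.cv_auc = cvres2.cv_mean.auc_roc
                    model2 = sdm.apply_gates(
                        model2, config.overfit_gap, config.min_cv_auc, retuned=True
                    )
                    model2.gates["reason"] = (
                        "re-tuned after overfit flag; " + model2.gates["reason"]
                    ).strip("; ")
                    model, cvres = model2, cvres2
                models[name] = model
                scores = model.score_table(t)
                sp = evaluation.ScoredPoints(scores, t.response)
                train_thr = evaluation.sens_eq_spec_threshold(sp)
                train_ms = evaluation.threshold_metrics(sp, train_thr, split="train")
                metric_rows.append({"model": name, **train_ms.as_dict()})
                metric_rows.append({"model": name, **cvres.cv_mean.as_dict()})
                pf = cvres.per_fold.copy()
                pf.insert(0, "model", name)
                fold_rows.append(pf)
                manifest["models"][name] = model.manifest()
        pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
        pd.concat(fold_rows, ignore_index=True).to_csv(
            out / "metrics_per_fold.csv", index=False
        )
    except Exception as exc:
        raise StageFailure("models", exc) from exc

    retained = {n: m for n, m in models.items() if not m.gates["dropped"]}
    manifest["stages"]["gates"] = {
        "retained": sorted(retained),
        "dropped": {
            n: m.gates["reason"] for n, m in models.items() if m.gates["dropped"]
        },
    }
    if not retained:
        manifest["notes"].append(
            "all models were dropped by the quality gates; no ensembles, "
            "importance, or risk products were produced"
        )

    # ---- thresholds, rasters, ensembles, MESS, importance ----
    ensembles: dict[str, thr.EnsembleProduct] = {}
    try:
        suit_rasters: dict[str, RasterGrid] = {}
        thresholds: dict[str, dict[str, float]] = {}
        importance_rows = []
        for name, model in sorted(retained.items()):
            method = model.spec.background_method
            t = tables[method]
            scores = model.score_table(t)
            sp = evaluation.ScoredPoints(scores, t.response)
            pres_scores = sp.presence_scores
            rules = {
                kind: thr.compute_threshold(kind, pres_scores, sp)
                for kind in config.threshold_rules
            }
            thresholds[name] = {k: r.value for k, r in rules.items()}
            grid = sdm.predict_raster(model, stack)
            suit_rasters[name] = grid
            grid.write_ascii(out / f"suitability_{name}.asc")
            if config.write_mess:
                mess = thr.mess_surface(stack, t, model.input_variables)
                mess.mess.write_ascii(out / f"mess_{name}.asc")
            ranking = thr.permutation_importance(
                model, t, seed=seeded(f"importance:{name}")
            )
            df = ranking.as_frame()
            df.insert(0, "model", name)
            importance_rows.append(df)
        manifest["stages"]["thresholds"] = thresholds
        if importance_rows:
            pd.concat(importance_rows, ignore_index=True).to_csv(
                out / "importance.csv", index=False
            )
        for kind in config.threshold_rules:
            if not retained:
                continue
            binaries = {
                name: thr.binarize_raster(
                    suit_rasters[name],
                    thr.ThresholdRule(kind, thresholds[name][kind]),
                )
                for name in sorted(retained)
            }
            product = thr.build_ensemble(
                binaries, thr.ThresholdRule(kind, float("nan"))
            )
            ensembles[kind] = product
            product.ensemble.write_ascii(out / f"ensemble_{kind}.asc")
        manifest["stages"]["ensembles"] = {
            kind: {"retained_count": p.retained_count} for kind, p in ensembles.items()
        }
    except Exception as exc:
        raise StageFailure("ensembles", exc) from exc

    # ---- risk products ----
    try:
        if config.units_path and ensembles and config.risk_rule in ensembles:
            units = _load_units(config.units_path)
            table = risk.zonal_risk_summary(
                ensembles[config.risk_rule],
                units,
                min_agreement=config.min_agreement,
                occurrences=cleaned,
            )
            table.to_csv(out / "risk_summary.csv", index=False)
            manifest["stages"]["risk"] = {
                "rule": config.risk_rule,
                "n_units": len(units),
            }
        if config.independent_points_path and ensembles:
            points = occ.load_occurrences(config.independent_points_path)
            hist, drop_log = risk.independent_point_evaluation(ensembles, points)
            hist.to_csv(out / "independent_evaluation.csv", index=False)
            manifest["stages"]["independent_evaluation"] = {
                "n_points": len(points),
                "dropped": drop_log,
            }
    except Exception as exc:
        raise StageFailure("risk", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def run_from_manifest(manifest_path) -> dict:
    """Replay a run from its manifest alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig(**manifest["config"])
    return run_workflow(config)
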