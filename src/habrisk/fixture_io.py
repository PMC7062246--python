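"""Write synthetic fixtures to disk in the same text formats the real
pipeline consumes, so fixture and real inputs are interchangeable."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic_fixtures import (
    generate_landscape,
    make_virtual_species,
    sample_presences,
    sample_target_guild,
)
from .workflow import RunConfig, stage_seed


def default_correlation(n_vars: int, rho: float = 0.3) -> np.ndarray:
    """Mild exchangeable-style correlation among landscape layers."""
    R = np.full((n_vars, n_vars), rho)
    np.fill_diagonal(R, 1.0)
    return R


def write_fixture_bundle(
    outdir: Path,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    n_vars: int = 6,
    n_presences: int = 300,
    n_targets: int = 2000,
    beta: dict | None = None,
    intercept: float = -8.0,
    spatial_range: float = 4.0,
    correlation: np.ndarray | str | None = None,
) -> dict[str, Path]:
    """Write rasters, occurrence tables, a unit polygon, and independent
    points; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if correlation is None:
        correlation = default_correlation(n_vars)
    stack = generate_landscape(
        n_vars,
        shape,
        spatial_range=spatial_range,
        inter_var_correlation=correlation,
        seed=stage_seed(seed, "fixture:landscape"),
    )
    beta = beta if beta is not None else {"x1": 3.0, "x2": -3.0}
    vs = make_virtual_species(stack, beta, intercept=intercept)
    presences = sample_presences(
        vs, n_presences, seed=stage_seed(seed, "fixture:presences")
    )
    targets = sample_target_guild(
        stack, n_targets, lifeform="grass", seed=stage_seed(seed, "fixture:targets")
    )
    independent = sample_presences(
        vs, max(50, n_presences // 4), seed=stage_seed(seed, "fixture:independent")
    )

    paths: dict[str, Path] = {}
    for name in stack.names:
        p = outdir / f"{name}.asc"
        stack[name].write_ascii(p)
        paths[name] = p
    paths["occurrences"] = outdir / "occurrences.csv"
    presences.write_csv(paths["occurrences"])
    paths["targets"] = outdir / "targets.csv"
    tf = targets.to_frame()
    tf.to_csv(paths["targets"], index=False)
    paths["independent"] = outdir / "independent.csv"
    independent.write_csv(paths["independent"])

    # a toy management unit covering the middle ninth of the landscape
    xmin, ymin, xmax, ymax = stack.template.bounds
    dx, dy = (xmax - xmin) / 3.0, (ymax - ymin) / 3.0
    ring = [
        [xmin + dx, ymin + dy],
        [xmin + 2 * dx, ymin + dy],
        [xmin + 2 * dx, ymin + 2 * dy],
        [xmin + dx, ymin + 2 * dy],
        [xmin + dx, ymin + dy],
    ]
    units = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": "central unit"},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        ],
    }
    paths["units"] = outdir / "units.geojson"
    with open(paths["units"], "w") as fh:
        json.dump(units, fh)
    return paths


def fixture_run_config(
    outdir: Path,
    paths: dict[str, Path],
    seed: int = 0,
    n_background: int = 1000,
    algorithms: list | None = None,
    algorithm_settings: dict | None = None,
    cv_folds: int = 10,
    background_methods: list | None = None,
    **overrides,
) -> RunConfig:
    """A RunConfig wired to a fixture bundle, with small fast defaults."""
    predictor_paths = {
        k: str(v) for k, v in paths.items() if str(v).endswith(".asc")
    }
    cfg = RunConfig(
        species_name="virtual species",
        occurrences_path=str(paths["occurrences"]),
        predictor_paths=predictor_paths,
        output_dir=str(outdir),
        seed=seed,
        background_methods=background_methods or ["kde", "target"],
        n_background=n_background,
        target_occurrences_path=str(paths["targets"]),
        lifeform="grass",
        algorithms=algorithms or ["glm_stepwise", "mars", "brt", "rf", "maxent_like"],
        algorithm_settings=algorithm_settings
        or {
            "rf": {"n_trees": 200},
            "brt": {"max_trees": 300},
            "glm_stepwise": {"max_steps": 8},
        },
        cv_folds=cv_folds,
        units_path=str(paths["units"]),
        independent_points_path=str(paths["independent"]),
        **overrides,
    )
    return cfg
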