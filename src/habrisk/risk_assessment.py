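"""Management-unit interpretation products: zonal suitable area and
percent, occurrence counts, nearest-occurrence distances, and
independent-point ensemble evaluation.

Cell membership in a polygon uses the cell-center test; distances are
planar (an equal-area projected system is assumed).  1 ha = 1e4 map
units squared, 1 acre = 4046.8564224.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .occurrences import OccurrenceSet
from .thresholds_ensemble import EnsembleProduct

M2_PER_HA = 1.0e4
M2_PER_ACRE = 4046.8564224


@dataclass
class ManagementUnit:
    name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"unit {self.name!r} has an invalid polygon")
        if self.polygon.area <= 0:
            raise ValueError(f"unit {self.name!r} has zero area")

    @property
    def area(self) -> float:
        return float(self.polygon.area)


def zonal_risk_summary(
    ensemble: EnsembleProduct,
    units: Sequence[ManagementUnit],
    min_agreement: int | None = None,
    occurrences: OccurrenceSet | None = None,
) -> pd.DataFrame:
    """One row per unit: suitable area (>= ``min_agreement`` models
    agreeing; default = ceil(retained/2)), percent of the unit, interior
    occurrence count, and nearest-occurrence distance.

    Units entirely outside the raster get null areas and a warning.
    """
    if min_agreement is None:
        min_agreement = int(np.ceil(ensemble.retained_count / 2)) or 1
    grid = ensemble.ensemble
    X, Y = grid.cell_centers()
    vals = grid.values
    suitable = ~np.isnan(vals) & (vals >= min_agreement)
    cell_area = grid.cell_area
    xmin, ymin, xmax, ymax = grid.bounds
    rows = []
    for unit in units:
        uxmin, uymin, uxmax, uymax = unit.polygon.bounds
        outside = uxmax < xmin or uxmin > xmax or uymax < ymin or uymin > ymax
        if outside:
            warnings.warn(f"unit {unit.name!r} lies outside the raster bounds")
            rows.append(
                {
                    "unit_name": unit.name,
                    "suitable_area": np.nan,
                    "suitable_area_ha": np.nan,
                    "suitable_area_acres": np.nan,
                    "percent_of_unit": np.nan,
                    "n_occurrences_inside": _count_inside(unit, occurrences),
                    "min_distance_to_occurrence": _nearest(unit, occurrences),
                }
            )
            continue
        inside = shapely.intersects_xy(unit.polygon, X.ravel(), Y.ravel()).reshape(
            X.shape
        )
        n_suitable = int((inside & suitable).sum())
        area = n_suitable * cell_area
        rows.append(
            {
                "unit_name": unit.name,
                "suitable_area": area,
                "suitable_area_ha": area / M2_PER_HA,
                "suitable_area_acres": area / M2_PER_ACRE,
                "percent_of_unit": 100.0 * area / unit.area,
                "n_occurrences_inside": _count_inside(unit, occurrences),
                "min_distance_to_occurrence": _nearest(unit, occurrences),
            }
        )
    return pd.DataFrame(rows)


def _count_inside(unit: ManagementUnit, occurrences: OccurrenceSet | None):
    if occurrences is None or len(occurrences) == 0:
        return None
    xy = occurrences.xy
    return int(shapely.intersects_xy(unit.polygon, xy[:, 0], xy[:, 1]).sum())


def _nearest(unit: ManagementUnit, occurrences: OccurrenceSet | None):
    if occurrences is None or len(occurrences) == 0:
        return None
    return nearest_occurrence_distance(unit, occurrences)


def nearest_occurrence_distance(
    unit: ManagementUnit, occurrences: OccurrenceSet
) -> float:
    """0 if any occurrence lies within or on the unit boundary, else the
    minimum planar distance from the boundary to an occurrence."""
    if len(occurrences) == 0:
        raise ValueError("occurrence set is empty")
    xy = occurrences.xy
    pts = shapely.points(xy[:, 0], xy[:, 1])
    dists = shapely.distance(unit.polygon, pts)
    return float(np.min(dists))


def independent_point_evaluation(
    ensembles: dict[str, EnsembleProduct],
    points: OccurrenceSet,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Histogram of ensemble values at independent points, per rule.

    Returns a long table (rule, ensemble_value, count) and a log of
    dropped out-of-bounds / nodata points per rule.
    """
    xy = points.xy
    rows = []
    drop_log: dict[str, int] = {}
    for rule_name, product in ensembles.items():
        vals = product.ensemble.sample(xy[:, 0], xy[:, 1]) if len(xy) else np.array([])
        ok = ~np.isnan(vals)
        drop_log[rule_name] = int((~ok).sum())
        values, counts = np.unique(vals[ok].astype(int), return_counts=True)
        for v, c in zip(values, counts):
            rows.append(
                {"rule": rule_name, "ensemble_value": int(v), "count": int(c)}
            )
    return (
        pd.DataFrame(rows, columns=["rule", "ensemble_value", "count"]),
        drop_log,
    )
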