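"""Synthetic landscapes and virtual species with known truth.

Landscapes are smooth Gaussian random fields (moving-average
construction: seeded white noise smoothed with a Gaussian filter),
standardized per layer, with optional cross-layer correlation imposed by
a Cholesky mix.  Virtual species assign each cell an inverse-logit
suitability from a linear (optionally quadratic) function of the
layers; presences are sampled with probability proportional to
suitability times an optional bias surface and emitted as fully
populated occurrence records that pass the default cleaning filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .occurrences import OccurrenceRecord, OccurrenceSet
from .raster import RasterGrid, RasterStack

FIXTURE_CRS = "synthetic-planar"
FIXTURE_CELL = 90.0


def generate_landscape(
    n_vars: int,
    shape: tuple[int, int],
    spatial_range: float,
    inter_var_correlation: Union[str, np.ndarray] = "independent",
    seed: int = 0,
    cell_size: float = FIXTURE_CELL,
) -> RasterStack:
    """Seeded stack of smooth, standardized random-field layers x1..xn.

    ``inter_var_correlation`` is either ``"independent"`` or a
    positive-definite correlation matrix imposed across layers.
    """
    rows, cols = shape
    if rows < 32 or cols < 32:
        raise ValueError("shape must be at least 32x32")
    rng = np.random.default_rng(seed)
    fields = np.empty((n_vars, rows, cols))
    for i in range(n_vars):
        noise = rng.standard_normal((rows, cols))
        smooth = gaussian_filter(noise, sigma=spatial_range, mode="reflect")
        fields[i] = (smooth - smooth.mean()) / smooth.std()
    if not (
        isinstance(inter_var_correlation, str)
        and inter_var_correlation == "independent"
    ):
        R = np.asarray(inter_var_correlation, dtype=float)
        if R.shape != (n_vars, n_vars):
            raise ValueError("correlation matrix shape must match n_vars")
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive-definite") from exc
        flat = fields.reshape(n_vars, -1)
        mixed = L @ flat
        fields = mixed.reshape(n_vars, rows, cols)
        for i in range(n_vars):
            fields[i] = (fields[i] - fields[i].mean()) / fields[i].std()
    layers = {
        f"x{i + 1}": RasterGrid(
            fields[i], x0=0.0, y0=0.0, cell_size=cell_size, crs_id=FIXTURE_CRS
        )
        for i in range(n_vars)
    }
    return RasterStack(layers)


@dataclass
class VirtualSpecies:
    coefficients: dict
    suitability: RasterGrid
    driving_variables: list[str]


def make_virtual_species(
    stack: RasterStack,
    coefficients: Mapping[str, float],
    intercept: float = 0.0,
    quadratic: Optional[Mapping[str, float]] = None,
) -> VirtualSpecies:
    """Inverse-logit suitability from a linear(+quadratic) predictor."""
    quadratic = dict(quadratic or {})
    unknown = [v for v in list(coefficients) + list(quadratic) if v not in stack]
    if unknown:
        raise KeyError(f"unknown variables: {unknown}")
    template = stack.template
    lin = np.full(template.shape, float(intercept))
    for name, beta in coefficients.items():
        lin = lin + beta * stack[name].values
    for name, gamma in quadratic.items():
        lin = lin + gamma * stack[name].values ** 2
    suit = 1.0 / (1.0 + np.exp(-lin))
    driving = sorted(
        {n for n, b in coefficients.items() if b != 0}
        | {n for n, g in quadratic.items() if g != 0}
    )
    return VirtualSpecies(
        coefficients={"intercept": intercept, **dict(coefficients), **{
            f"{k}^2": v for k, v in quadratic.items()
        }},
        suitability=template.like(suit),
        driving_variables=driving,
    )


def sample_presences(
    vs: VirtualSpecies,
    n: int,
    bias: Union[str, RasterGrid] = "uniform",
    seed: int = 0,
    species_name: str = "virtual species",
) -> OccurrenceSet:
    """Sample ``n`` presence cells with probability proportional to
    suitability x bias; points are placed at cell centers with metadata
    that passes the default occurrence filters."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = vs.suitability
    weights = grid.values.astype(float).copy()
    if not (isinstance(bias, str) and bias == "uniform"):
        if not bias.same_geometry(grid):
            raise ValueError("bias raster must share the suitability geometry")
        weights = weights * bias.values
    weights = np.where(np.isnan(weights), 0.0, np.clip(weights, 0.0, None))
    total = weights.sum()
    if total <= 0:
        raise ValueError("total sampling weight is zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(weights.size, size=n, replace=True, p=weights.ravel() / total)
    rows, cols = np.unravel_index(idx, grid.shape)
    xs, ys = grid.center_of_cell(rows, cols)
    records = [
        OccurrenceRecord(
            species_name=species_name,
            x=float(x),
            y=float(y),
            event_date=date(2000, 1, 1),
            record_type="observation",
            coordinate_uncertainty_m=1.0,
            source="synthetic",
        )
        for x, y in zip(np.atleast_1d(xs), np.atleast_1d(ys))
    ]
    return OccurrenceSet(records, crs_id=grid.crs_id, filter_log={})


def sample_target_guild(
    stack: RasterStack,
    n: int,
    lifeform: str,
    bias: Union[str, RasterGrid] = "uniform",
    seed: int = 0,
) -> OccurrenceSet:
    """Occurrences of a synthetic 'similar species' guild: uniform (or
    biased) samples across the landscape, tagged with a lifeform so the
    target-guild background filter applies."""
    template = stack.template
    flat_bias = (
        np.ones(template.shape)
        if isinstance(bias, str) and bias == "uniform"
        else bias.values
    )
    neutral = VirtualSpecies(
        coefficients={"intercept": 0.0},
        suitability=template.like(np.ones(template.shape) * 0.5),
        driving_variables=[],
    )
    occ = sample_presences(
        neutral,
        n,
        bias=template.like(flat_bias) if not isinstance(bias, str) else "uniform",
        seed=seed,
        species_name=f"synthetic {lifeform} guild",
    )
    for rec in occ.records:
        rec.lifeform = lifeform
    return occ
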