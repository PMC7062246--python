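"""Background (pseudo-absence) sample generation.

Two schemes:

* density-weighted sampling from a Gaussian kernel density estimate of
  the presences, restricted to a buffered minimum convex polygon, and
* target-guild sampling, which reuses occurrence records of similar
  species (matched on life form) clipped to a 99% KDE isopleth of the
  focal presences.

The KDE is a Gaussian product kernel with per-axis bandwidths
(Silverman's rule per axis when "auto").  Isopleth extraction and
density-weighted sampling both operate on the KDE discretized to the
analysis grid; the isopleth level is chosen by sorting cells by density
and accumulating mass, ties broken by flat cell index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon, box, mapping
from shapely.ops import unary_union

from .occurrences import OccurrenceSet
from .raster import RasterGrid


class DegenerateGeometryError(ValueError):
    """Too few / collinear points for a polygon, or zero bandwidth."""


class EmptyTargetError(ValueError):
    """No target-guild records match the filter inside the region."""


class SamplingError(RuntimeError):
    """The sampling extent carries no density mass."""


class ExtentKind(str, Enum):
    BUFFERED_MCP = "buffered_mcp"
    ISOPLETH_99 = "isopleth_99"


@dataclass
class SamplingExtent:
    polygon: Polygon
    construction: ExtentKind
    buffer_distance: Optional[float] = None
    #: optional raster mask of included cells (isopleth construction)
    mask: Optional[np.ndarray] = None
    grid: Optional[RasterGrid] = None

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise DegenerateGeometryError("extent polygon is empty or invalid")

    def contains_points(self, x, y) -> np.ndarray:
        """Boundary-inclusive point-in-extent test."""
        return shapely.intersects_xy(self.polygon, x, y)

    def write_geojson(self, path) -> None:
        payload = {
            "type": "Feature",
            "geometry": mapping(self.polygon),
            "properties": {
                "construction": self.construction.value,
                "buffer_distance": self.buffer_distance,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class KernelDensity:
    """Gaussian product-kernel density over 2-D presence points."""

    support_points: np.ndarray
    bandwidth: np.ndarray  # per-axis, shape (2,)

    def __post_init__(self) -> None:
        self.support_points = np.asarray(self.support_points, dtype=float).reshape(
            -1, 2
        )
        self.bandwidth = np.asarray(self.bandwidth, dtype=float).reshape(2)
        if np.any(self.bandwidth <= 0):
            raise DegenerateGeometryError("bandwidth must be positive on both axes")

    def pdf(self, x, y) -> np.ndarray:
        """Density at points; integrates to 1 over the plane."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        hx, hy = self.bandwidth
        pts = self.support_points
        norm = 1.0 / (2.0 * np.pi * hx * hy * len(pts))
        out = np.zeros(x.shape, dtype=float)
        # chunk over support to bound memory on large grids
        flat_x = x.ravel()
        flat_y = y.ravel()
        acc = np.zeros(flat_x.size, dtype=float)
        step = max(1, int(2e6 // max(flat_x.size, 1)) or 1)
        for i in range(0, len(pts), step):
            px = pts[i : i + step, 0][:, None]
            py = pts[i : i + step, 1][:, None]
            z = ((flat_x[None, :] - px) / hx) ** 2 + (
                (flat_y[None, :] - py) / hy
            ) ** 2
            acc += np.exp(-0.5 * z).sum(axis=0)
        out = (norm * acc).reshape(x.shape)
        return out

    def evaluate_on_grid(self, template: RasterGrid) -> RasterGrid:
        X, Y = template.cell_centers()
        return template.like(self.pdf(X, Y))


def silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Per-axis Silverman rule for a 2-D Gaussian product kernel.

    h_j = sigma_j * (n * (d + 2) / 4)^(-1/(d+4)) with d = 2.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    sigma = pts.std(axis=0, ddof=1)
    factor = (n * (2 + 2) / 4.0) ** (-1.0 / (2 + 4))
    return sigma * factor


def buffered_mcp(
    presences: Union[np.ndarray, Sequence], buffer_mode: str = "max_range"
) -> SamplingExtent:
    """Minimum convex polygon dilated by one third of the coordinate range.

    ``buffer_mode="max_range"`` (default) dilates uniformly by
    (1/3) * max(x_range, y_range).  ``"per_axis"`` applies an
    anisotropic dilation of (1/3) * x_range horizontally and
    (1/3) * y_range vertically (implemented by buffering in a
    y-rescaled frame).
    """
    pts = np.asarray(presences, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 presence points")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegenerateGeometryError("presence points are collinear")
    x_range = float(pts[:, 0].max() - pts[:, 0].min())
    y_range = float(pts[:, 1].max() - pts[:, 1].min())
    if buffer_mode == "max_range":
        dist = max(x_range, y_range) / 3.0
        poly = hull.buffer(dist)
    elif buffer_mode == "per_axis":
        bx, by = x_range / 3.0, y_range / 3.0
        dist = max(bx, by)
        scale = bx / by if by > 0 else 1.0
        scaled = shapely.transform(
            hull, lambda c: np.column_stack([c[:, 0], c[:, 1] * scale])
        )
        poly = shapely.transform(
            scaled.buffer(bx),
            lambda c: np.column_stack([c[:, 0], c[:, 1] / scale]),
        )
    else:
        raise ValueError(f"unknown buffer_mode {buffer_mode!r}")
    return SamplingExtent(
        polygon=poly, construction=ExtentKind.BUFFERED_MCP, buffer_distance=dist
    )


def fit_kde(
    presences: Union[np.ndarray, Sequence],
    bandwidth: Union[str, float, Sequence[float]] = "auto",
) -> KernelDensity:
    """Fit the Gaussian product-kernel density to presence coordinates."""
    pts = np.asarray(presences, dtype=float).reshape(-1, 2)
    if len(np.unique(pts, axis=0)) < 2:
        raise DegenerateGeometryError("need at least 2 distinct points for a KDE")
    if isinstance(bandwidth, str):
        if bandwidth != "auto":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        bw = silverman_bandwidth(pts)
        # degenerate axis (all identical along one axis): borrow the other
        if np.any(bw <= 0):
            fallback = max(bw.max(), 0.0)
            if fallback <= 0:
                raise DegenerateGeometryError("all points identical on both axes")
            bw = np.where(bw <= 0, fallback, bw)
    else:
        bw = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,)).copy()
        if np.any(bw <= 0):
            raise DegenerateGeometryError("bandwidth must be positive")
    return KernelDensity(support_points=pts, bandwidth=bw)


def kde_isopleth(
    k: KernelDensity, mass: float, template: RasterGrid
) -> SamplingExtent:
    """Smallest density-superlevel region (on the grid) holding >= ``mass``.

    Cells are sorted by density (descending, ties by flat index) and
    accumulated until the requested density mass is enclosed; the region
    is returned both as a cell mask and as the polygonized union of the
    selected cell squares.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    dens = k.evaluate_on_grid(template).values
    flat = dens.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    total = csum[-1]
    if total <= 0:
        raise SamplingError("density mass on the grid is zero")
    n_keep = int(np.searchsorted(csum, mass * total, side="left")) + 1
    keep = order[:n_keep]
    mask = np.zeros(flat.size, dtype=bool)
    mask[keep] = True
    mask = mask.reshape(dens.shape)
    poly = _mask_to_polygon(mask, template)
    return SamplingExtent(
        polygon=poly,
        construction=ExtentKind.ISOPLETH_99,
        buffer_distance=None,
        mask=mask,
        grid=template,
    )


def _mask_to_polygon(mask: np.ndarray, grid: RasterGrid) -> Polygon:
    rows, cols = np.nonzero(mask)
    cs = grid.cell_size
    boxes = []
    for r, c in zip(rows, cols):
        x_left = grid.x0 + c * cs
        y_bottom = grid.y0 + (grid.nrows - 1 - r) * cs
        boxes.append(box(x_left, y_bottom, x_left + cs, y_bottom + cs))
    merged = unary_union(boxes)
    return merged


def sample_kde_background(
    k: KernelDensity,
    extent: SamplingExtent,
    n: int,
    seed: int,
    template: Optional[RasterGrid] = None,
) -> "BackgroundSet":
    """Draw ``n`` background points with probability proportional to the
    KDE density restricted to ``extent``.

    The density is discretized to the analysis grid; cells whose centers
    fall inside the extent form the support.  A sampled point is placed
    uniformly within its cell (redrawn, center fallback, if the jittered
    position escapes the extent polygon at a ragged edge).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if template is None:
        template = extent.grid
    if template is None:
        raise ValueError("a template grid is required to discretize the density")
    dens = k.evaluate_on_grid(template).values
    X, Y = template.cell_centers()
    if extent.mask is not None and extent.grid is template:
        inside = extent.mask
    else:
        inside = extent.contains_points(X.ravel(), Y.ravel()).reshape(X.shape)
    weights = np.where(inside, dens, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise SamplingError("extent and density support are disjoint")
    rng = np.random.default_rng(seed)
    idx = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(idx, template.shape)
    cx, cy = template.center_of_cell(rows, cols)
    cs = template.cell_size
    px = cx + (rng.random(n) - 0.5) * cs
    py = cy + (rng.random(n) - 0.5) * cs
    bad = ~extent.contains_points(px, py)
    for _ in range(20):
        if not bad.any():
            break
        px[bad] = cx[bad] + (rng.random(bad.sum()) - 0.5) * cs
        py[bad] = cy[bad] + (rng.random(bad.sum()) - 0.5) * cs
        bad = ~extent.contains_points(px, py)
    # cell centers are inside by construction; final fallback
    px = np.where(bad, cx, px)
    py = np.where(bad, cy, py)
    return BackgroundSet(
        points=np.column_stack([px, py]),
        method="kde",
        n=n,
        seed=seed,
        extent=extent,
    )


def sample_target_background(
    target_occurrences: OccurrenceSet,
    lifeform_filter: str,
    region: SamplingExtent,
    n: int,
    seed: int,
) -> "BackgroundSet":
    """Target-guild background: same-lifeform occurrences inside ``region``.

    If more than ``n`` candidates remain a simple random subsample of
    ``n`` is drawn (seeded); otherwise all are kept and ``n`` shrinks.
    """
    want = lifeform_filter.strip().lower()
    matches = [
        r
        for r in target_occurrences.records
        if (r.lifeform or "").strip().lower() == want
    ]
    if not matches:
        raise EmptyTargetError(f"no target records with lifeform {lifeform_filter!r}")
    xy = np.array([[r.x, r.y] for r in matches], dtype=float)
    inside = region.contains_points(xy[:, 0], xy[:, 1])
    xy = xy[inside]
    if len(xy) == 0:
        raise EmptyTargetError("all matching target records fall outside the region")
    rng = np.random.default_rng(seed)
    if len(xy) > n:
        pick = rng.choice(len(xy), size=n, replace=False)
        pick.sort()
        xy = xy[pick]
    else:
        n = len(xy)
    return BackgroundSet(points=xy, method="target", n=n, seed=seed, extent=region)


@dataclass
class BackgroundSet:
    points: np.ndarray
    method: str
    n: int
    seed: int
    extent: SamplingExtent

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) != self.n:
            raise ValueError("point count does not match n")

    def __len__(self) -> int:
        return self.n

    @property
    def xy(self) -> np.ndarray:
        return self.points

    def write_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "method": self.method,
                "seed": self.seed,
            }
        ).to_csv(path, index=False)
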