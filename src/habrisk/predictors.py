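"""Predictor harmonization, point extraction, and collinearity screening.

Harmonization resamples each source raster onto a template geometry by
nearest-neighbour lookup of source cell centers (the project/aggregate/
resample/clip step reduced to a planar common-CRS setting).  Screening
removes one of any variable pair whose max(|Pearson|, |Spearman|,
|Kendall tau-b|) exceeds a threshold (0.7 default), computed jointly on
presence and background rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .background import BackgroundSet
from .occurrences import OccurrenceSet
from .raster import RasterGrid, RasterStack


class CoverageError(ValueError):
    """Source raster does not overlap the template."""


class ExtractionError(ValueError):
    """No rows survive point extraction."""


def parc_harmonize(src: RasterGrid, template: RasterGrid) -> RasterGrid:
    """Resample ``src`` onto ``template``'s geometry (nearest neighbour).

    Each template cell takes the value of the source cell whose center is
    nearest the template cell's center; template cells whose centers fall
    outside the source footprint become nodata.  Idempotent when ``src``
    already sits on the template geometry.
    """
    sx0, sy0, sx1, sy1 = src.bounds
    tx0, ty0, tx1, ty1 = template.bounds
    if tx0 >= sx1 or tx1 <= sx0 or ty0 >= sy1 or ty1 <= sy0:
        raise CoverageError("source and template bounds are disjoint")
    X, Y = template.cell_centers()
    # nearest source cell center index
    col = np.rint((X - src.x0) / src.cell_size - 0.5).astype(int)
    row_bu = np.rint((Y - src.y0) / src.cell_size - 0.5).astype(int)
    row = src.nrows - 1 - row_bu
    ok = (row >= 0) & (row < src.nrows) & (col >= 0) & (col < src.ncols)
    out = np.full(template.shape, np.nan)
    out[ok] = src.values[row[ok], col[ok]]
    if not ok.any():
        raise CoverageError("no template cell center falls inside the source")
    return template.like(out)


@dataclass
class DesignTable:
    """Presence/background rows with extracted predictor values.

    ``frame`` columns: point_id, x, y, response (1 presence / 0
    background), then one column per predictor.  Rows touching nodata in
    any predictor are dropped at construction and logged.
    """

    frame: pd.DataFrame
    variables: list[str]
    drop_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        resp = self.frame["response"].to_numpy()
        if not np.isin(resp, (0, 1)).all():
            raise ValueError("response must be 0/1")
        if self.frame[self.variables].isna().any().any():
            raise ValueError("design table contains nodata predictor values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def response(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=int)

    def matrix(self, variables: Optional[Sequence[str]] = None) -> np.ndarray:
        cols = list(variables) if variables is not None else self.variables
        return self.frame[cols].to_numpy(dtype=float)

    def subset_variables(self, variables: Sequence[str]) -> "DesignTable":
        keep = ["point_id", "x", "y", "response", *variables]
        return DesignTable(
            self.frame[keep].copy(), list(variables), dict(self.drop_log)
        )

    def subset_rows(self, index: np.ndarray) -> "DesignTable":
        return DesignTable(
            self.frame.iloc[index].reset_index(drop=True),
            list(self.variables),
            dict(self.drop_log),
        )


def extract_design_table(
    stack: RasterStack,
    presences: Union[OccurrenceSet, np.ndarray],
    background: Union[BackgroundSet, np.ndarray],
    variables: Optional[Sequence[str]] = None,
) -> DesignTable:
    """Build the model matrix by sampling the stack at presence and
    background coordinates.

    Out-of-bounds points and points landing on a nodata cell are dropped
    and counted in ``drop_log``.
    """
    names = list(variables) if variables is not None else stack.names
    pres_xy = presences.xy if hasattr(presences, "xy") else np.asarray(presences)
    back_xy = background.xy if hasattr(background, "xy") else np.asarray(background)
    pres_xy = np.asarray(pres_xy, dtype=float).reshape(-1, 2)
    back_xy = np.asarray(back_xy, dtype=float).reshape(-1, 2)
    xy = np.vstack([pres_xy, back_xy])
    resp = np.concatenate(
        [np.ones(len(pres_xy), dtype=int), np.zeros(len(back_xy), dtype=int)]
    )
    values = stack.sample(xy[:, 0], xy[:, 1], names)
    in_bounds = stack.template.in_bounds(xy[:, 0], xy[:, 1])
    has_data = ~np.isnan(values).any(axis=1)
    keep = in_bounds & has_data
    drop_log = {
        "out_of_bounds": int((~in_bounds).sum()),
        "nodata_cell": int((in_bounds & ~has_data).sum()),
    }
    if not keep.any():
        raise ExtractionError("no points with valid predictor values")
    frame = pd.DataFrame(
        {
            "point_id": np.arange(len(xy))[keep],
            "x": xy[keep, 0],
            "y": xy[keep, 1],
            "response": resp[keep],
        }
    )
    for j, name in enumerate(names):
        frame[name] = values[keep, j]
    return DesignTable(frame.reset_index(drop=True), names, drop_log)


@dataclass
class CorrelationScreen:
    pairwise_max_r: pd.DataFrame
    threshold: float = 0.7
    retained: list[str] = field(default_factory=list)
    removed: list[tuple[str, str]] = field(default_factory=list)  # (var, reason)
    zero_variance: list[str] = field(default_factory=list)

    def write_csv(self, matrix_path, removals_path) -> None:
        self.pairwise_max_r.to_csv(matrix_path)
        pd.DataFrame(self.removed, columns=["variable", "reason"]).to_csv(
            removals_path, index=False
        )


def max_correlation_matrix(
    t: DesignTable,
    variables: Optional[Sequence[str]] = None,
    threshold: float = 0.7,
) -> CorrelationScreen:
    """Pairwise max of |Pearson|, |Spearman|, |Kendall tau-b|.

    Zero-variance variables get zero entries (and are flagged) since no
    correlation is defined for them.
    """
    names = list(variables) if variables is not None else list(t.variables)
    if len(t) < 3:
        raise ValueError("need at least 3 rows to compute correlations")
    X = t.matrix(names)
    k = len(names)
    mat = np.eye(k)
    zero_var = [names[j] for j in range(k) if np.std(X[:, j]) == 0]
    for i in range(k):
        for j in range(i + 1, k):
            if names[i] in zero_var or names[j] in zero_var:
                r = 0.0
            else:
                xi, xj = X[:, i], X[:, j]
                pear = abs(stats.pearsonr(xi, xj).statistic)
                spear = abs(stats.spearmanr(xi, xj).statistic)
                kend = abs(stats.kendalltau(xi, xj).statistic)
                r = float(np.nanmax([pear, spear, kend]))
            mat[i, j] = mat[j, i] = r
    frame = pd.DataFrame(mat, index=names, columns=names)
    return CorrelationScreen(
        pairwise_max_r=frame, threshold=threshold, zero_variance=zero_var
    )


def select_uncorrelated(
    screen: CorrelationScreen,
    priority: Union[str, Sequence[str]] = "auto",
) -> CorrelationScreen:
    """Drop one member of each over-threshold pair until none remains.

    With an explicit ``priority`` list (highest priority first), the
    lower-priority member of the worst offending pair is removed.  With
    ``"auto"``, the retained variable with the largest mean absolute
    correlation to the other retained variables is removed (ties broken
    lexicographically).
    """
    names = list(screen.pairwise_max_r.columns)
    mat = screen.pairwise_max_r.to_numpy()
    retained = list(names)
    removed: list[tuple[str, str]] = list(screen.removed)

    def pair_over() -> Optional[tuple[str, str]]:
        idx = [names.index(v) for v in retained]
        best = None
        best_r = screen.threshold
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1 :]:
                if mat[a, b] > best_r:
                    best_r = mat[a, b]
                    best = (names[a], names[b])
        return best

    while True:
        pair = pair_over()
        if pair is None:
            break
        a, b = pair
        if priority == "auto":
            idx = [names.index(v) for v in retained]

            def mean_abs(v: str) -> float:
                vi = names.index(v)
                others = [j for j in idx if j != vi]
                return float(np.mean([mat[vi, j] for j in others])) if others else 0.0

            ra, rb = mean_abs(a), mean_abs(b)
            victim = (
                a
                if (ra > rb or (ra == rb and a > b))
                else b
            )
        else:
            prio = list(priority)

            def rank(v: str) -> int:
                return prio.index(v) if v in prio else len(prio)

            victim = a if rank(a) > rank(b) else b
        other = b if victim == a else a
        retained.remove(victim)
        removed.append(
            (victim, f"max |r|={mat[names.index(a), names.index(b)]:.3f} with {other}")
        )
    return CorrelationScreen(
        pairwise_max_r=screen.pairwise_max_r,
        threshold=screen.threshold,
        retained=retained,
        removed=removed,
        zero_variance=list(screen.zero_variance),
    )
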