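"""Binarization rules, equal-weight ensembles, environmental-similarity
(MESS) surfaces, and permutation delta-AUC variable importance.

Threshold conventions: a cell or point is suitable iff score >= the
threshold value.  The percentile rules use the exclusion convention
threshold = (floor(q*n) + 1)-th smallest presence score, which
guarantees exactly floor(q*n) training presences are classified
unsuitable; with q=0 this reduces to the minimum-predicted-presence
rule, so mpp <= pct1 <= pct10 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import ScoredPoints, rank_auc
from .predictors import DesignTable
from .raster import RasterAlignmentError, RasterGrid, RasterStack
from .sdm_models import FittedModel

RULE_KINDS = ("mpp", "pct1", "pct10", "mss")

_RULE_QUANTILE = {"mpp": 0.0, "pct1": 0.01, "pct10": 0.10}


@dataclass
class ThresholdRule:
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown threshold rule {self.kind!r}")


def compute_threshold(
    rule_kind: str,
    presence_scores: Sequence[float],
    all_scores: Optional[ScoredPoints] = None,
) -> ThresholdRule:
    """Compute one of the four binarization thresholds.

    mpp/pct1/pct10 need only presence scores; mss additionally needs the
    background scores (via ``all_scores``) and maximizes sensitivity +
    specificity over observed candidate thresholds, ties going to the
    lowest threshold.
    """
    pres = np.sort(np.asarray(presence_scores, dtype=float).ravel())
    if pres.size == 0:
        raise ValueError("presence scores must be non-empty")
    if rule_kind in _RULE_QUANTILE:
        q = _RULE_QUANTILE[rule_kind]
        drop = int(np.floor(q * pres.size))
        drop = min(drop, pres.size - 1)
        return ThresholdRule(rule_kind, float(pres[drop]))
    if rule_kind == "mss":
        if all_scores is None or not all_scores.both_classes():
            raise ValueError("mss requires scores for both classes")
        candidates = np.unique(all_scores.scores)
        p_sorted = np.sort(all_scores.presence_scores)
        b_sorted = np.sort(all_scores.background_scores)
        n1, n0 = len(p_sorted), len(b_sorted)
        k = np.searchsorted(p_sorted, candidates, side="left")  # presences < t
        m = np.searchsorted(b_sorted, candidates, side="left")  # background < t
        # sens + spec = (n1-k)/n1 + m/n0, compared in exact integers so
        # ties resolve deterministically to the lowest threshold
        objective = (n1 - k) * n0 + m * n1
        best = int(np.argmax(objective))  # first maximizer = lowest threshold
        return ThresholdRule("mss", float(candidates[best]))
    raise ValueError(f"unknown threshold rule {rule_kind!r}")


def binarize_raster(suitability: RasterGrid, rule: ThresholdRule) -> RasterGrid:
    """1 where suitability >= rule.value, 0 elsewhere, nodata propagated."""
    vals = suitability.values
    out = np.where(np.isnan(vals), np.nan, (vals >= rule.value).astype(float))
    return suitability.like(out)


@dataclass
class EnsembleProduct:
    rule: ThresholdRule
    binary_layers: dict[str, RasterGrid]
    ensemble: RasterGrid
    retained_count: int


def build_ensemble(
    binaries: dict[str, RasterGrid], rule: ThresholdRule
) -> EnsembleProduct:
    """Cellwise count of retained models predicting suitable."""
    if not binaries:
        raise ValueError("no binary layers to ensemble")
    names = list(binaries)
    template = binaries[names[0]]
    for name in names[1:]:
        if not binaries[name].same_geometry(template):
            raise RasterAlignmentError(f"binary layer {name!r} is misaligned")
    stackvals = np.stack([binaries[n].values for n in names])
    any_nodata = np.isnan(stackvals).any(axis=0)
    counts = np.nansum(stackvals, axis=0)
    counts[any_nodata] = np.nan
    return EnsembleProduct(
        rule=rule,
        binary_layers=dict(binaries),
        ensemble=template.like(counts),
        retained_count=len(names),
    )


@dataclass
class MessSurface:
    per_variable_similarity: dict[str, RasterGrid]
    mess: RasterGrid
    variables: list[str]
    excluded: list[str] = field(default_factory=list)


def _similarity(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Similarity of each value to the reference sample (in percent; can
    be negative outside the reference range, at most 100)."""
    ref = np.sort(np.asarray(reference, dtype=float))
    rmin, rmax = ref[0], ref[-1]
    span = rmax - rmin
    f = 100.0 * np.searchsorted(ref, values, side="left") / ref.size
    out = np.empty(values.shape, dtype=float)
    below = f == 0
    above = f == 100
    lower = (f > 0) & (f <= 50)
    upper = (f > 50) & (f < 100)
    out[below] = 100.0 * (values[below] - rmin) / span
    out[lower] = 2.0 * f[lower]
    out[upper] = 2.0 * (100.0 - f[upper])
    out[above] = 100.0 * (rmax - values[above]) / span
    return out


def mess_surface(
    stack: RasterStack,
    reference: DesignTable,
    variables: Optional[Sequence[str]] = None,
) -> MessSurface:
    """Multivariate environmental similarity: per-variable similarity to
    the reference rows, combined by cellwise minimum.

    Negative values flag cells outside the reference range of at least
    one variable.  Degenerate variables (max == min in the reference)
    are excluded and reported.
    """
    names = list(variables) if variables is not None else list(reference.variables)
    missing = [v for v in names if v not in stack]
    if missing:
        raise KeyError(f"stack lacks layers: {missing}")
    per_var: dict[str, RasterGrid] = {}
    excluded: list[str] = []
    template = stack.template
    for name in names:
        ref = reference.frame[name].to_numpy(dtype=float)
        if np.max(ref) == np.min(ref):
            excluded.append(name)
            continue
        vals = stack[name].values
        sim = np.full(vals.shape, np.nan)
        ok = ~np.isnan(vals)
        sim[ok] = _similarity(vals[ok], ref)
        per_var[name] = template.like(sim)
    if not per_var:
        raise ValueError("no usable reference variables for MESS")
    stacked = np.stack([per_var[n].values for n in per_var])
    with np.errstate(invalid="ignore"):
        mess = np.nanmin(stacked, axis=0)
    mess[np.isnan(stacked).any(axis=0)] = np.nan
    return MessSurface(
        per_variable_similarity=per_var,
        mess=template.like(mess),
        variables=list(per_var),
        excluded=excluded,
    )


@dataclass
class ImportanceRanking:
    per_variable: list[tuple[str, float]]  # sorted by delta_auc descending
    n_permutations: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_variable, columns=["variable", "delta_auc"])
        df["rank"] = np.arange(1, len(df) + 1)
        positive = df["delta_auc"].clip(lower=0.0).sum()
        df["percent_contribution"] = np.where(
            (df["delta_auc"] > 0) & (positive > 0),
            100.0 * df["delta_auc"].clip(lower=0.0) / positive if positive else 0.0,
            0.0,
        )
        return df


def permutation_importance(
    m: FittedModel,
    t: DesignTable,
    n_permutations: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """Delta-AUC importance: shuffle one predictor column across all rows
    (presence and background jointly), rescore, and average the AUC drop
    over ``n_permutations`` shuffles."""
    rng = np.random.default_rng(seed)
    X = t.matrix(m.input_variables)
    y = t.response
    base_auc = rank_auc(ScoredPoints(m.predict(X), y))
    rows = []
    for j, name in enumerate(m.input_variables):
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(rank_auc(ScoredPoints(m.predict(Xp), y)))
        rows.append((name, base_auc - float(np.mean(drops))))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return ImportanceRanking(
        per_variable=rows, n_permutations=n_permutations, seed=seed
    )
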