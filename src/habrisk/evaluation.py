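"""Model evaluation: rank-based AUC, precision-recall AUC, confusion
metrics, the sensitivity = specificity evaluation threshold, and seeded
stratified 10-fold cross-validation.

Conventions (applied throughout the package): a point is predicted
suitable iff its score is >= the threshold; AUC-PR is the average
precision (step interpolation); per-fold evaluation thresholds are
derived from each fold's *training* scores to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

if TYPE_CHECKING:  # pragma: no cover
    from .predictors import DesignTable
    from .sdm_models import ModelSpec


class UndefinedMetricError(ValueError):
    """Both classes are required for rank-based metrics."""


class FoldError(ValueError):
    """Too few presences to populate every fold."""


@dataclass
class ScoredPoints:
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have the same length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def presence_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def background_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    def both_classes(self) -> bool:
        return 0 < self.labels.sum() < len(self.labels)


@dataclass
class MetricSet:
    auc_roc: float
    auc_pr: float
    pcc: float  # percent, 0..100
    kappa: float
    tss: float
    sensitivity: float
    specificity: float
    threshold_used: float
    split: str = "train"  # "train" | "cv_mean"

    def __post_init__(self) -> None:
        assert abs(self.tss - (self.sensitivity + self.specificity - 1.0)) < 1e-12, (
            "TSS identity violated"
        )
        for name in ("auc_roc", "auc_pr", "sensitivity", "specificity"):
            v = getattr(self, name)
            assert -1e-12 <= v <= 1 + 1e-12, f"{name}={v} out of [0,1]"
        assert -1 - 1e-12 <= self.kappa <= 1 + 1e-12

    def as_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "pcc": self.pcc,
            "kappa": self.kappa,
            "tss": self.tss,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold_used": self.threshold_used,
            "split": self.split,
        }


def rank_auc(p: ScoredPoints) -> float:
    """Probability that a random presence outscores a random background
    point, ties counted one half (Mann-Whitney formulation)."""
    if not p.both_classes():
        raise UndefinedMetricError("AUC needs both classes")
    ranks = rankdata(p.scores)  # average ranks handle ties
    n1 = int(p.labels.sum())
    n0 = len(p.labels) - n1
    r1 = ranks[p.labels == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def precision_recall_auc(p: ScoredPoints) -> float:
    """Average precision (step-interpolated area under the PR curve)."""
    if not p.both_classes():
        raise UndefinedMetricError("AUC-PR needs both classes")
    return float(average_precision_score(p.labels, p.scores))


def threshold_metrics(
    p: ScoredPoints, threshold: float, split: str = "train"
) -> MetricSet:
    """Confusion-matrix metrics at ``threshold`` (suitable iff score >=
    threshold), plus the rank metrics."""
    if not p.both_classes():
        raise UndefinedMetricError("metrics need both classes")
    pred = p.scores >= threshold
    actual = p.labels == 1
    tp = int((pred & actual).sum())
    tn = int((~pred & ~actual).sum())
    fp = int((pred & ~actual).sum())
    fn = int((~pred & actual).sum())
    n = tp + tn + fp + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    pcc = 100.0 * (tp + tn) / n
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return MetricSet(
        auc_roc=rank_auc(p),
        auc_pr=precision_recall_auc(p),
        pcc=pcc,
        kappa=kappa,
        tss=sens + spec - 1.0,
        sensitivity=sens,
        specificity=spec,
        threshold_used=float(threshold),
        split=split,
    )


def sens_eq_spec_threshold(p: ScoredPoints) -> float:
    """Observed score minimizing |sensitivity - specificity|; ties go to
    the lower threshold."""
    if not p.both_classes():
        raise UndefinedMetricError("threshold needs both classes")
    candidates = np.unique(p.scores)
    pres = np.sort(p.presence_scores)
    back = np.sort(p.background_scores)
    n1, n0 = len(pres), len(back)
    # sens(t) = (n1-k)/n1 with k presences < t; spec(t) = m/n0 with m
    # background < t.  |sens - spec| is compared via its exact integer
    # numerator so ties break deterministically to the lowest threshold.
    k = np.searchsorted(pres, candidates, side="left")
    m = np.searchsorted(back, candidates, side="left")
    gap = np.abs((n1 - k) * n0 - m * n1)
    best = int(np.argmin(gap))  # argmin returns the first (lowest) minimizer
    return float(candidates[best])


@dataclass
class CrossValidationResult:
    cv_mean: MetricSet
    per_fold: pd.DataFrame
    fold_assignment: np.ndarray = field(repr=False, default=None)


def cross_validate(
    spec: "ModelSpec",
    t: "DesignTable",
    k: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Seeded stratified k-fold cross-validation of one model spec.

    Each fold's evaluation threshold is the sensitivity = specificity
    point of the fold's *training* scores; per-fold metrics are averaged
    unweighted into ``cv_mean``.
    """
    from .sdm_models import fit_model  # local import; avoids a cycle

    y = t.response
    if y.sum() < k or (len(y) - y.sum()) < k:
        raise FoldError(f"need at least {k} points of each class for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    assignment = np.empty(len(y), dtype=int)
    X_index = np.arange(len(y))
    for fold, (tr, te) in enumerate(skf.split(X_index, y)):
        assignment[te] = fold
        t_tr = t.subset_rows(tr)
        t_te = t.subset_rows(te)
        model = fit_model(spec, t_tr)
        train_scores = model.score_table(t_tr)
        test_scores = model.score_table(t_te)
        thr = sens_eq_spec_threshold(ScoredPoints(train_scores, t_tr.response))
        ms = threshold_metrics(
            ScoredPoints(test_scores, t_te.response), thr, split=f"fold{fold}"
        )
        rows.append({"fold": fold, **ms.as_dict()})
    per_fold = pd.DataFrame(rows)
    num_cols = [
        "auc_roc",
        "auc_pr",
        "pcc",
        "kappa",
        "tss",
        "sensitivity",
        "specificity",
        "threshold_used",
    ]
    means = per_fold[num_cols].mean()
    cv_mean = MetricSet(
        auc_roc=float(means["auc_roc"]),
        auc_pr=float(means["auc_pr"]),
        pcc=float(means["pcc"]),
        kappa=float(means["kappa"]),
        tss=float(means["sensitivity"] + means["specificity"] - 1.0),
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        threshold_used=float(means["threshold_used"]),
        split="cv_mean",
    )
    return CrossValidationResult(
        cv_mean=cv_mean, per_fold=per_fold, fold_assignment=assignment
    )
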