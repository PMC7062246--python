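"""The five-algorithm model stage behind one interface.

Algorithms: AIC-stepwise binomial GLM with squared and interaction
terms, additive (degree-1) piecewise-linear adaptive regression splines
pruned by generalized cross-validation, boosted regression trees
(bag fraction 0.5, tree count by internal holdout deviance), random
forest, and a maxent-style penalized logistic regression on linear +
quadratic + hinge features with heavily weighted background (the
weighted-logistic equivalence of maxent; the Java implementation is not
bundled).

All fits are seeded and are made row-order invariant by sorting the
design rows into a canonical order before fitting.  Suitability scores
live in [0, 1]: inverse-logit for glm/brt/maxent-like, tree-vote
fraction for rf, least-squares response clamped to [0, 1] for mars.

Quality gates: a model is flagged overfit when train AUC exceeds
cross-validated AUC by more than ``overfit_gap`` (0.05), re-tuned once
with stronger regularization, and dropped if still overfit or if its
cross-validated AUC falls below ``min_cv_auc`` (0.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .evaluation import ScoredPoints, rank_auc
from .predictors import DesignTable
from .raster import RasterGrid, RasterStack

ALGORITHMS = ("glm_stepwise", "mars", "brt", "rf", "maxent_like")

DEFAULT_SETTINGS: dict[str, dict] = {
    "glm_stepwise": {
        "terms": "full",  # main effects + squares + pairwise interactions
        "max_candidate_terms": 200,
        "max_steps": 30,
    },
    "mars": {
        "degree": 1,
        "gcv_penalty": 2.0,
        "max_terms": 21,
        "n_knots": 15,
    },
    "brt": {
        "bag_fraction": 0.5,
        "learning_rate": 0.01,
        "tree_depth": 3,
        "max_trees": 1000,
        "holdout_fraction": 0.2,
    },
    "rf": {
        "n_trees": 1000,
        "max_features": "sqrt",
        "min_samples_leaf": 1,
        "max_depth": None,
        "bootstrap": True,
    },
    "maxent_like": {
        "c": 1.0,
        "n_hinge_knots": 5,
        "background_weight": 100.0,
    },
}

#: One automated re-tuning pass with stronger regularization, applied
#: when the overfitting gate trips.
RETUNE_OVERRIDES: dict[str, dict] = {
    "glm_stepwise": {"terms": "main_only"},
    "mars": {"gcv_penalty": 4.0, "max_terms": 11},
    "brt": {"learning_rate": 0.005, "tree_depth": 2},
    "rf": {"min_samples_leaf": 20, "max_depth": 12},
    "maxent_like": {"c": 0.1},
}


class ClassError(ValueError):
    """The design table holds a single class."""


class FitError(RuntimeError):
    pass


class GateOrderingError(RuntimeError):
    """Gates applied before cross-validation filled cv_auc."""


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    background_method: str = "kde"
    settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        unknown = set(self.settings) - set(DEFAULT_SETTINGS[self.algorithm])
        if unknown:
            raise ValueError(
                f"unknown settings for {self.algorithm}: {sorted(unknown)}"
            )

    def resolved_settings(self) -> dict:
        out = dict(DEFAULT_SETTINGS[self.algorithm])
        out.update(self.settings)
        return out


@dataclass
class FittedModel:
    spec: ModelSpec
    input_variables: list[str]
    variables_used: list[str]
    scorer: Callable[[np.ndarray], np.ndarray]
    train_auc: float
    cv_auc: Optional[float] = None
    gates: dict = field(
        default_factory=lambda: {"overfit_flag": False, "dropped": False, "reason": ""}
    )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for rows of ``X`` (columns =
        ``input_variables`` in order)."""
        out = np.asarray(self.scorer(np.asarray(X, dtype=float)), dtype=float)
        return np.clip(out, 0.0, 1.0)

    def score_table(self, t: DesignTable) -> np.ndarray:
        return self.predict(t.matrix(self.input_variables))

    def manifest(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "background_method": self.spec.background_method,
            "settings": self.spec.resolved_settings(),
            "seed": self.spec.seed,
            "input_variables": self.input_variables,
            "variables_used": self.variables_used,
            "train_auc": self.train_auc,
            "cv_auc": self.cv_auc,
            "gates": self.gates,
        }


# ---------------------------------------------------------------------
# helpers


def _canonical_rows(t: DesignTable) -> DesignTable:
    """Sort rows into a canonical order so fits ignore input row order."""
    keys = [t.frame[v].to_numpy() for v in t.variables[::-1]]
    keys += [t.frame["y"].to_numpy(), t.frame["x"].to_numpy()]
    keys += [-t.frame["response"].to_numpy()]
    order = np.lexsort(keys)
    return t.subset_rows(order)


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------
# GLM with bidirectional AIC stepwise


def _glm_term_columns(Xs: np.ndarray, terms: list[tuple]) -> np.ndarray:
    cols = [np.ones(len(Xs))]
    for term in terms:
        if term[0] == "main":
            cols.append(Xs[:, term[1]])
        elif term[0] == "sq":
            cols.append(Xs[:, term[1]] ** 2)
        else:  # ("int", i, j)
            cols.append(Xs[:, term[1]] * Xs[:, term[2]])
    return np.column_stack(cols)


def _glm_aic_fit(y: np.ndarray, design: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=50)
        except Exception:
            return None, np.inf
    aic = float(res.aic)
    if not np.isfinite(aic):
        return None, np.inf
    return res, aic


def _fit_glm_stepwise(t: DesignTable, settings: dict, seed: int) -> "FittedModel":
    y = t.response
    X = t.matrix()
    std = _Standardizer(X)
    Xs = std(X)
    p = X.shape[1]
    candidates: list[tuple] = [("main", i) for i in range(p)]
    if settings["terms"] == "full":
        candidates += [("sq", i) for i in range(p)]
        candidates += [("int", i, j) for i in range(p) for j in range(i + 1, p)]
    candidates = candidates[: settings["max_candidate_terms"]]

    current = [("main", i) for i in range(p)]
    res, aic = _glm_aic_fit(y, _glm_term_columns(Xs, current))
    for _ in range(settings["max_steps"]):
        best_move, best_aic, best_res = None, aic, res
        for term in candidates:
            if term in current:
                continue
            trial = current + [term]
            r, a = _glm_aic_fit(y, _glm_term_columns(Xs, trial))
            if a < best_aic:
                best_move, best_aic, best_res = ("add", term), a, r
        for term in list(current):
            trial = [tm for tm in current if tm != term]
            if not trial:
                continue
            r, a = _glm_aic_fit(y, _glm_term_columns(Xs, trial))
            if a < best_aic:
                best_move, best_aic, best_res = ("drop", term), a, r
        if best_move is None:
            break
        kind, term = best_move
        if kind == "add":
            current.append(term)
        else:
            current.remove(term)
        aic, res = best_aic, best_res

    if res is None:
        # separation fallback: ridge logistic on main effects
        clf = LogisticRegression(C=1e4, max_iter=5000)
        clf.fit(Xs, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        current = [("main", i) for i in range(p)]
    else:
        params = np.asarray(res.params)

    terms = list(current)

    def scorer(Xnew: np.ndarray) -> np.ndarray:
        design = _glm_term_columns(std(Xnew), terms)
        return _sigmoid(design @ params)

    used = sorted(
        {t.variables[i] for tm in terms for i in tm[1:]},
        key=t.variables.index,
    )
    scores = scorer(X)
    return FittedModel(
        spec=None,  # filled by fit_model
        input_variables=list(t.variables),
        variables_used=used,
        scorer=scorer,
        train_auc=rank_auc(ScoredPoints(scores, y)),
    )


# ---------------------------------------------------------------------
# MARS (additive, degree 1), GCV pruning


def _fit_mars(t: DesignTable, settings: dict, seed: int) -> "FittedModel":
    if settings["degree"] != 1:
        raise ValueError("only additive (degree 1) splines are implemented")
    y = t.response.astype(float)
    X = t.matrix()
    n, p = X.shape
    n_knots = settings["n_knots"]
    penalty = settings["gcv_penalty"]
    max_terms = settings["max_terms"]

    # candidate hinge columns: per variable, per knot, both directions
    col_meta: list[tuple[int, float, int]] = []  # (var, knot, sign)
    cols = []
    for j in range(p):
        qs = np.quantile(X[:, j], np.linspace(0.05, 0.95, n_knots))
        for knot in np.unique(qs):
            cols.append(np.maximum(X[:, j] - knot, 0.0))
            col_meta.append((j, float(knot), +1))
            cols.append(np.maximum(knot - X[:, j], 0.0))
            col_meta.append((j, float(knot), -1))
    C = np.column_stack([np.ones(n)] + cols)  # column 0 = intercept
    G = C.T @ C
    cy = C.T @ y
    yty = float(y @ y)

    def rss_of(idx: list[int]) -> tuple[float, np.ndarray]:
        sub = np.ix_(idx, idx)
        try:
            b = np.linalg.solve(G[sub], cy[idx])
        except np.linalg.LinAlgError:
            b, *_ = np.linalg.lstsq(G[sub], cy[idx], rcond=None)
        return max(yty - float(b @ cy[idx]), 0.0), b

    selected = [0]
    rss, _ = rss_of(selected)
    # forward pass: add hinge pairs
    n_pairs = (C.shape[1] - 1) // 2
    while len(selected) + 2 <= max_terms:
        best = None
        best_rss = rss * (1 - 1e-4)
        for pair in range(n_pairs):
            i1, i2 = 1 + 2 * pair, 2 + 2 * pair
            if i1 in selected:
                continue
            r, _ = rss_of(selected + [i1, i2])
            if r < best_rss:
                best, best_rss = (i1, i2), r
        if best is None:
            break
        selected += list(best)
        rss = best_rss

    # backward pass: prune single columns, track GCV-optimal subset
    def gcv(r: float, m: int) -> float:
        c_eff = m + penalty * (m - 1) / 2.0
        denom = (1.0 - c_eff / n) ** 2
        return np.inf if denom <= 0 else (r / n) / denom

    best_subset = list(selected)
    best_gcv = gcv(rss, len(selected))
    work = list(selected)
    while len(work) > 1:
        trial_best, trial_rss = None, np.inf
        for col in work[1:]:  # never drop the intercept
            cand = [c for c in work if c != col]
            r, _ = rss_of(cand)
            if r < trial_rss:
                trial_best, trial_rss = cand, r
        work = trial_best
        g = gcv(trial_rss, len(work))
        if g < best_gcv:
            best_gcv, best_subset = g, list(work)

    _, beta = rss_of(best_subset)
    basis = [(col_meta[c - 1]) for c in best_subset if c != 0]
    intercept_included = 0 in best_subset

    def scorer(Xnew: np.ndarray) -> np.ndarray:
        out = np.zeros(len(Xnew))
        k = 0
        if intercept_included:
            out += beta[0]
            k = 1
        for (j, knot, sign), b in zip(basis, beta[k:]):
            h = (
                np.maximum(Xnew[:, j] - knot, 0.0)
                if sign > 0
                else np.maximum(knot - Xnew[:, j], 0.0)
            )
            out += b * h
        return np.clip(out, 0.0, 1.0)

    used = sorted({t.variables[j] for j, _, _ in basis}, key=t.variables.index)
    scores = scorer(X)
    return FittedModel(
        spec=None,
        input_variables=list(t.variables),
        variables_used=used,
        scorer=scorer,
        train_auc=rank_auc(ScoredPoints(scores, t.response)),
    )


# ---------------------------------------------------------------------
# Boosted regression trees


def _fit_brt(t: DesignTable, settings: dict, seed: int) -> "FittedModel":
    y = t.response
    X = t.matrix()
    holdout = settings["holdout_fraction"]
    max_trees = settings["max_trees"]
    Xtr, Xho, ytr, yho = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=seed
    )
    probe = GradientBoostingClassifier(
        learning_rate=settings["learning_rate"],
        max_depth=settings["tree_depth"],
        subsample=settings["bag_fraction"],
        n_estimators=max_trees,
        random_state=seed,
    )
    probe.fit(Xtr, ytr)
    eps = 1e-12
    losses = []
    for proba in probe.staged_predict_proba(Xho):
        pr = np.clip(proba[:, 1], eps, 1 - eps)
        losses.append(-np.mean(yho * np.log(pr) + (1 - yho) * np.log(1 - pr)))
    best_n = int(np.argmin(losses)) + 1
    clf = GradientBoostingClassifier(
        learning_rate=settings["learning_rate"],
        max_depth=settings["tree_depth"],
        subsample=settings["bag_fraction"],
        n_estimators=best_n,
        random_state=seed,
    )
    clf.fit(X, y)

    def scorer(Xnew: np.ndarray) -> np.ndarray:
        return clf.predict_proba(Xnew)[:, 1]

    used = [
        v
        for v, imp in zip(t.variables, clf.feature_importances_)
        if imp > 0
    ]
    return FittedModel(
        spec=None,
        input_variables=list(t.variables),
        variables_used=used,
        scorer=scorer,
        train_auc=rank_auc(ScoredPoints(scorer(X), y)),
    )


# ---------------------------------------------------------------------
# Random forest


def _fit_rf(t: DesignTable, settings: dict, seed: int) -> "FittedModel":
    y = t.response
    X = t.matrix()
    clf = RandomForestClassifier(
        n_estimators=settings["n_trees"],
        max_features=settings["max_features"],
        min_samples_leaf=settings["min_samples_leaf"],
        max_depth=settings["max_depth"],
        bootstrap=settings["bootstrap"],
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)

    def scorer(Xnew: np.ndarray) -> np.ndarray:
        return clf.predict_proba(Xnew)[:, 1]  # tree-vote fraction

    return FittedModel(
        spec=None,
        input_variables=list(t.variables),
        variables_used=list(t.variables),  # rf retains all variables
        scorer=scorer,
        train_auc=rank_auc(ScoredPoints(scorer(X), y)),
    )


# ---------------------------------------------------------------------
# Maxent-like weighted penalized logistic regression


def _fit_maxent_like(t: DesignTable, settings: dict, seed: int) -> "FittedModel":
    y = t.response
    X = t.matrix()
    std = _Standardizer(X)
    Xs = std(X)
    n_knots = settings["n_hinge_knots"]
    knots = [
        np.quantile(Xs[:, j], np.linspace(0.1, 0.9, n_knots))
        for j in range(X.shape[1])
    ]

    def features(Z: np.ndarray) -> np.ndarray:
        parts = [Z, Z**2]
        for j, ks in enumerate(knots):
            for knot in ks:
                parts.append(np.maximum(Z[:, j] - knot, 0.0)[:, None])
        return np.hstack(parts)

    F = features(Xs)
    weights = np.where(y == 1, 1.0, settings["background_weight"])
    clf = LogisticRegression(C=settings["c"], max_iter=5000, random_state=seed)
    clf.fit(F, y, sample_weight=weights)

    def scorer(Xnew: np.ndarray) -> np.ndarray:
        return clf.predict_proba(features(std(Xnew)))[:, 1]

    return FittedModel(
        spec=None,
        input_variables=list(t.variables),
        variables_used=list(t.variables),  # maxent retains all variables
        scorer=scorer,
        train_auc=rank_auc(ScoredPoints(scorer(X), y)),
    )


_FITTERS = {
    "glm_stepwise": _fit_glm_stepwise,
    "mars": _fit_mars,
    "brt": _fit_brt,
    "rf": _fit_rf,
    "maxent_like": _fit_maxent_like,
}


def fit_model(
    spec: ModelSpec, t: DesignTable, min_presences: int = 10
) -> FittedModel:
    """Fit one algorithm x background-method combination."""
    y = t.response
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise ClassError("design table must contain both classes")
    if n1 < min_presences:
        raise FitError(
            f"{n1} presences < configured floor of {min_presences}"
        )
    t = _canonical_rows(t)
    settings = spec.resolved_settings()
    try:
        model = _FITTERS[spec.algorithm](t, settings, spec.seed)
    except (ClassError, FitError):
        raise
    except Exception as exc:  # echo algorithm + settings per contract
        raise FitError(
            f"{spec.algorithm} failed with settings {settings}: {exc}"
        ) from exc
    model.spec = spec
    return model


def predict_raster(m: FittedModel, stack: RasterStack) -> RasterGrid:
    """Per-cell suitability; nodata wherever any input layer is nodata."""
    missing = [v for v in m.input_variables if v not in stack]
    if missing:
        raise KeyError(f"stack lacks layers required by the model: {missing}")
    template = stack.template
    valid = stack.valid_mask(m.input_variables)
    out = np.full(template.shape, np.nan)
    if valid.any():
        X = np.column_stack(
            [stack[v].values[valid] for v in m.input_variables]
        )
        out[valid] = m.predict(X)
    return template.like(out)


def apply_gates(
    m: FittedModel,
    overfit_gap: float = 0.05,
    min_cv_auc: float = 0.7,
    retuned: bool = False,
) -> FittedModel:
    """Apply the overfitting and quality gates once cv_auc is filled."""
    if m.cv_auc is None:
        raise GateOrderingError("cv_auc must be filled before applying gates")
    overfit = (m.train_auc - m.cv_auc) > overfit_gap
    reasons = []
    dropped = False
    if m.cv_auc < min_cv_auc:
        dropped = True
        reasons.append(f"cv_auc {m.cv_auc:.3f} < {min_cv_auc}")
    if overfit:
        reasons.append(
            f"train-cv AUC gap {m.train_auc - m.cv_auc:.3f} > {overfit_gap}"
        )
        if retuned:
            dropped = True
            reasons.append("still overfit after re-tuning pass")
    m.gates = {
        "overfit_flag": bool(overfit),
        "dropped": bool(dropped),
        "reason": "; ".join(reasons),
    }
    return m


def retune_spec(spec: ModelSpec) -> ModelSpec:
    """Stronger-regularization settings for the single automated retry."""
    settings = dict(spec.settings)
    settings.update(RETUNE_OVERRIDES[spec.algorithm])
    return replace(spec, settings=settings)


def fit_evaluate_gate(
    spec: ModelSpec,
    t: DesignTable,
    k: int = 10,
    cv_seed: int = 0,
    overfit_gap: float = 0.05,
    min_cv_auc: float = 0.7,
) -> FittedModel:
    """Fit, cross-validate, gate; one automated re-tuning pass on an
    overfit flag, then final gating."""
    from .evaluation import cross_validate

    model = fit_model(spec, t)
    model.cv_auc = cross_validate(spec, t, k=k, seed=cv_seed).cv_mean.auc_roc
    model = apply_gates(model, overfit_gap, min_cv_auc, retuned=False)
    if model.gates["overfit_flag"] and not model.gates["dropped"]:
        spec2 = retune_spec(spec)
        model2 = fit_model(spec2, t)
        model2.cv_auc = cross_validate(spec2, t, k=k, seed=cv_seed).cv_mean.auc_roc
        model2 = apply_gates(model2, overfit_gap, min_cv_auc, retuned=True)
        model2.gates["reason"] = (
            "re-tuned after overfit flag; " + model2.gates["reason"]
        ).strip("; ")
        return model2
    return model
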