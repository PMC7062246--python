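import numpy as np
import pandas as pd
import pytest

from habrisk import sdm_models as sdm
from habrisk.evaluation import ScoredPoints, rank_auc
from habrisk.predictors import DesignTable
from habrisk.raster import RasterGrid, RasterStack

FAST_SETTINGS = {
    "glm_stepwise": {"max_steps": 5},
    "mars": {},
    "brt": {"max_trees": 100},
    "rf": {"n_trees": 100},
    "maxent_like": {},
}


def make_table(X, y, variables=None):
    n, p = X.shape
    variables = variables or [f"x{i + 1}" for i in range(p)]
    frame = pd.DataFrame(
        {
            "point_id": np.arange(n),
            "x": np.arange(n, dtype=float),
            "y": np.zeros(n),
            "response": y.astype(int),
        }
    )
    for j, v in enumerate(variables):
        frame[v] = X[:, j]
    return DesignTable(frame, variables)


def noise_table(n=200, p=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    return make_table(X, y)


class TestModelSpec:
    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            sdm.ModelSpec("svm")

    def test_unknown_setting(self):
        with pytest.raises(ValueError):
            sdm.ModelSpec("rf", settings={"bogus": 1})

    def test_defaults_mirror_stated_values(self):
        assert sdm.DEFAULT_SETTINGS["brt"]["bag_fraction"] == 0.5
        assert sdm.DEFAULT_SETTINGS["mars"]["degree"] == 1
        assert sdm.DEFAULT_SETTINGS["mars"]["gcv_penalty"] == 2.0


@pytest.mark.parametrize("algorithm", sdm.ALGORITHMS)
class TestFitAllAlgorithms:
    def test_separable_toy_perfect_train_auc(self, algorithm,
                                             separable_design_table):
        spec = sdm.ModelSpec(algorithm, settings=FAST_SETTINGS[algorithm], seed=1)
        m = sdm.fit_model(spec, separable_design_table)
        assert m.train_auc == 1.0
        scores = m.score_table(separable_design_table)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_seeded_determinism(self, algorithm, separable_design_table):
        spec = sdm.ModelSpec(algorithm, settings=FAST_SETTINGS[algorithm], seed=5)
        m1 = sdm.fit_model(spec, separable_design_table)
        m2 = sdm.fit_model(spec, separable_design_table)
        assert m1.variables_used == m2.variables_used
        np.testing.assert_allclose(
            m1.score_table(separable_design_table),
            m2.score_table(separable_design_table),
            atol=1e-12,
        )

    def test_row_order_invariance(self, algorithm, separable_design_table):
        spec = sdm.ModelSpec(algorithm, settings=FAST_SETTINGS[algorithm], seed=5)
        t = separable_design_table
        rng = np.random.default_rng(2)
        t_perm = t.subset_rows(rng.permutation(len(t)))
        m1 = sdm.fit_model(spec, t)
        m2 = sdm.fit_model(spec, t_perm)
        np.testing.assert_allclose(
            m1.score_table(t), m2.score_table(t), atol=1e-12
        )

    def test_single_class_error(self, algorithm):
        t = noise_table()
        ones = t.subset_rows(np.flatnonzero(t.response == 1))
        spec = sdm.ModelSpec(algorithm, settings=FAST_SETTINGS[algorithm])
        with pytest.raises(sdm.ClassError):
            sdm.fit_model(spec, ones)

    def test_presence_floor(self, algorithm):
        t = noise_table(n=30)
        few = t.subset_rows(np.r_[np.flatnonzero(t.response == 1)[:3],
                                  np.flatnonzero(t.response == 0)])
        spec = sdm.ModelSpec(algorithm, settings=FAST_SETTINGS[algorithm])
        with pytest.raises(sdm.FitError):
            sdm.fit_model(spec, few)


class TestGlmStepwise:
    def test_noise_train_auc_band(self):
        spec = sdm.ModelSpec("glm_stepwise", settings={"max_steps": 5}, seed=1)
        m = sdm.fit_model(spec, noise_table(n=200, seed=31))
        assert 0.4 <= m.train_auc <= 0.75

    def test_recovers_driving_variable(self):
        rng = np.random.default_rng(32)
        n = 300
        x1 = rng.normal(size=n)
        noise = rng.normal(size=n)
        prob = 1 / (1 + np.exp(-(3 * x1)))
        y = (rng.random(n) < prob).astype(int)
        t = make_table(np.column_stack([x1, noise]), y, ["x1", "noise"])
        m = sdm.fit_model(sdm.ModelSpec("glm_stepwise", seed=2), t)
        assert "x1" in m.variables_used

    def test_main_only_retune_setting(self, separable_design_table):
        spec = sdm.ModelSpec("glm_stepwise", settings={"terms": "main_only"})
        m = sdm.fit_model(spec, separable_design_table)
        assert m.train_auc == 1.0


class TestMars:
    def test_prunes_pure_noise_variable(self):
        rng = np.random.default_rng(33)
        n = 400
        x1 = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = (x1 > 0.3).astype(int)
        t = make_table(np.column_stack([x1, noise]), y, ["x1", "noise"])
        m = sdm.fit_model(sdm.ModelSpec("mars", seed=1), t)
        assert m.variables_used == ["x1"]

    def test_scores_clamped(self, separable_design_table):
        m = sdm.fit_model(sdm.ModelSpec("mars", seed=1), separable_design_table)
        s = m.score_table(separable_design_table)
        assert s.min() >= 0.0 and s.max() <= 1.0


class TestPredictRaster:
    def _stack(self, a=1.0, b=2.0):
        g1 = RasterGrid(np.full((4, 4), a), cell_size=10.0)
        g2 = RasterGrid(np.full((4, 4), b), cell_size=10.0)
        return RasterStack({"x1": g1, "x2": g2})

    def test_constant_rasters_constant_output(self, separable_design_table):
        m = sdm.fit_model(sdm.ModelSpec("mars", seed=1), separable_design_table)
        stack = self._stack(a=0.9, b=0.0)
        out = sdm.predict_raster(m, stack)
        expected = m.predict(np.array([[0.9, 0.0]]))[0]
        np.testing.assert_allclose(out.values, expected)

    def test_nodata_propagates(self, separable_design_table):
        m = sdm.fit_model(sdm.ModelSpec("mars", seed=1), separable_design_table)
        stack = self._stack()
        vals = stack["x1"].values.copy()
        vals[2, 2] = np.nan
        stack = RasterStack({"x1": stack["x1"].like(vals), "x2": stack["x2"]})
        out = sdm.predict_raster(m, stack)
        assert np.isnan(out.values[2, 2])
        assert np.isfinite(out.values[0, 0])

    def test_missing_layer_schema_error(self, separable_design_table):
        m = sdm.fit_model(sdm.ModelSpec("mars", seed=1), separable_design_table)
        stack = RasterStack({"x1": RasterGrid(np.zeros((4, 4)), cell_size=10.0)})
        with pytest.raises(KeyError, match="x2"):
            sdm.predict_raster(m, stack)

    def test_raster_matches_pointwise_scorer(self, landscape, design_table):
        m = sdm.fit_model(
            sdm.ModelSpec("maxent_like", seed=4),
            design_table,
        )
        out = sdm.predict_raster(m, landscape)
        rng = np.random.default_rng(44)
        rows = rng.integers(0, landscape.template.nrows, 100)
        cols = rng.integers(0, landscape.template.ncols, 100)
        x, y = landscape.template.center_of_cell(rows, cols)
        X = landscape.sample(x, y, m.input_variables)
        np.testing.assert_allclose(
            out.values[rows, cols], m.predict(X), atol=1e-10
        )


class TestGates:
    def _model(self, train, cv):
        m = sdm.FittedModel(
            spec=sdm.ModelSpec("rf"),
            input_variables=["x1"],
            variables_used=["x1"],
            scorer=lambda X: np.full(len(X), 0.5),
            train_auc=train,
            cv_auc=cv,
        )
        return m

    def test_overfit_flag(self):
        m = sdm.apply_gates(self._model(0.99, 0.90))
        assert m.gates["overfit_flag"] is True
        assert m.gates["dropped"] is False  # first pass: re-tune, not drop

    def test_low_cv_dropped(self):
        m = sdm.apply_gates(self._model(0.68, 0.65))
        assert m.gates["dropped"] is True

    def test_both_gates_pass(self):
        m = sdm.apply_gates(self._model(0.95, 0.93))
        assert m.gates == {"overfit_flag": False, "dropped": False, "reason": ""}

    def test_still_overfit_after_retune_dropped(self):
        m = sdm.apply_gates(self._model(0.99, 0.90), retuned=True)
        assert m.gates["dropped"] is True

    def test_missing_cv_is_ordering_error(self):
        m = self._model(0.9, None)
        with pytest.raises(sdm.GateOrderingError):
            sdm.apply_gates(m)

    def test_retune_spec_strengthens_regularization(self):
        spec = sdm.ModelSpec("rf")
        spec2 = sdm.retune_spec(spec)
        assert spec2.settings["min_samples_leaf"] > 1
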