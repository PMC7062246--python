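import numpy as np
import pandas as pd
import pytest

from habrisk import thresholds_ensemble as te
from habrisk.evaluation import ScoredPoints
from habrisk.predictors import DesignTable
from habrisk.raster import RasterAlignmentError, RasterGrid, RasterStack


def scored(pres, back):
    scores = np.concatenate([pres, back])
    labels = np.r_[np.ones(len(pres), dtype=int), np.zeros(len(back), dtype=int)]
    return ScoredPoints(scores, labels)


class TestComputeThreshold:
    def test_mpp_is_minimum(self):
        r = te.compute_threshold("mpp", [0.2, 0.5, 0.9])
        assert r.value == pytest.approx(0.2)

    def test_pct10_excludes_exactly_one_of_ten(self):
        pres = np.arange(0.1, 1.05, 0.1)
        r = te.compute_threshold("pct10", pres)
        assert r.value == pytest.approx(0.2)
        assert int((pres < r.value).sum()) == 1

    def test_pct1_small_n_equals_mpp(self):
        pres = [0.3, 0.5, 0.8]  # floor(0.01*3) = 0 -> first order statistic
        assert te.compute_threshold("pct1", pres).value == pytest.approx(0.3)

    def test_mss_hand_example(self):
        p = scored([0.9, 0.8, 0.7], [0.2, 0.3, 0.6])
        r = te.compute_threshold("mss", [0.9, 0.8, 0.7], p)
        assert r.value == pytest.approx(0.7)

    def test_mss_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            pres = rng.random(20)
            back = rng.random(30)
            p = scored(pres, back)
            from fractions import Fraction

            best_v, best_t = Fraction(-1), None
            for t in np.unique(p.scores):
                v = Fraction(int((pres >= t).sum()), len(pres)) + Fraction(
                    int((back < t).sum()), len(back)
                )
                if v > best_v:
                    best_v, best_t = v, t
            assert te.compute_threshold("mss", pres, p).value == pytest.approx(
                best_t
            )

    def test_empty_presences_error(self):
        with pytest.raises(ValueError):
            te.compute_threshold("mpp", [])

    def test_ordering_property(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            pres = rng.random(rng.integers(1, 60))
            mpp = te.compute_threshold("mpp", pres).value
            p1 = te.compute_threshold("pct1", pres).value
            p10 = te.compute_threshold("pct10", pres).value
            assert mpp <= p1 <= p10


class TestBinarize:
    def test_ge_convention(self):
        g = RasterGrid(np.array([[0.4, 0.5, 0.6]]), cell_size=1.0)
        out = te.binarize_raster(g, te.ThresholdRule("mss", 0.5))
        np.testing.assert_array_equal(out.values, [[0.0, 1.0, 1.0]])

    def test_zero_threshold_all_suitable(self):
        g = RasterGrid(np.random.default_rng(1).random((3, 3)), cell_size=1.0)
        out = te.binarize_raster(g, te.ThresholdRule("mpp", 0.0))
        assert np.all(out.values == 1.0)

    def test_nodata_propagates(self):
        g = RasterGrid(np.array([[np.nan, 0.9]]), cell_size=1.0)
        out = te.binarize_raster(g, te.ThresholdRule("mss", 0.5))
        assert np.isnan(out.values[0, 0]) and out.values[0, 1] == 1.0

    def test_binary_area_monotone_over_rules(self):
        rng = np.random.default_rng(5)
        g = RasterGrid(rng.random((20, 20)), cell_size=1.0)
        pres = rng.random(40)
        areas = []
        for kind in ("mpp", "pct1", "pct10"):
            rule = te.compute_threshold(kind, pres)
            areas.append(np.nansum(te.binarize_raster(g, rule).values))
        assert areas[0] >= areas[1] >= areas[2]


class TestEnsemble:
    def _bin(self, arr):
        return RasterGrid(np.asarray(arr, dtype=float), cell_size=1.0)

    def test_hand_sum(self):
        layers = {
            "a": self._bin([[1, 0], [1, 1]]),
            "b": self._bin([[1, 1], [0, 1]]),
            "c": self._bin([[1, 0], [0, 0]]),
        }
        p = te.build_ensemble(layers, te.ThresholdRule("mpp", 0.1))
        np.testing.assert_array_equal(p.ensemble.values, [[3, 1], [1, 2]])
        assert p.retained_count == 3

    def test_counts_conserved(self):
        rng = np.random.default_rng(6)
        layers = {
            f"m{i}": self._bin((rng.random((5, 5)) > 0.5).astype(float))
            for i in range(4)
        }
        p = te.build_ensemble(layers, te.ThresholdRule("mpp", 0.1))
        total = sum(np.nansum(g.values) for g in layers.values())
        assert np.nansum(p.ensemble.values) == total
        assert p.ensemble.values.max() <= p.retained_count

    def test_misaligned_error(self):
        a = self._bin([[1, 0]])
        b = RasterGrid(np.array([[1.0, 0.0]]), x0=5.0, cell_size=1.0)
        with pytest.raises(RasterAlignmentError):
            te.build_ensemble({"a": a, "b": b}, te.ThresholdRule("mpp", 0.1))


def reference_table(values_by_var: dict) -> DesignTable:
    n = len(next(iter(values_by_var.values())))
    frame = pd.DataFrame(
        {
            "point_id": np.arange(n),
            "x": np.zeros(n),
            "y": np.zeros(n),
            "response": np.r_[1, np.zeros(n - 1, dtype=int)],
            **{k: np.asarray(v, dtype=float) for k, v in values_by_var.items()},
        }
    )
    return DesignTable(frame, list(values_by_var))


class TestMess:
    REF = [2.0, 4.0, 6.0, 8.0, 10.0]

    def _surface(self, cell_values, ref=None):
        ref = ref if ref is not None else self.REF
        grid = RasterGrid(np.asarray([cell_values], dtype=float), cell_size=1.0)
        stack = RasterStack({"v": grid})
        t = reference_table({"v": ref})
        return te.mess_surface(stack, t, ["v"])

    def test_interior_value(self):
        s = self._surface([6.0])
        assert s.mess.values[0, 0] == pytest.approx(80.0)

    def test_below_range(self):
        s = self._surface([1.0])
        assert s.mess.values[0, 0] == pytest.approx(-12.5)

    def test_above_range_and_min_rule(self):
        grid_v = RasterGrid(np.array([[12.0]]), cell_size=1.0)
        grid_w = RasterGrid(np.array([[6.0]]), cell_size=1.0)
        stack = RasterStack({"v": grid_v, "w": grid_w})
        t = reference_table({"v": self.REF, "w": self.REF})
        s = te.mess_surface(stack, t, ["v", "w"])
        assert s.per_variable_similarity["v"].values[0, 0] == pytest.approx(-25.0)
        assert s.mess.values[0, 0] == pytest.approx(-25.0)

    def test_at_most_100_and_100_iff_median(self):
        vals = np.linspace(0, 12, 49)
        s = self._surface(list(vals))
        sims = s.mess.values[0]
        assert np.all(sims <= 100.0 + 1e-9)
        # =100 only where exactly half the reference lies strictly below
        at100 = np.isclose(sims, 100.0)
        ref = np.asarray(self.REF)
        f = np.array([(ref < v).mean() * 100 for v in vals])
        np.testing.assert_array_equal(at100, f == 50.0)

    def test_negative_iff_out_of_range(self):
        vals = np.linspace(0, 12, 49)
        s = self._surface(list(vals))
        sims = s.mess.values[0]
        out = (vals < min(self.REF)) | (vals > max(self.REF))
        # strictly outside -> negative; inside -> nonnegative
        assert np.all(sims[out] < 0)
        assert np.all(sims[~out] >= 0)

    def test_degenerate_reference_excluded(self):
        grid_v = RasterGrid(np.array([[1.0]]), cell_size=1.0)
        grid_w = RasterGrid(np.array([[6.0]]), cell_size=1.0)
        stack = RasterStack({"v": grid_v, "w": grid_w})
        t = reference_table({"v": [3.0, 3.0, 3.0], "w": [2.0, 6.0, 10.0]})
        s = te.mess_surface(stack, t, ["v", "w"])
        assert s.excluded == ["v"]
        assert "v" not in s.per_variable_similarity


class TestPermutationImportance:
    def test_noise_variable_near_zero(self, design_table):
        from habrisk.sdm_models import ModelSpec, fit_model

        m = fit_model(ModelSpec("maxent_like", seed=9), design_table)
        rank = te.permutation_importance(m, design_table, n_permutations=5, seed=1)
        deltas = dict(rank.per_variable)
        for var in ("x3", "x4"):
            assert abs(deltas[var]) < 0.02

    def test_driver_ranked_first(self, design_table):
        from habrisk.sdm_models import ModelSpec, fit_model

        m = fit_model(ModelSpec("maxent_like", seed=9), design_table)
        rank = te.permutation_importance(m, design_table, n_permutations=5, seed=1)
        assert {rank.per_variable[0][0], rank.per_variable[1][0]} == {"x1", "x2"}

    def test_deterministic(self, design_table):
        from habrisk.sdm_models import ModelSpec, fit_model

        m = fit_model(ModelSpec("maxent_like", seed=9), design_table)
        r1 = te.permutation_importance(m, design_table, n_permutations=1, seed=7)
        r2 = te.permutation_importance(m, design_table, n_permutations=1, seed=7)
        assert r1.per_variable == r2.per_variable

    def test_frame_has_percent_contribution(self, design_table):
        from habrisk.sdm_models import ModelSpec, fit_model

        m = fit_model(ModelSpec("maxent_like", seed=9), design_table)
        df = te.permutation_importance(m, design_table, seed=1).as_frame()
        assert set(df.columns) >= {"variable", "delta_auc", "rank",
                                   "percent_contribution"}
        pos = df[df["delta_auc"] > 0]["percent_contribution"].sum()
        assert pos == pytest.approx(100.0)
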