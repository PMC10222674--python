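"""Permutation contributions, normalization and response-curve ranges."""

import numpy as np
import pandas as pd
import pytest

import invasdm as iv
from invasdm.ensemble import EnsembleModel
from invasdm.importance import (ResponseCurve, best_suitable_range,
                                key_variable_count, normalize_contributions,
                                response_curve, variable_contributions)


class _LinearRun:
    """Stub member whose prediction uses only declared columns."""

    def __init__(self, used_cols, variables):
        self.used = used_cols
        self.variables = list(variables)
        self.status = "ok"
        self.run_id = "lin"
        self.algorithm = "GLM"
        self.pa_set = 0
        self.repetition = 0
        self.evaluation = iv.EvaluationResult(0.95, 0.9, 0.5, 0.95, 0.95, 9, 9)

    def predict(self, X):
        z = sum(np.asarray(X[c], dtype=float) for c in self.used)
        from scipy.special import expit

        return expit(z)


class TestContributions:
    def test_unused_variable_has_zero_importance(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        em = EnsembleModel(members=[_LinearRun(["a"], list("abc"))],
                           weights=np.array([1.0]), gate=0.9)
        imp = variable_contributions(em, X, n_permutations=2, seed=1)
        assert imp["b"] == 0.0 and imp["c"] == 0.0
        assert imp["a"] > 0.2

    def test_duplicated_column_unused_by_members_scores_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        X["a_copy"] = X["a"]
        em = EnsembleModel(members=[_LinearRun(["a"], ["a", "b", "a_copy"])],
                           weights=np.array([1.0]), gate=0.9)
        imp = variable_contributions(em, X, n_permutations=2, seed=2)
        assert imp["a_copy"] == 0.0

    def test_constant_predictions_yield_zero_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])

        class _Const(_LinearRun):
            def predict(self, X):
                return np.full(len(X), 0.4)

        em = EnsembleModel(members=[_Const([], ["a", "b"])],
                           weights=np.array([1.0]), gate=0.9)
        with pytest.warns(UserWarning, match="constant"):
            imp = variable_contributions(em, X, n_permutations=1, seed=3)
        assert (imp == 0).all()

    def test_dominant_simulated_variable_ranks_first(self, fitted_small):
        land = fitted_small["landscape"]
        df = land.table(fitted_small["variables"])[fitted_small["variables"]]
        imp = variable_contributions(fitted_small["ensemble"], df,
                                     n_permutations=2, seed=4)
        assert imp.idxmax() == "env01"  # the narrow-optimum niche axis


class TestNormalization:
    def test_percent_arithmetic_and_cumulative(self):
        table = normalize_contributions(pd.Series({"a": 2.0, "b": 1.0, "c": 1.0}))
        df = table.table
        np.testing.assert_allclose(df["contribution_pct"], [50, 25, 25])
        np.testing.assert_allclose(df["cumulative_pct"], [50, 75, 100])

    def test_single_variable_is_total(self):
        df = normalize_contributions(pd.Series({"only": 0.42})).table
        assert df["contribution_pct"].iloc[0] == pytest.approx(100.0)

    def test_scale_invariance(self, rng):
        raw = pd.Series(rng.uniform(0.1, 1, 6), index=list("abcdef"))
        t1 = normalize_contributions(raw).table
        t2 = normalize_contributions(raw * 37.5).table
        np.testing.assert_allclose(t1["contribution_pct"], t2["contribution_pct"])

    def test_sum_is_hundred(self, rng):
        raw = pd.Series(rng.uniform(0, 1, 20))
        total = normalize_contributions(raw).table["contribution_pct"].sum()
        assert total == pytest.approx(100.0, abs=0.05)

    def test_key_variable_count_at_90(self):
        table = normalize_contributions(
            pd.Series({"a": 50.0, "b": 30.0, "c": 15.0, "d": 5.0}))
        # cumulative 50, 80, 95, 100 -> three variables reach 90%
        assert key_variable_count(table, 90.0) == 3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_contributions(pd.Series({"a": 0.0, "b": 0.0}))


class TestResponseCurves:
    def test_argmax_near_simulated_optimum(self, fitted_small):
        curve = response_curve(fitted_small["ensemble"],
                               fitted_small["landscape"], "env01",
                               n_grid=60, seed=1)
        step = curve.grid[1] - curve.grid[0]
        vhat = curve.grid[np.argmax(curve.mean_hsi)]
        assert abs(vhat - 10.0) <= 2 * step  # optimum of the generating niche

    def test_monotone_truth_gives_monotone_curve(self, landscape64):
        # midpoint at the centre of env02's generated range so the truth
        # actually varies over the landscape
        niche = iv.TrueNiche({"env02": iv.LogisticResponse(20.0, 1.0)})
        vs = iv.make_species(landscape64, niche, n_presence=300, seed=31)
        occ = iv.thin_occurrences(vs.to_frame(), landscape64)
        runs = iv.run_ensemble_protocol(
            landscape64, occ, landscape64.layer_names,
            iv.ProtocolConfig(algorithms=("GLM",), n_repetitions=1,
                              n_pa_sets=1, n_pseudo_absences=400), seed=32)
        em = EnsembleModel.from_runs(runs, gate=0.0)
        curve = response_curve(em, landscape64, "env02", n_grid=50, seed=2)
        inversions = (np.diff(curve.mean_hsi) < -1e-6).sum()
        assert inversions <= 1  # one inversion per 50 grid points allowed

    def test_two_point_grid_returns_endpoints(self, fitted_small):
        curve = response_curve(fitted_small["ensemble"],
                               fitted_small["landscape"], "env01",
                               n_grid=2, seed=3)
        df = fitted_small["landscape"].table(["env01"])
        assert curve.grid[0] == pytest.approx(df["env01"].min())
        assert curve.grid[-1] == pytest.approx(df["env01"].max())

    def test_unknown_variable_rejected(self, fitted_small):
        with pytest.raises(ValueError):
            response_curve(fitted_small["ensemble"],
                           fitted_small["landscape"], "nope", seed=1)


class TestBestRange:
    def _curve(self, y, lo=0.0, hi=10.0):
        grid = np.linspace(lo, hi, len(y))
        return ResponseCurve(variable="v", grid=grid,
                             mean_hsi=np.asarray(y, dtype=float),
                             n_cells=100)

    def test_symmetric_unimodal_range_is_symmetric(self):
        grid = np.linspace(0, 10, 101)
        y = np.exp(-((grid - 5.0) ** 2) / 2.0)
        lo, hi, meta = best_suitable_range(self._curve(y))
        # half-max of a unit Gaussian: 5 +/- sqrt(2 ln 2)
        hw = np.sqrt(2 * np.log(2))
        step = grid[1] - grid[0]
        assert lo == pytest.approx(5 - hw, abs=step)
        assert hi == pytest.approx(5 + hw, abs=step)
        assert not meta["multimodal"]

    def test_flat_curve_returns_full_range(self):
        lo, hi, _ = best_suitable_range(self._curve(np.ones(20), 2.0, 8.0))
        assert (lo, hi) == (2.0, 8.0)

    def test_constructed_half_max_interval_recovered(self):
        # response >= half-max exactly on [4, 6]
        grid = np.linspace(0, 10, 201)
        y = np.where((grid >= 4) & (grid <= 6), 1.0, 0.2)
        lo, hi, _ = best_suitable_range(ResponseCurve("v", grid, y, 100))
        step = grid[1] - grid[0]
        assert abs(lo - 4.0) <= step and abs(hi - 6.0) <= step

    def test_multimodal_flagged_and_widest_block_with_max(self):
        grid = np.linspace(0, 10, 101)
        y = np.exp(-((grid - 2.0) ** 2) / 0.5) * 0.8 \
            + np.exp(-((grid - 7.0) ** 2) / 0.5)
        lo, hi, meta = best_suitable_range(ResponseCurve("v", grid, y, 100))
        assert meta["multimodal"]
        assert lo <= 7.0 <= hi and hi < 9.0 and lo > 5.0

    def test_absolute_criterion_differs_from_half_max(self):
        grid = np.linspace(0, 10, 101)
        y = 0.4 * np.exp(-((grid - 5.0) ** 2) / 2.0)  # peak below 0.5
        lo_h, hi_h, _ = best_suitable_range(ResponseCurve("v", grid, y, 100))
        lo_a, hi_a, meta = best_suitable_range(
            ResponseCurve("v", grid, y, 100), criterion="absolute")
        assert np.isfinite(lo_h) and np.isfinite(hi_h)
        assert meta["empty"] and np.isnan(lo_a)
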