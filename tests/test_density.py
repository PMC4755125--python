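"""Zonal summaries, the bagged density forest, OOB diagnostics, importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor

from popgrid import (
    CensusUnit,
    DensityForest,
    GridRaster,
    HarmonizedCensus,
    ZoneRaster,
    fit_forest,
    oob_error,
    predict_density_surface,
    zonal_summarize,
)
from popgrid.covariates import CovariateStack
from popgrid.density import DensityModelError, covariate_columns


def _stack_and_zones(values_by_layer, zone_values, ps=100.0):
    values_by_layer = {n: np.asarray(v, dtype=float)
                       for n, v in values_by_layer.items()}
    shape = next(iter(values_by_layer.values())).shape
    template = GridRaster(np.zeros(shape), 0, shape[0] * ps, ps)
    layers = {n: template.like(np.asarray(v, dtype=float))
              for n, v in values_by_layer.items()}
    zones = ZoneRaster(np.asarray(zone_values, dtype=np.int32), 0,
                       shape[0] * ps, ps)
    return CovariateStack(year="y", layers=layers), zones


class TestZonalSummarize:
    def test_mean_and_log_density(self):
        stack, zones = _stack_and_zones(
            {"cov": [[1.0, 3.0], [5.0, 7.0]]}, [[1, 1], [2, 2]]
        )
        census = HarmonizedCensus({1: 1000.0, 2: 20.0})
        table = zonal_summarize(stack, zones, census)
        row1 = table[table.zone_id == 1].iloc[0]
        assert row1["cov"] == pytest.approx(2.0)
        assert row1["pixel_count"] == 2
        # ln(1000 / 2) = ln 500
        assert row1["log_density"] == pytest.approx(np.log(500.0))

    def test_ln10_example(self):
        vals = np.ones((10, 10))
        stack, zones = _stack_and_zones({"cov": vals}, np.ones((10, 10), dtype=int))
        table = zonal_summarize(stack, zones, HarmonizedCensus({1: 1000.0}))
        assert table.iloc[0]["log_density"] == pytest.approx(np.log(10.0), abs=1e-6)

    def test_matches_per_pixel_groupby_oracle(self):
        rng = np.random.default_rng(12)
        zone_vals = rng.integers(1, 8, (20, 20))
        covs = {f"c{i}": rng.normal(size=(20, 20)) for i in range(3)}
        stack, zones = _stack_and_zones(covs, zone_vals)
        census = HarmonizedCensus({z: float(100 + z) for z in range(1, 8)})
        table = zonal_summarize(stack, zones, census).set_index("zone_id")

        df = pd.DataFrame({n: stack.layers[n].values.ravel() for n in covs})
        df["zone"] = zone_vals.ravel()
        oracle = df.groupby("zone").mean()
        for z in oracle.index:
            for n in covs:
                assert table.loc[z, n] == pytest.approx(oracle.loc[z, n], rel=1e-12)

    def test_nodata_pixels_excluded_and_zero_count_zones_dropped(self):
        cov = np.array([[1.0, -9999.0], [3.0, 5.0]])
        stack, zones = _stack_and_zones({"cov": cov}, [[1, 1], [2, 2]])
        census = HarmonizedCensus({1: 10.0, 2: 0.0})
        table = zonal_summarize(stack, zones, census)
        assert table.zone_id.tolist() == [1]
        assert table.iloc[0]["pixel_count"] == 1  # the nodata pixel is unusable

    def test_missing_census_id_raises(self):
        stack, zones = _stack_and_zones({"cov": [[1.0, 2.0]]}, [[1, 2]])
        with pytest.raises(DensityModelError):
            zonal_summarize(stack, zones, HarmonizedCensus({1: 5.0}))


def _toy_table(n=200, seed=0, n_noise=0):
    rng = np.random.default_rng(seed)
    cov1 = rng.uniform(-2, 2, n)
    data = {"cov1": cov1}
    for i in range(n_noise):
        data[f"noise{i}"] = rng.normal(size=n)
    X = pd.DataFrame(data)
    y = 2.0 * cov1
    return X, y


class TestDensityForest:
    def test_default_hyperparameters_match_convention(self):
        model = DensityForest()
        assert model.n_estimators == 500
        assert model.min_samples_leaf == 1
        assert model.max_features is None  # all covariates at every split

    def test_noise_free_signal_recovered(self):
        X, y = _toy_table(n=200, seed=1)
        model = DensityForest(n_estimators=200, random_state=0).fit(X, y)
        assert model.oob_variance_explained_ >= 0.90

    def test_seeded_fits_are_identical(self):
        X, y = _toy_table(n=60, seed=2, n_noise=2)
        a = DensityForest(n_estimators=50, random_state=42).fit(X, y)
        b = DensityForest(n_estimators=50, random_state=42).fit(X, y)
        np.testing.assert_array_equal(a.oob_prediction_, b.oob_prediction_)

    def test_too_few_rows_rejected(self):
        X, y = _toy_table(n=10)
        with pytest.raises(DensityModelError):
            DensityForest(n_estimators=10, random_state=0).fit(X, y)

    def test_constant_response_flagged_not_crashed(self):
        X, _ = _toy_table(n=30, seed=3)
        model = DensityForest(n_estimators=20, random_state=0).fit(X, np.full(30, 2.0))
        assert np.isnan(model.oob_variance_explained_)

    def test_sklearn_estimator_protocol(self):
        model = DensityForest(n_estimators=25, random_state=1)
        params = model.get_params()
        assert params["n_estimators"] == 25
        cloned = clone(model)
        assert cloned.get_params() == params
        X, y = _toy_table(n=40, seed=4)
        cloned.set_params(n_estimators=30).fit(X, y)
        assert len(cloned.estimators_) == 30

    def test_agrees_with_sklearn_random_forest_oracle(self):
        """Independent cross-check: same recipe via sklearn's own forest."""
        X, y = _toy_table(n=150, seed=5, n_noise=2)
        ours = DensityForest(n_estimators=300, random_state=0).fit(X, y)
        ref = RandomForestRegressor(
            n_estimators=300, min_samples_leaf=1, max_features=1.0,
            bootstrap=True, oob_score=True, random_state=0,
        ).fit(X, y)
        grid = pd.DataFrame({
            "cov1": np.linspace(-2, 2, 50), "noise0": 0.0, "noise1": 0.0})
        ours_pred = ours.predict(grid)
        ref_pred = ref.predict(grid)
        assert np.corrcoef(ours_pred, ref_pred)[0, 1] > 0.99
        assert ours.oob_variance_explained_ == pytest.approx(ref.oob_score_, abs=0.05)


class TestOOBError:
    def test_perfect_prediction(self):
        model = DensityForest()
        model.oob_mse_ = 0.0
        model.oob_variance_explained_ = 1.0
        model.estimators_ = [None]
        assert oob_error(model) == (0.0, 1.0)

    def test_hand_arithmetic_residuals(self):
        # oob_pred [1, 1] on y = [0, 2]: mse 1, var(y) = 1 -> var explained 0
        y = np.array([0.0, 2.0])
        pred = np.array([1.0, 1.0])
        mse = float(np.mean((pred - y) ** 2))
        var_expl = 1.0 - mse / float(np.var(y))
        assert mse == pytest.approx(1.0)
        assert var_expl == pytest.approx(0.0)

    def test_fit_forest_wrapper_reads_covariates_from_table(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({
            "zone_id": np.arange(40), "pixel_count": 10, "area_ha": 10.0,
            "covA": rng.normal(size=40), "count": 100.0,
        })
        table["log_density"] = 1.5 * table["covA"]
        model = fit_forest(table, seed=0, n_estimators=50)
        assert list(model.feature_names_in_) == ["covA"]
        mse, ve = oob_error(model, table)
        assert mse >= 0 and ve <= 1


class TestPermutationImportance:
    def test_identity_permutation_is_exactly_zero(self):
        X, y = _toy_table(n=40, seed=7, n_noise=1)
        model = DensityForest(n_estimators=30, random_state=0).fit(X, y)
        imp = model.permutation_importance(n_repeats=2, random_state=0, _identity=True)
        assert all(v == 0.0 for v in imp.values())

    def test_independent_covariate_near_zero_signal_largest(self):
        rng = np.random.default_rng(8)
        n = 150
        X = pd.DataFrame({
            "signal": rng.uniform(-2, 2, n),
            "noise0": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        y = 2.0 * X["signal"].to_numpy() + rng.normal(0, 0.1, n)
        model = DensityForest(n_estimators=200, random_state=0).fit(X, y)
        imp = model.permutation_importance(n_repeats=10, random_state=0)
        assert max(imp, key=imp.get) == "signal"
        for k in ("noise0", "noise1", "noise2"):
            assert abs(imp[k]) < 5.0

    def test_deterministic_given_seed(self):
        X, y = _toy_table(n=40, seed=9, n_noise=1)
        model = DensityForest(n_estimators=30, random_state=0).fit(X, y)
        a = model.permutation_importance(n_repeats=3, random_state=5)
        b = model.permutation_importance(n_repeats=3, random_state=5)
        assert a == b


class TestPredictSurface:
    def _fitted_model(self, names, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({n: rng.normal(size=50) for n in names})
        y = X[names[0]].to_numpy() * 2.0
        return DensityForest(n_estimators=30, random_state=0).fit(X, y)

    def test_constant_covariates_give_constant_surface(self):
        model = self._fitted_model(["a", "b"])
        stack, _ = _stack_and_zones(
            {"a": np.full((4, 4), 0.5), "b": np.full((4, 4), -0.2)},
            np.ones((4, 4), dtype=int),
        )
        surf = predict_density_surface(model, stack)
        assert np.allclose(surf.values, surf.values[0, 0])
        assert (surf.values > 0).all()

    def test_nodata_pixel_masked(self):
        model = self._fitted_model(["a", "b"])
        a = np.full((3, 3), 0.5)
        a[1, 1] = -9999.0
        stack, _ = _stack_and_zones({"a": a, "b": np.zeros((3, 3))},
                                    np.ones((3, 3), dtype=int))
        surf = predict_density_surface(model, stack)
        assert surf.values[1, 1] == surf.nodata
        assert (surf.values[surf.data_mask] > 0).all()

    def test_layer_name_mismatch_rejected(self):
        model = self._fitted_model(["a", "b"])
        stack, _ = _stack_and_zones({"a": np.zeros((2, 2)), "c": np.zeros((2, 2))},
                                    np.ones((2, 2), dtype=int))
        with pytest.raises(DensityModelError):
            predict_density_surface(model, stack)

    def test_monotone_decreasing_density_with_built_distance(self, small_world):
        """Fig.-3-style check: mean predicted weight falls with edge distance."""
        from scipy.stats import spearmanr

        from popgrid.pipeline import run_year

        res = run_year(small_world, 0, seed=0, n_estimators=150)
        d = res.stack.layers["built_dist_1990"].values
        w = res.weights
        mask = w.data_mask
        bins = np.quantile(d[mask], np.linspace(0, 1, 11))
        idx = np.clip(np.digitize(d[mask], bins[1:-1]), 0, 9)
        mean_w = [w.values[mask][idx == b].mean() for b in range(10)]
        rho = spearmanr(np.arange(10), mean_w).statistic
        assert rho <= -0.9
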