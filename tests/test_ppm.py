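import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppmsdm import ppm
from ppmsdm.grid import GeoGrid
from ppmsdm.synthetic import SyntheticScenario, realize


@pytest.fixture()
def calib(rng):
    return pd.DataFrame({"a": rng.uniform(2, 8, 100), "b": rng.normal(size=100)})


class TestFeatures:
    def test_linear_features_hit_bounds(self, calib):
        spec = ppm.FeatureSpec.from_calibration(calib, classes=("linear",))
        feats, _ = ppm.build_features(calib, spec)
        assert feats.shape == (100, 2)
        assert feats.min() == pytest.approx(0.0)
        assert feats.max() == pytest.approx(1.0)

    def test_feature_count_by_class(self, calib):
        for classes, k in ((("linear",), 2), (("linear", "quadratic"), 4),
                           (("quadratic",), 2)):
            spec = ppm.FeatureSpec.from_calibration(calib, classes=classes)
            feats, _ = ppm.build_features(calib, spec)
            assert feats.shape[1] == k

    def test_projection_data_clamped(self, calib):
        spec = ppm.FeatureSpec.from_calibration(calib)
        beyond = pd.DataFrame({"a": [100.0], "b": [0.0]})
        feats, n_clamped = ppm.build_features(beyond, spec)
        assert n_clamped > 0
        assert feats.max() <= 1.0 and feats.min() >= 0.0

    def test_constant_predictor_rejected_by_name(self):
        df = pd.DataFrame({"fine": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            ppm.FeatureSpec.from_calibration(df)

    def test_regularization_schedule_interpolates(self):
        assert ppm.default_regularization("linear", 10) == 1.0
        assert ppm.default_regularization("linear", 100) == 0.05
        assert ppm.default_regularization("linear", 1000) == 0.05
        assert ppm.default_regularization("quadratic", 17) == 0.8
        mid = ppm.default_regularization("linear", 65)
        assert 0.05 < mid < 0.2


def _toy_problem(rng, n_pres=60, n_bg=300, seed_sep=0.8):
    x = rng.normal(size=(n_bg, 2))
    bg = pd.DataFrame(x, columns=["a", "b"])
    eta = seed_sep * x[:, 0] - 0.3 * x[:, 0] ** 2
    p = np.exp(eta)
    p /= p.sum()
    pres = bg.iloc[rng.choice(n_bg, size=n_pres, p=p)].reset_index(drop=True)
    spec = ppm.FeatureSpec.from_calibration(
        pd.concat([pres, bg], ignore_index=True))
    pres_f, _ = ppm.build_features(pres, spec)
    bg_f, _ = ppm.build_features(bg, spec)
    return pres, bg, spec, pres_f, bg_f


class TestFit:
    def test_huge_penalty_drives_coefficients_to_zero(self, rng):
        _, _, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1e6)
        np.testing.assert_array_equal(model.coefficients, 0.0)
        raw = np.exp(bg_f @ model.coefficients - model.log_z)
        np.testing.assert_allclose(raw, 1.0 / len(bg_f), rtol=1e-12)

    def test_duplicated_presences_leave_fit_unchanged(self, rng):
        # with the penalty sample size held fixed, replicating every row
        # leaves the objective — hence the optimum — identical
        pres, bg, spec, pres_f, bg_f = _toy_problem(rng)
        n = pres_f.shape[0]
        m1 = ppm.fit(pres_f, bg_f, spec, rm=1.0, tol=1e-9, max_iter=20000)
        m2 = ppm.fit(np.vstack([pres_f, pres_f]), bg_f, spec, rm=1.0,
                     tol=1e-9, max_iter=20000, penalty_n=n)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-4)

    def test_fitted_objective_beats_null(self, rng):
        _, _, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0)
        lam = ppm.penalty_vector(spec, pres_f, 1.0)
        null = ppm._ipp_objective(np.zeros(pres_f.shape[1]), pres_f, bg_f, lam)
        assert model.objective <= null + 1e-10

    def test_predictor_rescaling_leaves_predictions_unchanged(self, rng):
        pres, bg, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0, tol=1e-9, max_iter=20000)
        scaled_pres = pres.copy()
        scaled_bg = bg.copy()
        scaled_pres["a"] *= 37.0
        scaled_bg["a"] *= 37.0
        spec2 = ppm.FeatureSpec.from_calibration(
            pd.concat([scaled_pres, scaled_bg], ignore_index=True))
        pres_f2, _ = ppm.build_features(scaled_pres, spec2)
        bg_f2, _ = ppm.build_features(scaled_bg, spec2)
        model2 = ppm.fit(pres_f2, bg_f2, spec2, rm=1.0, tol=1e-9, max_iter=20000)
        np.testing.assert_allclose(model.predict(pres, output="cloglog"),
                                   model2.predict(scaled_pres, output="cloglog"),
                                   atol=1e-5)

    def test_zero_model_cloglog_is_uniform_limit(self, rng):
        _, bg, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1e6)
        scores = model.predict(bg, output="cloglog")
        np.testing.assert_allclose(scores, 1.0 - np.exp(-1.0), atol=1e-12)

    def test_cloglog_increases_with_eta(self, rng):
        _, bg, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0)
        eta = model.eta(bg)
        cll = model.predict(bg, output="cloglog")
        order = np.argsort(eta)
        assert (np.diff(cll[order]) >= 0).all()

    def test_raw_sums_to_one_over_calibration_background(self, rng):
        _, bg, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0)
        assert model.predict(bg, output="raw").sum() == pytest.approx(1.0, abs=1e-9)

    def test_iwlr_route_converges_to_ipp_with_weight(self, rng):
        _, _, spec, pres_f, bg_f = _toy_problem(rng, n_pres=20, n_bg=200,
                                                seed_sep=0.4)
        b_ipp = ppm.fit(pres_f, bg_f, spec, rm=1.0, tol=1e-12,
                        max_iter=100000).coefficients
        err = [np.max(np.abs(b_ipp - ppm.fit_iwlr(pres_f, bg_f, spec, rm=1.0,
                                                  bg_weight=w)))
               for w in (100.0, 1e4)]
        assert err[1] < err[0]          # the claimed infinite-weight limit
        assert err[1] < 1e-3

    def test_serialization_roundtrip(self, rng, tmp_path):
        pres, bg, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.5)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ppm.PPMModel.from_json(path)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        np.testing.assert_allclose(back.predict(bg), model.predict(bg))


class TestAicc:
    def test_closed_form(self):
        # K=2, n=100, logL=-50 -> 104 + 12/97
        k, n, log_l = 2, 100, -50.0
        expected = 2 * k - 2 * log_l + 2 * k * (k + 1) / (n - k - 1)
        assert expected == pytest.approx(104.0 + 12.0 / 97.0)
        spec = ppm.FeatureSpec(predictors=["a"], classes=("linear",),
                               bounds={"a": {"lin_min": 0.0, "lin_max": 1.0,
                                             "sq_min": 0.0, "sq_max": 1.0}})
        grid = pd.DataFrame({"a": np.linspace(0, 1, 50)})
        pres = pd.DataFrame({"a": np.full(100, 0.8)})
        model = ppm.PPMModel(coefficients=np.array([1.0]), spec=spec, rm=1.0,
                             log_z=0.0, entropy_h=0.0, n_presences=100,
                             n_background=50, converged=True, n_iter=1,
                             objective=0.0)
        a = ppm.aicc(model, pres, grid)
        eta_g = np.linspace(0, 1, 50)
        log_l_direct = (0.8 - np.log(np.exp(eta_g).sum())) * 100
        assert a == pytest.approx(2 * 1 - 2 * log_l_direct + 4 / 98)

    def test_zero_coefficient_does_not_count_toward_k(self, rng):
        _, bg, spec, pres_f, bg_f = _toy_problem(rng)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0)
        pres_df, bg_df = _toy_problem(rng)[:2]
        a1 = ppm.aicc(model, pres_df, bg_df)
        padded = ppm.PPMModel(
            coefficients=model.coefficients.copy(), spec=model.spec,
            rm=model.rm, log_z=model.log_z, entropy_h=model.entropy_h,
            n_presences=model.n_presences, n_background=model.n_background,
            converged=True, n_iter=1, objective=0.0)
        padded.coefficients[np.abs(padded.coefficients) < 1e-15] = 0.0
        assert ppm.aicc(padded, pres_df, bg_df) == pytest.approx(a1)

    def test_too_many_parameters_flagged_invalid(self):
        spec = ppm.FeatureSpec(predictors=["a"], classes=("linear",),
                               bounds={"a": {"lin_min": 0.0, "lin_max": 1.0,
                                             "sq_min": 0.0, "sq_max": 1.0}})
        model = ppm.PPMModel(coefficients=np.array([1.0]), spec=spec, rm=1.0,
                             log_z=0.0, entropy_h=0.0, n_presences=2,
                             n_background=5, converged=True, n_iter=1,
                             objective=0.0)
        pres = pd.DataFrame({"a": [0.1, 0.9]})
        grid = pd.DataFrame({"a": np.linspace(0, 1, 5)})
        assert np.isnan(ppm.aicc(model, pres, grid))


class TestCheckerboard:
    def test_nested_colorings_produce_four_labels(self):
        # 4x4 grid, fine blocks of 1 cell, coarse blocks of 2: every
        # (fine, coarse) color combination occurs
        g = GeoGrid(np.zeros((4, 4)), 0, 4, 1.0)
        lon, lat = np.meshgrid(np.arange(4) + 0.5, np.arange(4) + 0.5)
        folds = ppm.checkerboard_partition(lon.ravel(), lat.ravel(), g,
                                           agg1=1, agg2=2)
        assert sorted(np.unique(folds)) == [1, 2, 3, 4]
        assert np.bincount(folds)[1:].tolist() == [4, 4, 4, 4]

    def test_clustered_points_warn_about_empty_folds(self):
        g = GeoGrid(np.zeros((8, 8)), 0, 8, 1.0)
        with pytest.warns(UserWarning, match="folds"):
            ppm.checkerboard_partition([0.1] * 5, [7.9] * 5, g, agg1=4, agg2=2)

    def test_uniform_points_fill_folds_evenly(self, rng):
        g = GeoGrid(np.zeros((100, 100)), 0, 100, 1.0)
        lon = rng.uniform(0, 100, 20000)
        lat = rng.uniform(0, 100, 20000)
        folds = ppm.checkerboard_partition(lon, lat, g, agg1=5, agg2=2)
        counts = np.bincount(folds)[1:]
        assert counts.min() > 0.9 * 5000 and counts.max() < 1.1 * 5000


@pytest.fixture(scope="module")
def tuned():
    scenario = SyntheticScenario(n_rows=40, n_cols=40, n_layers=2,
                                 beta_linear=(1.0, 0.4),
                                 beta_quadratic=(-0.6, 0.0),
                                 n_presences=150, seed=21)
    study = realize(scenario)
    from ppmsdm import predictors as pred
    bg = ppm.sample_background(study.stack, n=1200, seed=3)[study.stack.names]
    pres = pred.extract(study.stack, study.occurrences).matrix
    folds = ppm.checkerboard_partition(study.occurrences.lon,
                                       study.occurrences.lat,
                                       study.stack.grid, 5, 2)
    _, _, grid_matrix = study.stack.cell_table()
    grid_values = pd.DataFrame(grid_matrix, columns=study.stack.names)
    return ppm.tune(pres, bg, grid_values, folds)


class TestTune:
    def test_default_grids_give_18_candidates(self, tuned):
        assert len(tuned.table) == 18
        assert set(tuned.table["classes"]) == {"L", "LQ"}

    def test_delta_aicc_minimum_is_zero(self, tuned):
        assert tuned.table["delta_aicc"].min() == 0.0
        assert (tuned.table["delta_aicc"].dropna() >= 0).all()
        assert (tuned.table["delta_aicc"] == 0).sum() >= 1

    def test_selected_model_reproduces_its_own_aicc(self, tuned):
        scenario = SyntheticScenario(n_rows=40, n_cols=40, n_layers=2,
                                     beta_linear=(1.0, 0.4),
                                     beta_quadratic=(-0.6, 0.0),
                                     n_presences=150, seed=21)
        study = realize(scenario)
        from ppmsdm import predictors as pred
        pres = pred.extract(study.stack, study.occurrences).matrix
        _, _, grid_matrix = study.stack.cell_table()
        grid_values = pd.DataFrame(grid_matrix, columns=study.stack.names)
        again = ppm.aicc(tuned.best, pres, grid_values)
        assert again == pytest.approx(
            tuned.table.loc[tuned.best_index, "aicc"], rel=1e-12)


class TestRecovery:
    def test_single_seed_parameter_recovery(self):
        scenario = SyntheticScenario(n_rows=60, n_cols=60, n_layers=2,
                                     beta_linear=(1.0, 0.6),
                                     beta_quadratic=(-0.8, 0.0),
                                     n_presences=1000, seed=5)
        study = realize(scenario)
        from ppmsdm import predictors as pred
        bg = ppm.sample_background(study.stack, n=3600, seed=1)[study.stack.names]
        pres = pred.extract(study.stack, study.occurrences).matrix
        spec = ppm.FeatureSpec.from_calibration(
            pd.concat([pres, bg], ignore_index=True))
        pres_f, _ = ppm.build_features(pres, spec)
        bg_f, _ = ppm.build_features(bg, spec)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0)
        predicted = model.predict_grid(study.stack, output="raw")
        shared = predicted.mask & study.true_raw.mask
        rho = stats.spearmanr(predicted.values[shared],
                              study.true_raw.values[shared]).statistic
        assert rho >= 0.9


class TestImportance:
    def test_permutation_importance_finds_the_active_predictor(self, rng):
        pres, bg, spec, pres_f, bg_f = _toy_problem(rng, n_pres=150, n_bg=600)
        model = ppm.fit(pres_f, bg_f, spec, rm=1.0)
        imp = ppm.permutation_importance(model, pres, bg, n_repeats=3, seed=0)
        assert imp.sum() == pytest.approx(100.0)
        assert imp["a"] > imp["b"]

    def test_jackknife_gain_orders_predictors(self, rng):
        pres, bg, *_ = _toy_problem(rng, n_pres=150, n_bg=600)
        table = ppm.jackknife_gain(pres, bg)
        only = table.set_index("predictor")["gain_only"]
        assert only["a"] > only["b"]
        assert (table["gain_full"] >= -1e-9).all()
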