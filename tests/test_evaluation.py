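"""Index regressions, hyperparameter search, realizations, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from leafchl.assembly import PairedDataset
from leafchl.chlorophyll import CHL_METRICS
from leafchl.errors import ParameterError
from leafchl.evaluation import (
    ESTIMATOR_IDS,
    SearchSpec,
    anova_tukey,
    eval_index_linear,
    fit_with_search,
    make_estimator,
    rmse_pct,
    run_realizations,
)


class TestEvalIndexLinear:
    def test_exact_linear_relation_gives_perfect_fit(self):
        x = np.linspace(0, 5, 40)
        out = eval_index_linear(x, 2 * x + 1)
        assert out["r2"] == pytest.approx(1.0)
        assert out["rmse_pct"] == pytest.approx(0.0, abs=1e-10)
        assert out["slope"] == pytest.approx(2.0)

    def test_four_point_set_matches_normal_equations_oracle(self, benchmarks):
        pts = benchmarks["ols_points"]  # {(1,2),(2,3),(3,5),(4,6)}
        x, y = pts[:, 0], pts[:, 1]
        # normal equations oracle
        A = np.vstack([x, np.ones_like(x)]).T
        slope_o, icept_o = np.linalg.solve(A.T @ A, A.T @ y)
        out = eval_index_linear(x, y)
        assert out["slope"] == pytest.approx(slope_o)
        assert out["intercept"] == pytest.approx(icept_o)
        pred = slope_o * x + icept_o
        assert out["rmse_pct"] == pytest.approx(
            100 * np.sqrt(np.mean((y - pred) ** 2)) / y.mean())

    def test_orthogonal_index_has_near_zero_r2(self):
        rng = np.random.default_rng(8)
        out = eval_index_linear(rng.normal(size=2000), rng.normal(10, 1, 2000))
        assert abs(out["r2"]) < 0.01

    def test_nan_index_values_excluded_pairwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = 3 * x + 2
        out = eval_index_linear(x, y)
        assert out["n"] == 4 and out["r2"] == pytest.approx(1.0)

    def test_zero_variance_index_is_flagged(self):
        out = eval_index_linear(np.ones(10), np.arange(10.0))
        assert out["flagged"] and np.isnan(out["r2"])


class TestRmsePct:
    def test_invariant_to_common_positive_scaling(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(5, 10, 50)
        p = y + rng.normal(0, 0.5, 50)
        assert rmse_pct(y, p) == pytest.approx(rmse_pct(7.3 * y, 7.3 * p))

    def test_perfect_prediction_is_zero(self):
        y = np.arange(1.0, 9.0)
        assert rmse_pct(y, y) == 0.0


class TestFitWithSearch:
    def make_linear(self, n=80, p=5, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = X @ np.arange(1.0, p + 1) + noise * rng.normal(size=n)
        return X, y

    def test_single_candidate_grid_returns_that_candidate(self):
        X, y = self.make_linear()
        _, chosen = fit_with_search(SearchSpec("Ridge", grid={"alpha": [0.5]}), X, y)
        assert chosen == {"alpha": 0.5}

    def test_ridge_choice_matches_exhaustive_refit_oracle(self):
        X, y = self.make_linear(noise=0.1, seed=3)
        grid = np.logspace(-4, 2, 7)
        spec = SearchSpec("Ridge", grid={"alpha": grid.tolist()}, cv_repeats=2)
        _, chosen = fit_with_search(spec, X, y)
        # oracle: exhaustive refit over the same folds
        from sklearn.model_selection import RepeatedKFold, cross_val_score
        scores = []
        for a in grid:
            cv = RepeatedKFold(n_splits=5, n_repeats=2, random_state=spec.seed)
            s = cross_val_score(make_estimator("Ridge").set_params(alpha=a), X, y,
                                scoring="neg_root_mean_squared_error", cv=cv)
            scores.append(s.mean())
        oracle_alpha = grid[int(np.argmax(scores))]
        # within one grid step of the oracle optimum
        assert abs(np.log10(chosen["alpha"]) - np.log10(oracle_alpha)) <= 1.0

    def test_same_seed_reproduces_hyperparameters(self):
        X, y = self.make_linear(noise=0.5, seed=5)
        spec = SearchSpec("DecisionTreeRegressor",
                          grid={"max_depth": [2, 4, 8]}, cv_repeats=2, seed=4)
        _, a = fit_with_search(spec, X, y)
        _, b = fit_with_search(spec, X, y)
        assert a == b

    def test_no_grid_estimators_fit_directly(self):
        X, y = self.make_linear()
        model, chosen = fit_with_search(SearchSpec("BayesianRidge"), X, y)
        assert chosen == {}
        assert np.corrcoef(model.predict(X), y)[0, 1] > 0.99

    def test_empty_grid_list_rejected(self):
        X, y = self.make_linear()
        with pytest.raises(ParameterError):
            fit_with_search(SearchSpec("Ridge", grid={"alpha": []}), X, y)

    def test_pls_with_full_components_reproduces_ols(self):
        X, y = self.make_linear(n=40, p=4, noise=0.3, seed=9)
        pls, _ = fit_with_search(
            SearchSpec("PLSRegression", grid={"n_components": [4]}, cv_repeats=1), X, y)
        ols = LinearRegression().fit(X, y)
        np.testing.assert_allclose(np.ravel(pls.predict(X)), ols.predict(X), atol=1e-8)


def tiny_dataset(n, seed, experiment="exp1"):
    rng = np.random.default_rng(seed)
    bands = [f"R{w}" for w in range(350, 2501, 50)]  # 44-band reduced grid
    chl = rng.uniform(20, 60, n)
    feats = np.outer(chl, np.linspace(0.001, 0.01, len(bands)))
    feats += rng.normal(0, 0.01, feats.shape) + 0.1
    targets = {m: chl * (1 + 0.1 * i) for i, m in enumerate(CHL_METRICS)}
    return PairedDataset(
        scale="plot",
        ids=pd.DataFrame({"row_id": [f"{experiment}-{seed}-{i}" for i in range(n)],
                          "experiment_id": experiment}),
        features=pd.DataFrame(feats, columns=bands),
        targets=pd.DataFrame(targets),
    )


class TestRunRealizations:
    def test_row_count_is_metrics_x_sets_x_estimators_x_phases(self):
        train, test = tiny_dataset(60, 1), tiny_dataset(30, 2)
        res = run_realizations(
            train, test,
            estimators=("Ridge", "KNeighborsRegressor", "PLSRegression"),
            spectral_sets=("reflectance", "d1"),
            chl_metrics=("chl_ab_area", "chl_ab_mass"),
            grids={"Ridge": {"alpha": [1.0]},
                   "KNeighborsRegressor": {"n_neighbors": [5]},
                   "PLSRegression": {"n_components": [3]}},
            cv_repeats=1,
        )
        assert len(res) == 2 * 2 * 3 * 2
        assert set(res["phase"]) == {"train", "test"}
        assert (res["rmse_pct"] >= 0).all()
        assert (res["r2"] <= 1).all()

    def test_member_failure_is_flagged_and_run_continues(self, monkeypatch):
        train, test = tiny_dataset(40, 3), tiny_dataset(20, 4)
        res = run_realizations(
            train, test, estimators=("Ridge", "PLSRegression"),
            spectral_sets=("reflectance",), chl_metrics=("chl_ab_area",),
            grids={"Ridge": {"alpha": [1.0]},
                   "PLSRegression": {"n_components": [-1]}},  # invalid -> failure
            cv_repeats=1,
        )
        flagged = res[res["flagged"]]
        assert set(flagged["estimator"]) == {"PLSRegression"}
        assert not res[res["estimator"] == "Ridge"]["flagged"].any()

    def test_train_error_does_not_exceed_test_error_on_average(self):
        diffs = []
        for seed in range(20):
            train, test = tiny_dataset(50, 100 + seed), tiny_dataset(25, 200 + seed)
            res = run_realizations(
                train, test, estimators=("Ridge",), spectral_sets=("reflectance",),
                chl_metrics=("chl_ab_area",), grids={"Ridge": {"alpha": [0.01]}},
                cv_repeats=1,
            )
            tr = res.loc[res.phase == "train", "rmse_pct"].iloc[0]
            te = res.loc[res.phase == "test", "rmse_pct"].iloc[0]
            diffs.append(te - tr)
        assert np.mean(diffs) >= 0


class TestAnovaTukey:
    def results_frame(self, rmse_by_cell):
        rows = []
        for (est, sset, met), values in rmse_by_cell.items():
            for v in values:
                rows.append({"estimator": est, "spectral_set": sset,
                             "chl_metric": met, "phase": "test", "rmse_pct": v})
        return pd.DataFrame(rows)

    def test_all_equal_errors_give_zero_f_and_one_letter(self):
        cells = {(e, s, m): [10.0, 10.0]
                 for e in ("A", "B") for s in ("r", "d1") for m in ("x", "y")}
        out = anova_tukey(self.results_frame(cells))
        assert (out["anova"]["F"] == 0).all()
        for table in out["tukey"].values():
            assert set(table["letters"]) == {"a"}

    def test_two_level_f_matches_hand_anova_on_six_numbers(self):
        # factor A: level a -> {1, 2, 3}; level b -> {5, 6, 7}
        df = pd.DataFrame({
            "estimator": ["a"] * 3 + ["b"] * 3,
            "spectral_set": "s", "chl_metric": "m",
            "rmse_pct": [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],
        })
        out = anova_tukey(df, factors=("estimator",))
        # hand ANOVA: SSB = 24, SSW = 4, F = 24 / (4/4) = 24
        assert out["anova"]["F"].iloc[0] == pytest.approx(24.0)

    def test_clearly_separated_levels_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "estimator": np.repeat(["a", "b"], 10),
            "spectral_set": "s", "chl_metric": "m",
            "rmse_pct": np.concatenate([rng.normal(5, 0.1, 10),
                                        rng.normal(50, 0.1, 10)]),
        })
        out = anova_tukey(df, factors=("estimator",))
        letters = dict(zip(out["tukey"]["estimator"]["level"],
                           out["tukey"]["estimator"]["letters"]))
        assert letters["a"] != letters["b"]

    def test_unreplicated_factor_raises_naming_it(self):
        df = pd.DataFrame({
            "estimator": ["a", "b"], "spectral_set": "s", "chl_metric": "m",
            "rmse_pct": [1.0, 2.0],
        })
        with pytest.raises(ParameterError, match="estimator"):
            anova_tukey(df, factors=("estimator",))


def test_zoo_covers_the_fourteen_reported_algorithms():
    assert len(ESTIMATOR_IDS) == 14
    for est in ESTIMATOR_IDS:
        make_estimator(est, random_state=0)  # instantiable with static settings
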