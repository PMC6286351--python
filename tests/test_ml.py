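import numpy as np
import pandas as pd
import pytest

from turnoverlab.ml import (
    BaggedForest,
    ModelSpec,
    TurnoverEnsemble,
    TurnoverEnsembleResults,
    TurnoverModel,
    TurnoverModelResults,
    _Member,
    permutation_importance,
    train_cv,
)
from turnoverlab.synthetic import PlantedTurnoverModel, generate_planted_regression


def planted(seed=0, r2=0.76, **kw):
    return generate_planted_regression(
        300, PlantedTurnoverModel(target_r2=r2, seed=seed, **kw)
    )


class TestTrainCv:
    def test_five_by_five_gives_25_scores(self):
        d = planted()
        _, cv = train_cv(d.features_complete, d.y, ModelSpec("elastic_net", seed=0))
        assert len(cv.r2) == 25 and len(cv.rmse) == 25
        assert cv.folds == 5 and cv.repeats == 5

    def test_neural_net_defaults_to_one_repeat(self):
        spec = ModelSpec("neural_net", seed=0)
        assert spec.repeats == 1

    @pytest.mark.parametrize("folds,repeats", [(3, 2), (4, 1)])
    def test_score_count_is_folds_times_repeats(self, folds, repeats):
        d = planted()
        spec = ModelSpec("elastic_net", folds=folds, repeats=repeats, seed=0,
                         grid=[{"alpha": 0.01, "l1_ratio": 0.5}])
        _, cv = train_cv(d.features_complete, d.y, spec)
        assert len(cv.r2) == folds * repeats

    def test_noiseless_linear_signal_recovered(self):
        d = generate_planted_regression(
            200, PlantedTurnoverModel(noise_sigma=0.0, seed=1)
        )
        _, cv = train_cv(
            d.features_complete,
            d.y,
            ModelSpec("elastic_net", seed=1,
                      grid=[{"alpha": 1e-4, "l1_ratio": 0.5}]),
        )
        assert cv.median_r2 >= 0.99

    def test_reproducible_given_seed(self):
        d = planted()
        spec = ModelSpec("elastic_net", seed=3)
        res_a, cv_a = train_cv(d.features_complete, d.y, spec)
        res_b, cv_b = train_cv(d.features_complete, d.y, spec)
        np.testing.assert_array_equal(cv_a.r2, cv_b.r2)
        np.testing.assert_array_equal(
            res_a.predict(d.features_complete), res_b.predict(d.features_complete)
        )

    def test_hyperparameters_minimize_cv_rmse(self):
        d = planted()
        grid = [{"alpha": 0.01, "l1_ratio": 0.5}, {"alpha": 100.0, "l1_ratio": 0.5}]
        res, cv = train_cv(d.features_complete, d.y,
                           ModelSpec("elastic_net", grid=grid, seed=0))
        assert cv.best_params["alpha"] == 0.01  # alpha=100 shrinks all away

    def test_too_few_rows_error(self):
        d = planted()
        few = d.features_complete.head(6)
        with pytest.raises(ValueError, match="too few"):
            TurnoverModel(few, d.y.loc[few.index], ModelSpec("elastic_net"))

    def test_constant_response_error(self):
        d = planted()
        with pytest.raises(ValueError, match="constant"):
            TurnoverModel(
                d.features_complete,
                pd.Series(1.0, index=d.features_complete.index),
                ModelSpec("elastic_net"),
            )

    def test_null_response_has_no_skill(self):
        """Leakage guard: on permuted responses the cross-validated R2 must
        stay at chance level."""
        d = planted(seed=5)
        rng = np.random.default_rng(5)
        y_null = pd.Series(
            rng.permutation(d.y.to_numpy()), index=d.y.index
        )
        _, cv = train_cv(
            d.features_complete, y_null,
            ModelSpec("elastic_net", seed=5,
                      grid=[{"alpha": 0.01, "l1_ratio": 0.5}]),
        )
        assert cv.median_r2 <= 0.05

    def test_test_split_reported_not_selected_on(self):
        d = planted()
        res = TurnoverModel(
            d.features_complete, d.y,
            ModelSpec("elastic_net", seed=0,
                      grid=[{"alpha": 0.01, "l1_ratio": 0.5}]),
            test_fraction=0.2,
        ).fit()
        assert res.cv.test_r2 is not None
        assert res.cv.test_r2 > 0.4  # real signal generalizes

    def test_summary_mentions_protocol(self):
        d = planted()
        res, _ = train_cv(d.features_complete, d.y,
                          ModelSpec("elastic_net", seed=0,
                                    grid=[{"alpha": 0.01, "l1_ratio": 0.5}]))
        text = res.summary()
        assert "5 x 5-fold" in text and "25 validations" in text


class TestPermutationImportance:
    def test_constant_feature_importance_not_positive(self, rng):
        X = rng.normal(size=(60, 4))
        X[:, 2] = 1.0
        y = X[:, 0] + rng.normal(0, 0.3, 60)
        f = BaggedForest(n_trees=50, seed=0).fit(X, y)
        imp = permutation_importance(f, X, y, n_response_permutations=19, seed=0)
        assert imp.importance.iloc[2] <= 0

    def test_planted_signal_ranks_first_with_small_p(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 10))
            y = 1.5 * X[:, 0] + rng.normal(0, 0.5, 100)
            f = BaggedForest(n_trees=60, seed=seed).fit(X, y)
            imp = permutation_importance(
                f, X, y, n_response_permutations=49, seed=seed
            )
            first = imp.importance.idxmax() == "x0"
            significant = imp.p_value.loc["x0"] < 0.05
            hits += first and significant
        assert hits >= 8

    def test_p_values_in_unit_interval(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        f = BaggedForest(n_trees=40, seed=1).fit(X, y)
        imp = permutation_importance(f, X, y, n_response_permutations=19, seed=1)
        assert ((imp.p_value > 0) & (imp.p_value <= 1)).all()
        assert list(imp.index) == [f"x{j}" for j in range(5)]

    def test_dataframe_feature_names_used(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["u", "v", "w"])
        y = X["u"] + rng.normal(0, 0.1, 50)
        f = BaggedForest(n_trees=30, seed=2).fit(X.to_numpy(), y)
        imp = permutation_importance(f, X, y, n_response_permutations=9, seed=2)
        assert list(imp.index) == ["u", "v", "w"]


def cheap_specs(seed=0):
    return {
        "elastic_net": ModelSpec("elastic_net", seed=seed,
                                 grid=[{"alpha": 0.01, "l1_ratio": 0.5}]),
        "random_forest": ModelSpec("random_forest", seed=seed, repeats=1,
                                   grid=[{"n_estimators": 40}]),
        "neural_net": ModelSpec("neural_net", seed=seed,
                                grid=[{"hidden_layer_sizes": (8,), "alpha": 1e-3}]),
    }


@pytest.fixture(scope="module")
def fitted_ensemble():
    d = planted(seed=0, missing_fractions={"km": 0.3, "active_site_depth": 0.2})
    labelled = d.features.index[:150]
    res = TurnoverEnsemble(
        d.features, d.y.loc[labelled], cheap_specs(), seed=0
    ).fit()
    return d, res


class TestEnsemble:
    def test_three_algorithms_times_four_strategies(self, fitted_ensemble):
        _, res = fitted_ensemble
        assert len(res.members) == 12
        combos = {(m.algorithm, m.strategy) for m in res.members}
        assert len(combos) == 12

    def test_fully_observed_strategies_coincide(self):
        d = planted(seed=2)  # no missingness
        y = d.y.loc[d.features.index[:150]]
        res = TurnoverEnsemble(d.features, y, cheap_specs(2), seed=2).fit()
        preds = {}
        for m in res.members:
            if m.algorithm == "elastic_net":
                preds[m.strategy] = m.results.predict(d.features)
        base = preds.pop("none")
        for strategy, p in preds.items():
            np.testing.assert_allclose(p, base, atol=1e-10, err_msg=strategy)

    def test_prediction_is_mean_of_members_in_s_units(self, fitted_ensemble):
        _, res = fitted_ensemble
        log_pred = res.predict_log10()
        pred = res.predict()
        np.testing.assert_allclose(pred.to_numpy(), 10.0 ** log_pred.to_numpy())

    def test_ensemble_mean_within_member_range(self, fitted_ensemble):
        _, res = fitted_ensemble
        member_preds = []
        for m in res.members:
            table = res._predict_tables[m.strategy]
            complete = table.notna().all(axis=1)
            vals = pd.Series(m.fallback_median, index=table.index, dtype=float)
            vals.loc[complete] = m.results.predict(table.loc[complete])
            member_preds.append(vals)
        stack = pd.concat(member_preds, axis=1)
        mean = res.predict_log10()
        assert (mean <= stack.max(axis=1) + 1e-9).all()
        assert (mean >= stack.min(axis=1) - 1e-9).all()

    def test_incomplete_rows_fall_back_to_member_median(self):
        members = [
            _Member("elastic_net", "none", _ConstantResults(2.0), 0.5),
            _Member("random_forest", "none", _ConstantResults(4.0), 1.5),
        ]
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]}, index=["r1", "r2"])
        res = TurnoverEnsembleResults(members, 0.0, X, {"none": X})
        log_pred = res.predict_log10()
        # complete row: mean(2, 4) = 3; incomplete row: mean(0.5, 1.5) = 1
        assert log_pred["r1"] == pytest.approx(3.0)
        assert log_pred["r2"] == pytest.approx(1.0)
        assert res.predict()["r2"] == pytest.approx(10.0)

    def test_identical_members_exponentiate_back(self):
        members = [
            _Member("elastic_net", s, _ConstantResults(1.5), 1.5)
            for s in ("none", "labelled_only")
        ]
        X = pd.DataFrame({"a": [1.0]}, index=["r1"])
        res = TurnoverEnsembleResults(members, 1.5, X, {s: X for s in
                                                        ("none", "labelled_only")})
        assert res.predict()["r1"] == pytest.approx(10.0 ** 1.5)

    def test_reproducible_given_seed(self):
        d = planted(seed=4, missing_fractions={"km": 0.3})
        y = d.y.loc[d.features.index[:150]]
        a = TurnoverEnsemble(d.features, y, cheap_specs(4), seed=4).fit().predict()
        b = TurnoverEnsemble(d.features, y, cheap_specs(4), seed=4).fit().predict()
        pd.testing.assert_series_equal(a, b)

    def test_summary_names_members(self, fitted_ensemble):
        _, res = fitted_ensemble
        text = res.summary()
        assert "12 members" in text


class _ConstantResults:
    """Stand-in member model returning a fixed log10 prediction."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)
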