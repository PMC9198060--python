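"""The pairwise sigmoid-basis regression: design, fitting, decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import bgestimate as bg
from bgestimate.model_core import (
    CONST_TERM, PairwiseModel, SelectionResult, decompose, expand_design,
    fit_ridge, predict, rank_importance, select_hyperparameters,
    train_pairwise_model, visualize_pairwise,
)


def _hand_model():
    """A 2-term model small enough to verify by hand arithmetic."""
    return PairwiseModel(
        target_name="ph_t",
        key_name="ph_prev",
        nonkey_names=(CONST_TERM, "a"),
        basis=bg.SigmoidBasis((7.3,), 10.0),
        weights=np.array([[2.0], [3.0]]),
        intercept=0.5,
        standardization={"a": (1.0, 2.0)},
        key_mean=7.35,
        nonkey_means={"a": 1.5},
    )


class TestSigmoidBasis:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bg.SigmoidBasis((7.4, 7.3), 10.0)     # not increasing
        with pytest.raises(ValueError):
            bg.SigmoidBasis((7.3,), 0.0)          # slope must be positive
        with pytest.raises(ValueError):
            bg.SigmoidBasis((), 10.0)             # at least one center

    def test_values_bounded_and_monotone(self):
        basis = bg.SigmoidBasis((7.2, 7.4), 12.0)
        z = np.linspace(6.8, 7.8, 101)
        f = basis.evaluate(z)
        assert np.all((f > 0) & (f < 1))
        assert np.all(np.diff(f, axis=0) > 0)

    def test_centers_from_quantiles_are_increasing(self, derivation_rows):
        centers = bg.make_centers(derivation_rows["ph_prev"].to_numpy(), 7)
        assert len(centers) == 7
        assert np.all(np.diff(centers) > 0)


class TestExpandDesign:
    def test_hand_computed_values(self):
        rows = pd.DataFrame({"ph_prev": [7.25, 7.35, 7.45], "a": [1.0, -2.0, 0.5]})
        basis = bg.SigmoidBasis((7.3, 7.4), 8.0)
        X = expand_design(rows, basis, (CONST_TERM, "a"))
        for r, z in enumerate(rows["ph_prev"]):
            for j, c in enumerate(basis.centers):
                f = 1.0 / (1.0 + np.exp(-8.0 * (z - c)))
                assert X[r, j] == pytest.approx(f * 1.0, abs=1e-12)
                assert X[r, 2 + j] == pytest.approx(f * rows["a"][r], abs=1e-12)

    def test_saturated_sigmoid_recovers_plain_design(self):
        rows = pd.DataFrame({"ph_prev": [7.3, 7.4, 7.5], "a": [1.0, 2.0, 3.0]})
        basis = bg.SigmoidBasis((6.0,), 500.0)  # center far below all z
        X = expand_design(rows, basis, (CONST_TERM, "a"))
        assert np.allclose(X, np.column_stack([np.ones(3), rows["a"]]), atol=1e-12)

    def test_zero_predictor_gives_zero_columns(self):
        rows = pd.DataFrame({"ph_prev": [7.3, 7.4], "a": [0.0, 0.0]})
        X = expand_design(rows, bg.SigmoidBasis((7.35,), 10.0), (CONST_TERM, "a"))
        assert np.all(X[:, 1] == 0)

    def test_non_finite_rejected(self):
        rows = pd.DataFrame({"ph_prev": [7.3, np.nan], "a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="non-finite"):
            expand_design(rows, bg.SigmoidBasis((7.35,), 10.0), (CONST_TERM, "a"))


class TestFitRidge:
    def test_zero_penalty_interpolates_square_system(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 6)) + np.eye(6)
        y = rng.normal(size=6)
        w = fit_ridge(X, y, 0.0)
        assert np.allclose(X @ w, y, atol=1e-8)

    def test_huge_penalty_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        w = fit_ridge(X, y, 1e12)
        assert np.abs(w).max() < 1e-6

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        w = fit_ridge(X, y, 1.0)
        oracle = np.linalg.inv(X.T @ X + np.eye(6)) @ X.T @ y
        assert np.abs(w - oracle).max() < 1e-8

    def test_singular_zero_penalty_raises(self):
        X = np.ones((5, 3))  # rank 1
        with pytest.raises(ValueError, match="penalty > 0"):
            fit_ridge(X, np.ones(5), 0.0)

    def test_agrees_with_sklearn_ridge(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        w = fit_ridge(X, y, 2.5)
        ref = sklearn.Ridge(alpha=2.5, fit_intercept=False, solver="cholesky").fit(X, y)
        assert np.abs(w - ref.coef_).max() < 1e-8

    def test_unpenalized_intercept_absorbs_offset(self):
        rng = np.random.default_rng(4)
        cols = rng.normal(size=(50, 2))
        cols -= cols.mean(axis=0)  # zero-mean regressors isolate the offset
        X = np.column_stack([np.ones(50), cols])
        y = 100.0 + X[:, 1] + rng.normal(0, 0.01, 50)
        w = fit_ridge(X, y, 1e6, penalize=np.array([False, True, True]))
        assert w[0] == pytest.approx(y.mean(), abs=1e-6)
        assert np.abs(w[1:]).max() < 1e-3


class TestPredictDecompose:
    def test_hand_model_prediction_and_decomposition(self):
        model = _hand_model()
        row = pd.DataFrame({"ph_prev": [7.3], "a": [2.0]})
        # f(7.3) = 0.5; standardized a = (2-1)/2 = 0.5
        # prediction = 0.5 + 0.5*2*1 + 0.5*3*0.5 = 2.25
        assert predict(model, row)[0] == pytest.approx(2.25, abs=1e-12)
        contrib = decompose(model, row)
        assert contrib[CONST_TERM].iloc[0] == pytest.approx(1.5, abs=1e-12)
        assert contrib["a"].iloc[0] == pytest.approx(0.75, abs=1e-12)

    def test_zero_weights_predict_intercept(self, derivation_rows):
        model = _hand_model()
        model.weights = np.zeros((2, 1))
        row = pd.DataFrame({"ph_prev": [7.5], "a": [3.0]})
        assert predict(model, row)[0] == pytest.approx(0.5)
        assert decompose(model, row)["a"].iloc[0] == 0.0

    def test_contributions_sum_to_prediction(self, ph_model, validation_rows):
        total = decompose(ph_model, validation_rows).sum(axis=1).to_numpy()
        assert np.abs(total - predict(ph_model, validation_rows)).max() < 1e-10

    def test_predictor_at_center_contributes_zero(self, ph_model, validation_rows):
        row = validation_rows.iloc[[0]].copy()
        center, _ = ph_model.standardization["etco2_t"]
        row["etco2_t"] = center
        assert decompose(ph_model, row)["etco2_t"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_predictor_named_in_error(self, ph_model, validation_rows):
        with pytest.raises(ValueError, match="d_spo2"):
            predict(ph_model, validation_rows.drop(columns=["d_spo2"]))


class TestImportance:
    def test_all_predictors_at_population_mean_give_zero(self, ph_model):
        row = {name: mean for name, mean in ph_model.nonkey_means.items()}
        row[ph_model.key_name] = 7.32
        ranking = rank_importance(ph_model, pd.Series(row))
        for item in ranking:
            assert item.importance == pytest.approx(0.0, abs=1e-12)

    def test_single_perturbation_moves_only_that_predictor(self, ph_model):
        row = {name: mean for name, mean in ph_model.nonkey_means.items()}
        row[ph_model.key_name] = 7.32
        row["etco2_t"] += 10.0
        ranking = rank_importance(ph_model, pd.Series(row))
        assert ranking.items[0].name == "etco2_t"
        assert abs(ranking.items[0].importance) > 0
        for item in ranking.items[1:]:
            assert item.importance == pytest.approx(0.0, abs=1e-12)

    def test_hand_model_importance_value(self):
        model = _hand_model()
        row = pd.Series({"ph_prev": 7.3, "a": 2.0})
        ranking = rank_importance(model, row)
        # I_a = f(7.3)*w*( (2-1)/2 - (1.5-1)/2 ) = 0.5*3*0.25 = 0.375
        item = ranking.items[0]
        assert item.name == "a"
        assert item.importance == pytest.approx(0.375, abs=1e-12)
        assert item.value == 2.0 and item.population_mean == 1.5

    def test_sorted_by_magnitude_with_stable_ties(self):
        model = PairwiseModel(
            target_name="ph_t", key_name="ph_prev",
            nonkey_names=(CONST_TERM, "a", "b"),
            basis=bg.SigmoidBasis((7.3,), 10.0),
            weights=np.array([[0.0], [1.0], [-1.0]]),
            intercept=0.0,
            standardization={"a": (0.0, 1.0), "b": (0.0, 1.0)},
            key_mean=7.3, nonkey_means={"a": 0.0, "b": 0.0},
        )
        row = pd.Series({"ph_prev": 7.3, "a": 2.0, "b": 2.0})
        ranking = rank_importance(model, row)
        assert [i.name for i in ranking] == ["a", "b"]  # equal |I|: predictor order
        assert ranking.items[0].importance == pytest.approx(1.0)
        assert ranking.items[1].importance == pytest.approx(-1.0)


class TestVisualizePairwise:
    def test_zero_weight_model_is_flat(self):
        model = _hand_model()
        model.weights = np.zeros((2, 1))
        surface = visualize_pairwise(model, "a", [7.2, 7.4], [0.0, 1.0, 2.0])
        assert np.all(surface == 0)

    def test_surface_matches_decompose(self, ph_model):
        zs, xs = [7.25, 7.40], [30.0, 50.0]
        surface = visualize_pairwise(ph_model, "etco2_t", zs, xs)
        for a, z in enumerate(zs):
            for b, x in enumerate(xs):
                row = {name: mean for name, mean in ph_model.nonkey_means.items()}
                row[ph_model.key_name] = z
                row["etco2_t"] = x
                contrib = decompose(ph_model, pd.DataFrame([row]))["etco2_t"].iloc[0]
                assert surface[a, b] == pytest.approx(contrib, abs=1e-12)

    def test_linear_in_x_with_analytic_slope(self, ph_model):
        xs = np.array([20.0, 30.0, 40.0, 50.0])
        surface = visualize_pairwise(ph_model, "etco2_t", [7.35], xs)[0]
        i = ph_model.nonkey_names.index("etco2_t")
        f = ph_model.basis.evaluate(np.array([7.35]))[0]
        _, scale = ph_model.standardization["etco2_t"]
        analytic = float(f @ ph_model.weights[i]) / scale
        finite = np.diff(surface) / np.diff(xs)
        assert np.allclose(finite, analytic, atol=1e-10)

    def test_unknown_predictor_rejected(self, ph_model):
        with pytest.raises(ValueError, match="unknown"):
            visualize_pairwise(ph_model, "lactate", [7.3], [0.0])


class TestSelectHyperparameters:
    def test_single_point_grid_returned(self, derivation_rows, split_plan):
        sel = select_hyperparameters(
            derivation_rows, split_plan, lambda_grid=(1.0,),
            basis_grid=({"m": 3, "slope": 10.0},))
        assert sel.penalty == 1.0
        assert sel.basis.m == 3

    def test_empty_grid_rejected(self, derivation_rows, split_plan):
        with pytest.raises(ValueError, match="non-empty"):
            select_hyperparameters(derivation_rows, split_plan, lambda_grid=())

    def test_noise_basis_loses_to_sane_basis(self, derivation_rows, split_plan):
        # centers far above any previous pH -> f ~= 0 -> the whole design
        # collapses toward zero and only the intercept remains
        sel = select_hyperparameters(
            derivation_rows, split_plan, lambda_grid=(1.0,),
            basis_grid=({"centers": (9.0,), "slope": 50.0},
                        {"m": 5, "slope": 10.0}))
        assert sel.basis.m == 5

    def test_identical_grid_points_keep_first(self, derivation_rows, split_plan):
        sel = select_hyperparameters(
            derivation_rows, split_plan, lambda_grid=(1.0, 1.0),
            basis_grid=({"m": 3, "slope": 10.0},))
        assert len(sel.scores) == 2
        assert sel.scores["score"].iloc[0] == sel.scores["score"].iloc[1]
        assert isinstance(sel, SelectionResult)


class TestParameterRecovery:
    def _simulate(self, n, seed, noise_sd=0.05):
        rng = np.random.default_rng(seed)
        names = (CONST_TERM, "a", "b", "c", "d")
        rows = pd.DataFrame({
            "ph_prev": rng.uniform(7.0, 7.6, n),
            **{k: rng.normal(size=n) for k in names[1:]},
        })
        basis = bg.SigmoidBasis((7.15, 7.30, 7.45), 20.0)
        true_w = np.random.default_rng(7).normal(size=(5, 3))
        X = expand_design(rows, basis, names)
        y = X @ true_w.reshape(-1) + rng.normal(0, noise_sd, n)
        w = fit_ridge(X, y, 1e-6)
        return np.linalg.norm(w - true_w.reshape(-1)) / np.linalg.norm(true_w)

    def test_weights_recovered_and_error_shrinks_with_n(self):
        err_small = self._simulate(200, seed=1)
        err_large = self._simulate(2000, seed=2)
        assert err_large < 0.10
        assert err_large < err_small


class TestPhysiologicDirection:
    def test_higher_etco2_lowers_predicted_ph(self, ph_model):
        """More end-tidal CO2 means more arterial CO2, hence a lower pH."""
        i = ph_model.nonkey_names.index("etco2_t")
        f = ph_model.basis.evaluate(np.linspace(7.2, 7.5, 13))
        slopes = f @ ph_model.weights[i]
        assert np.all(slopes < 0)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, ph_model, validation_rows, tmp_path):
        path = tmp_path / "model.json"
        ph_model.save(path)
        loaded = PairwiseModel.load(path)
        assert np.allclose(predict(loaded, validation_rows),
                           predict(ph_model, validation_rows), atol=0)

    def test_unsupported_version_rejected(self, ph_model):
        d = ph_model.to_dict()
        d["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            PairwiseModel.from_dict(d)


def test_train_pairwise_model_fits_synthetic_cohort(ph_model, validation_rows):
    err = np.abs(predict(ph_model, validation_rows) - validation_rows["ph_t"])
    assert np.percentile(err, 95) < 0.10  # well inside the clinically useful band


class TestSelectPredictors:
    def test_pure_noise_predictor_dropped(self, derivation_rows, split_plan,
                                          default_basis):
        rows = derivation_rows.copy()
        rows["noise"] = np.random.default_rng(0).normal(size=len(rows))
        from bgestimate.model_core import DEFAULT_NONKEY, select_predictors

        selected, score = select_predictors(
            rows, split_plan, default_basis, 1.0,
            candidates=(CONST_TERM, "etco2_t", "hco3_prev", "paco2_prev",
                        "etco2_prev", "noise"))
        assert "noise" not in selected
        assert CONST_TERM in selected
        assert score > 0

    def test_constant_term_always_retained(self, derivation_rows, split_plan,
                                           default_basis):
        from bgestimate.model_core import select_predictors

        selected, _ = select_predictors(
            rows=derivation_rows, split_plan=split_plan, basis=default_basis,
            penalty=1.0, candidates=("etco2_t", "hco3_prev", "paco2_prev",
                                     "etco2_prev"), min_keep=2)
        assert selected[0] == CONST_TERM
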