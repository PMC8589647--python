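"""Ridge brain-age model: oracle equivalence, shrinkage properties,
serialization, and brain-PAD arithmetic."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import brainpad as bp
from brainpad.model import (DEFAULT_LAMBDA, ModelError, crossvalidate,
                            fit_model, load_model, predict, save_model,
                            scaled_mae, prediction_metrics)


def _instance(n=20, p=5, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    beta = rng.normal(size=p)
    y = 45.0 + x.to_numpy() @ beta + noise * rng.normal(size=n)
    return x, y


def _ridge_oracle(x, y, lam):
    """Normal-equations oracle on standardized, centered data."""
    z = (x - x.mean(0)) / x.std(0)
    yc = y - y.mean()
    p = z.shape[1]
    coef = np.linalg.solve(z.T @ z + lam * np.eye(p), z.T @ yc)
    return coef, y.mean()


class TestFit:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 50.0])
    def test_matches_normal_equations_oracle(self, lam):
        x, y = _instance()
        m = fit_model(x, y, lam=lam)
        coef, intercept = _ridge_oracle(x.to_numpy(), y, lam)
        assert np.allclose(m.coef, coef, atol=1e-8)
        assert m.intercept == pytest.approx(intercept, abs=1e-8)

    def test_noiseless_linear_data_recovered(self):
        x, y = _instance(n=60, noise=0.0)
        m = fit_model(x, y, lam=1e-8)
        mae = np.abs(m.predict_array(x.to_numpy()) - y).mean()
        assert mae < 0.01

    def test_infinite_shrinkage_predicts_mean_age(self):
        x, y = _instance(n=60)
        m = fit_model(x, y, lam=1e9)
        yhat = m.predict_array(x.to_numpy())
        assert np.allclose(yhat, y.mean(), atol=0.01)

    def test_zero_variance_feature_named(self):
        x, y = _instance()
        x["flatline"] = 3.14
        with pytest.raises(ModelError, match="flatline"):
            fit_model(x, y)

    def test_missing_values_rejected(self):
        x, y = _instance()
        x.iloc[0, 0] = np.nan
        with pytest.raises(ModelError, match="missing"):
            fit_model(x, y)

    def test_underdetermined_warns(self):
        x, y = _instance(n=4, p=5)
        with pytest.warns(UserWarning, match="underdetermined"):
            fit_model(x, y)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_standardization_equivariance(self, scale):
        # rescaling a raw feature by any constant leaves predictions fixed
        x, y = _instance()
        base = fit_model(x, y).predict_array(x.to_numpy())
        x2 = x.copy()
        x2["f2"] = x2["f2"] * scale
        rescaled = fit_model(x2, y).predict_array(x2.to_numpy())
        assert np.allclose(base, rescaled, atol=1e-6)

    def test_monotone_shrinkage(self):
        x, y = _instance(n=100)
        var = [fit_model(x, y, lam=lam).predict_array(x.to_numpy()).var()
               for lam in (0.0, 1.0, 10.0, 100.0, 1e4)]
        assert all(a >= b - 1e-12 for a, b in zip(var, var[1:]))


class TestCrossvalidate:
    def test_deterministic(self):
        x, y = _instance(n=80)
        a = crossvalidate(x, y, folds=5, seed=3)
        b = crossvalidate(x, y, folds=5, seed=3)
        assert a == b

    def test_perfect_predictor(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(18, 75, 100)
        x = pd.DataFrame({"age_copy": age, "noise": rng.normal(size=100)})
        cv = crossvalidate(x, age, lam=1e-8, folds=5, seed=0)
        assert cv.mae < 0.05
        assert cv.r > 0.999

    def test_too_small_fold_rejected(self):
        x, y = _instance(n=10)
        with pytest.raises(ModelError, match="fold"):
            crossvalidate(x, y, folds=9)

    def test_single_fold_rejected(self):
        x, y = _instance()
        with pytest.raises(ModelError, match="folds"):
            crossvalidate(x, y, folds=1)


class TestPredict:
    def test_brain_pad_is_yhat_minus_age(self):
        x, y = _instance(n=40)
        m = fit_model(x, y)
        out = predict(m, x, y)
        assert np.allclose(out["brain_pad"], out["yhat"] - out["age"])

    def test_held_out_age_slope_below_one(self, default_study):
        # regression-to-the-mean bias of shrinkage age predictors
        preds = default_study.predictions.merge(
            default_study.cohort[["participant_id", "dx"]])
        ctl = preds[preds["dx"] == "control"]
        slope = np.polyfit(ctl["age"], ctl["yhat"], 1)[0]
        assert 0.4 < slope < 1.0

    def test_old_subsample_has_negative_mean_pad(self, default_study):
        preds = default_study.predictions.merge(
            default_study.cohort[["participant_id", "dx"]])
        old = preds[(preds["dx"] == "control") & (preds["age"] >= 60)]
        assert old["brain_pad"].mean() < 0

    def test_unit_mismatch_warns(self, small_study):
        m = small_study.models["female"]
        feats = small_study.features77.head(5).copy()
        feats["insula_thickavg"] = 2500.0  # mm^2-scale value in a mm column
        with pytest.warns(UserWarning, match="unit"):
            predict(m, feats, np.full(5, 50.0))


class TestScaledMAE:
    def test_worked_example(self):
        assert round(scaled_mae(4.6, 18, 65), 2) == 0.10

    def test_wide_range_ratio(self):
        assert scaled_mae(6.6, 18, 75) == pytest.approx(0.1158, abs=1e-4)

    def test_zero_mae(self):
        assert scaled_mae(0.0, 18, 75) == 0.0

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            scaled_mae(5.0, 65, 18)


class TestSerialization:
    def test_round_trip_predictions_identical(self, tmp_path):
        x, y = _instance(n=30)
        m = fit_model(x, y)
        p = tmp_path / "model.json"
        save_model(m, p)
        m2 = load_model(p)
        assert np.array_equal(m.predict_array(x.to_numpy()),
                              m2.predict_array(x.to_numpy()))

    def test_permuted_feature_order_same_predictions(self, tmp_path):
        x, y = _instance(n=30)
        m = fit_model(x, y)
        p = tmp_path / "model.json"
        save_model(m, p)
        m2 = load_model(p)
        permuted = x[list(reversed(x.columns))]
        a = predict(m, x, y)["yhat"]
        b = predict(m2, permuted, y)["yhat"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_truncated_file_is_explicit_error(self, tmp_path):
        x, y = _instance()
        p = tmp_path / "model.json"
        save_model(fit_model(x, y), p)
        p.write_text(p.read_text()[: 40])
        with pytest.raises(ModelError, match="valid model file"):
            load_model(p)

    def test_schema_version_mismatch(self, tmp_path):
        x, y = _instance()
        p = tmp_path / "model.json"
        save_model(fit_model(x, y), p)
        doc = json.loads(p.read_text())
        doc["schema_version"] = 99
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelError, match="schema version"):
            load_model(p)


class TestSexSeparation:
    def test_models_share_nothing(self, small_study):
        a, b = small_study.models["male"], small_study.models["female"]
        assert a.scaler_mean != b.scaler_mean
        assert a.coef != b.coef
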