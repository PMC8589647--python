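"""Sex-specific normative brain-age models.

A model is a ridge regression of chronological age on z-scored
morphometric features, fit in healthy controls only. Prediction is the
affine map

    yhat = intercept + sum_f coef_f * (x_f - mean_f) / sd_f

with scaler statistics learned on the training sample and carried with
the model. Brain-PAD (brain-predicted age difference) is yhat - age.

Like any shrinkage estimator of age, the model systematically
overpredicts in the young and underpredicts in the old (the slope of
yhat on age in held-out controls is < 1); downstream inference handles
this with age covariates rather than by rescaling predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

SCHEMA_VERSION = 1

MODEL_VARIANTS = ("all77", "left_right_separate", "thickness_only",
                  "area_only", "subcortical_only", "icv_only")

DEFAULT_LAMBDA = 1.0  # ridge penalty on standardized features


class ModelError(ValueError):
    pass


@dataclass
class CVMetrics:
    """Pooled out-of-fold performance: MAE (with SD of absolute errors),
    Pearson r, and R^2 (proportion of variance explained)."""

    mae: float
    mae_sd: float
    r: float
    r2: float
    n: int
    folds: int


@dataclass
class BrainAgeModel:
    sex: str
    feature_names: list[str]
    scaler_mean: list[float]
    scaler_sd: list[float]
    coef: list[float]  # years per standardized unit
    intercept: float  # years
    lam: float
    variant: str = "all77"
    metadata: dict = field(default_factory=dict)

    def predict_array(self, x: np.ndarray) -> np.ndarray:
        z = (x - np.asarray(self.scaler_mean)) / np.asarray(self.scaler_sd)
        return self.intercept + z @ np.asarray(self.coef)


def _feature_frame(features: pd.DataFrame,
                   names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    x = features.drop(columns=["participant_id"], errors="ignore")
    if names is not None:
        missing = [c for c in names if c not in x.columns]
        if missing:
            raise ModelError(f"missing feature columns: {missing[:5]}")
        x = x[list(names)]  # name-based alignment; column order is free
    return x.astype(float)


def fit_model(train_features: pd.DataFrame, ages: Sequence[float],
              lam: float = DEFAULT_LAMBDA, sex: str = "pooled",
              variant: str = "all77", metadata: Optional[dict] = None,
              ) -> BrainAgeModel:
    """Fit the standardized ridge model of age on features.

    With ``lam = 0`` this is ordinary least squares. Raises on missing
    values or zero-variance features (the scaler would be undefined).
    """
    if lam < 0:
        raise ModelError("ridge penalty must be >= 0")
    x = _feature_frame(train_features)
    y = np.asarray(ages, dtype=float)
    if x.isna().any().any() or np.isnan(y).any():
        raise ModelError("missing values in training data; run QC first")
    if len(x) <= x.shape[1]:
        warnings.warn(
            f"n = {len(x)} <= p = {x.shape[1]}: ridge fit is underdetermined",
            stacklevel=2)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    dead = sd[sd == 0]
    if len(dead):
        raise ModelError(f"zero-variance feature(s): {list(dead.index)[:5]}")
    z = (x - mean) / sd
    ridge = Ridge(alpha=lam, fit_intercept=True)
    ridge.fit(z.to_numpy(), y)
    return BrainAgeModel(
        sex=sex,
        feature_names=list(x.columns),
        scaler_mean=[float(v) for v in mean],
        scaler_sd=[float(v) for v in sd],
        coef=[float(c) for c in ridge.coef_],
        intercept=float(ridge.intercept_),
        lam=float(lam),
        variant=variant,
        metadata=dict(metadata or {}, n_train=len(x)),
    )


def crossvalidate(train_features: pd.DataFrame, ages: Sequence[float],
                  lam: float = DEFAULT_LAMBDA, folds: int = 10,
                  seed: int = 0) -> CVMetrics:
    """K-fold cross-validation with metrics on pooled out-of-fold
    predictions (a single MAE/SD pair, not per-fold averages)."""
    if folds < 2:
        raise ModelError("folds must be >= 2")
    x = _feature_frame(train_features)
    y = np.asarray(ages, dtype=float)
    if len(y) < 2 * folds:
        raise ModelError("a fold would have fewer than 2 members")
    oof = np.full(len(y), np.nan)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(x):
        m = fit_model(x.iloc[tr], y[tr], lam=lam)
        oof[te] = m.predict_array(x.iloc[te].to_numpy())
    err = np.abs(oof - y)
    ss_res = float(np.sum((y - oof) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CVMetrics(
        mae=float(err.mean()), mae_sd=float(err.std(ddof=1)),
        r=float(stats.pearsonr(oof, y)[0]), r2=1.0 - ss_res / ss_tot,
        n=len(y), folds=folds,
    )


def predict(model: BrainAgeModel, features: pd.DataFrame,
            ages: Sequence[float],
            participant_ids: Optional[Sequence] = None,
            role: str = "test") -> pd.DataFrame:
    """Apply a trained model; no refitting occurs.

    Returns a PredictionResult frame with columns
    ``participant_id, age, yhat, brain_pad, model, role``;
    ``brain_pad`` is identically ``yhat - age`` (years).
    """
    if participant_ids is None and "participant_id" in features.columns:
        participant_ids = features["participant_id"].to_numpy()
    x = _feature_frame(features, names=model.feature_names)
    thick = [c for c in model.feature_names if c.endswith("_thickavg")]
    if thick and (x[thick] > 100).any().any():
        warnings.warn("thickness column exceeds 100 (mm expected): "
                      "possible unit mismatch", stacklevel=2)
    yhat = model.predict_array(x.to_numpy())
    ages = np.asarray(ages, dtype=float)
    return pd.DataFrame({
        "participant_id": (participant_ids if participant_ids is not None
                           else np.arange(len(x))),
        "age": ages,
        "yhat": yhat,
        "brain_pad": yhat - ages,
        "model": f"{model.sex}:{model.variant}",
        "role": role,
    })


def prediction_metrics(predictions: pd.DataFrame) -> CVMetrics:
    """MAE / r / R^2 of a prediction frame (held-out evaluation)."""
    y = predictions["age"].to_numpy()
    yhat = predictions["yhat"].to_numpy()
    err = np.abs(yhat - y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # r undefined for a constant predictor (e.g. fully perturbed input)
    r = (np.nan if np.std(yhat) < 1e-8 or np.std(y) < 1e-8
         else float(stats.pearsonr(yhat, y)[0]))
    return CVMetrics(
        mae=float(err.mean()), mae_sd=float(err.std(ddof=1)),
        r=r,
        r2=1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot,
        n=len(y), folds=0,
    )


def scaled_mae(mae: float, age_lo: float, age_hi: float) -> float:
    """MAE scaled to the covered age range: ``mae / (age_hi - age_lo)``.

    A dimensionless accuracy measure that makes models trained on
    different age ranges comparable.
    """
    if age_hi <= age_lo:
        raise ValueError("age range must have positive width")
    if mae < 0:
        raise ValueError("mae must be >= 0")
    return mae / (age_hi - age_lo)


def save_model(model: BrainAgeModel, path) -> None:
    """Serialize to a versioned JSON document (round-trip exact)."""
    doc = {"schema_version": SCHEMA_VERSION, "model": asdict(model)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> BrainAgeModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelError(f"not a valid model file: {e}") from e
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelError(
            f"model schema version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})")
    return BrainAgeModel(**doc["model"])
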