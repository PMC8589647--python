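"""Model interpretation: structure coefficients, modality perturbation,
and single-modality model comparisons.

Ridge weights from a multivariable model of correlated brain measures do
not admit a direct regional interpretation, so feature importance is
summarized instead by (1) structure coefficients — Pearson correlations
between predicted brain age and each feature in the held-out samples,
(2) re-evaluating the fixed model after perturbing whole modalities, and
(3) refitting models restricted to a single modality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import registry
from .model import (BrainAgeModel, crossvalidate, fit_model, predict,
                    prediction_metrics)

#: modalities eligible for perturbation / single-modality refits
PERTURBABLE = (registry.THICKNESS, registry.SURFACE_AREA,
               registry.SUBCORTICAL_VOLUME)


def structure_coefficients(predictions: pd.DataFrame,
                           features: pd.DataFrame,
                           group_labels: Optional[pd.Series] = None,
                           ) -> pd.DataFrame:
    """Per-feature Pearson correlation with predicted brain age.

    Computed in held-out samples, per group (plus ``pooled``). Rows with
    an undefined correlation (zero-variance feature) are flagged.
    Structure coefficients are invariant to affine rescaling of the
    feature.
    """
    feats = features.drop(columns=["participant_id"], errors="ignore")
    yhat = predictions["yhat"].to_numpy()
    if len(feats) != len(yhat):
        raise ValueError("predictions and features must align row-wise")
    mod = registry.modality_map()
    groups = {"pooled": np.ones(len(yhat), dtype=bool)}
    if group_labels is not None:
        lab = np.asarray(group_labels)
        for g in pd.unique(lab):
            groups[str(g)] = lab == g
    rows = []
    for gname, mask in groups.items():
        for col in feats.columns:
            x = feats[col].to_numpy()[mask]
            flagged = np.std(x) == 0
            r = np.nan if flagged else float(sps.pearsonr(x, yhat[mask])[0])
            rows.append(dict(feature=col, modality=mod.get(col, "other"),
                             group=gname, r=r, flagged=bool(flagged)))
    return pd.DataFrame(rows)


def modality_summary(coefs: pd.DataFrame, group: str = "pooled") -> pd.Series:
    """Mean structure coefficient per modality within one group."""
    sub = coefs[(coefs["group"] == group) & ~coefs["flagged"]]
    return sub.groupby("modality")["r"].mean()


@dataclass
class PerturbationResult:
    modality: str
    mae_before: float
    mae_after: float

    @property
    def delta_mae(self) -> float:
        return self.mae_after - self.mae_before


def perturb_modality(model: BrainAgeModel, test_features: pd.DataFrame,
                     ages: Sequence[float], modality: str,
                     raw_zero: bool = False) -> PerturbationResult:
    """Zero out one modality in the test matrix and re-evaluate the
    unchanged model.

    By default features are zeroed on the standardized scale, i.e.
    replaced by their training means — a raw zero is an anatomically
    impossible thickness or volume and mostly measures distance to the
    origin; pass ``raw_zero=True`` to get that behaviour anyway.
    ``modality='none'`` is the identity control.
    """
    valid = PERTURBABLE + (registry.VENTRICLE, registry.ICV, "none", "all")
    if modality not in valid:
        raise ValueError(
            f"unknown modality {modality!r}; valid: {', '.join(valid)}")
    base = predict(model, test_features, ages)
    before = prediction_metrics(base).mae
    if modality == "none":
        return PerturbationResult(modality, before, before)
    if modality == "all":
        targets = [f for f in model.feature_names]
    else:
        targets = [f for f in registry.features_of_modality(modality)
                   if f in model.feature_names]
    perturbed = test_features.copy()
    means = dict(zip(model.feature_names, model.scaler_mean))
    for f in targets:
        perturbed[f] = 0.0 if raw_zero else means[f]
    after = prediction_metrics(predict(model, perturbed, ages)).mae
    return PerturbationResult(modality, before, after)


def single_modality_models(train_features: pd.DataFrame,
                           train_ages: Sequence[float],
                           test_features: pd.DataFrame,
                           test_ages: Sequence[float],
                           lam: float = 1.0, folds: int = 10,
                           seed: int = 0, sex: str = "pooled",
                           ) -> pd.DataFrame:
    """Fit the all-77 model and each restricted variant on identical
    splits and report CV + test MAE / r / R^2 per variant."""
    variants: dict[str, list[str]] = {
        "all77": registry.averaged_columns(),
        "thickness_only": registry.features_of_modality(registry.THICKNESS),
        "area_only": registry.features_of_modality(registry.SURFACE_AREA),
        "subcortical_only": registry.features_of_modality(
            registry.SUBCORTICAL_VOLUME),
        "icv_only": [registry.ICV_COLUMN],
    }
    rows = []
    for name, cols in variants.items():
        xtr = train_features[["participant_id"] + cols] \
            if "participant_id" in train_features.columns \
            else train_features[cols]
        xte = test_features[["participant_id"] + cols] \
            if "participant_id" in test_features.columns \
            else test_features[cols]
        m = fit_model(xtr, train_ages, lam=lam, sex=sex, variant=name)
        te = prediction_metrics(predict(m, xte, test_ages))
        cv = crossvalidate(xtr, train_ages, lam=lam, folds=folds, seed=seed)
        rows.append(dict(variant=name, n_features=len(cols),
                         test_mae=te.mae, test_r=te.r, test_r2=te.r2,
                         cv_mae=cv.mae, cv_r=cv.r, cv_r2=cv.r2))
    return pd.DataFrame(rows)


def plot_structure_coefficients(coefs: pd.DataFrame, group: str = "pooled",
                                path=None):
    """Strip plot of structure coefficients by modality (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = coefs[(coefs["group"] == group) & ~coefs["flagged"]]
    mods = [m for m in registry.MODALITIES if m in set(sub["modality"])]
    fig, ax = plt.subplots(figsize=(7, 4))
    rng = np.random.default_rng(0)
    for i, m in enumerate(mods):
        r = sub.loc[sub["modality"] == m, "r"]
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(r)), r, s=12, alpha=0.7)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xticks(range(len(mods)), mods, rotation=20)
    ax.set_ylabel("structure coefficient (Pearson r)")
    ax.set_title(f"Predicted brain age vs. features ({group})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
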