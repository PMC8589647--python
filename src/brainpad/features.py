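"""Construction and QC of the 77-feature analysis matrix.

``average_hemispheres`` collapses the 153 raw measures to 77 by taking
the arithmetic mean (left + right) / 2 of every paired measure; ICV is
unpaired and passes through. ``qc_outliers`` flags statistically extreme
cells (within-sex z-scores) and applies a complete-case policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import registry


class SchemaError(ValueError):
    """A required feature column is missing or malformed."""


def is_averaged(features: pd.DataFrame) -> bool:
    """True if the matrix carries the 77 averaged columns (vs. 153 raw)."""
    return all(c in features.columns for c in registry.averaged_columns())


def average_hemispheres(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse a 153-column raw matrix to the 77-feature analysis matrix.

    Idempotent: input that already carries the 77 averaged columns (and
    no paired hemisphere columns) is returned with columns in registry
    order. Non-feature columns (e.g. ``participant_id``) pass through in
    front.

    Raises
    ------
    SchemaError
        If one hemisphere of a paired measure (or ICV) is absent.
    """
    pairs = registry.hemisphere_pairs()
    has_raw = any(l in raw.columns or r in raw.columns for l, r in pairs.values())
    if not has_raw and is_averaged(raw):
        extra = [c for c in raw.columns if c not in registry.averaged_columns()]
        return raw[extra + registry.averaged_columns()]

    if registry.ICV_COLUMN not in raw.columns:
        raise SchemaError(f"missing measure: {registry.ICV_COLUMN}")
    out = pd.DataFrame(index=raw.index)
    for name, (left, right) in pairs.items():
        for col in (left, right):
            if col not in raw.columns:
                raise SchemaError(f"missing hemisphere column: {col}")
        out[name] = (raw[left].to_numpy() + raw[right].to_numpy()) / 2.0
    out[registry.ICV_COLUMN] = raw[registry.ICV_COLUMN]
    known = set(registry.raw_columns())
    extra = [c for c in raw.columns if c not in known]
    for c in reversed(extra):
        out.insert(0, c, raw[c])
    return out


@dataclass
class QCReport:
    """Outcome of the outlier screen: flagged cells and dropped rows."""

    threshold_z: float
    n_input: int
    n_dropped: int
    dropped_ids: list = field(default_factory=list)
    flagged: list = field(default_factory=list)  # (participant_id, feature, z)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def qc_outliers(features: pd.DataFrame, sex: pd.Series,
                threshold_z: float = 6.0) -> tuple[pd.DataFrame, QCReport]:
    """Screen an averaged feature matrix for statistical outliers.

    Cells with within-sex |z| > ``threshold_z`` for their feature are set
    missing, and participants with any missing feature are dropped
    (complete-case policy). Surviving values are never altered. The
    default of 6 SD removes only corrupt records, not biological extremes.

    Parameters
    ----------
    features : averaged matrix (77 feature columns, optional id column).
    sex : participant sex aligned with ``features`` rows.
    threshold_z : positive z-score cutoff; ``np.inf`` disables the screen.
    """
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")
    if not is_averaged(features):
        raise SchemaError("qc_outliers expects the 77-feature averaged matrix")
    cols = registry.averaged_columns()
    ids = (features["participant_id"]
           if "participant_id" in features.columns else features.index.to_series())
    x = features[cols].astype(float)

    flagged = []
    bad = pd.DataFrame(False, index=x.index, columns=cols)
    for s in pd.unique(sex):
        m = (sex == s).to_numpy()
        sub = x.loc[m]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1).replace(0.0, np.nan)
        z = (sub - mu) / sd
        hit = z.abs() > threshold_z
        bad.loc[m] = hit | sub.isna()
        for idx, col in zip(*np.where(hit.to_numpy())):
            flagged.append((str(ids.loc[sub.index[idx]]), cols[col],
                            float(z.iat[idx, col])))

    drop = bad.any(axis=1)
    report = QCReport(
        threshold_z=float(threshold_z),
        n_input=len(features),
        n_dropped=int(drop.sum()),
        dropped_ids=[str(i) for i in ids[drop]],
        flagged=flagged,
    )
    return features.loc[~drop].copy(), report
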