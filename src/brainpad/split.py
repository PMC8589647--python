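"""Training/test partition of a multi-site cohort.

Controls are split 50:50 within each site x sex cell, stratified on age
bins so that the training and test halves preserve the chronological age
distribution; all patients go to the test side. Site x sex cells with
fewer than 10 controls are excluded entirely (both roles, patients
included), since a normative model cannot be anchored there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_CONTROLS_PER_SITE = 10


class PartitionError(ValueError):
    pass


def split_controls(cohort: pd.DataFrame, seed: int = 0,
                   bin_width_years: float = 5.0) -> pd.DataFrame:
    """Assign participants to train/test roles.

    Within each retained site x sex cell, controls are sorted into age
    bins of ``bin_width_years``, shuffled within bin, and split 50:50
    (odd bins alternate the extra participant, train first, keeping the
    cell imbalance at most 1). Patients at retained
    cells all become test. Deterministic given ``seed`` and invariant to
    input row order (rows are ordered by participant_id before sampling).

    Returns a DataFrame with columns ``participant_id, role, stratum``.
    """
    if len(cohort) == 0:
        raise PartitionError("empty cohort")
    if bin_width_years <= 0:
        raise PartitionError("bin_width_years must be positive")
    required = {"participant_id", "site_id", "sex", "age", "dx"}
    missing = required - set(cohort.columns)
    if missing:
        raise PartitionError(f"cohort missing columns: {sorted(missing)}")

    df = cohort.sort_values("participant_id").reset_index(drop=True)
    rng = np.random.default_rng(seed)

    # retained site x sex cells: >= 10 controls of that sex at that site
    counts = (df[df["dx"] == "control"]
              .groupby(["site_id", "sex"], sort=True).size())
    retained = set(counts[counts >= MIN_CONTROLS_PER_SITE].index)
    if not retained:
        raise PartitionError(
            f"all site x sex cells fall below the {MIN_CONTROLS_PER_SITE}-control floor"
        )

    records = []
    cells = sorted(df.groupby(["site_id", "sex"], sort=True).groups)
    for site_id, sex in cells:
        if (site_id, sex) not in retained:
            continue
        cell = df[(df["site_id"] == site_id) & (df["sex"] == sex)]
        controls = cell[cell["dx"] == "control"]
        bins = np.floor((controls["age"].to_numpy() - 18.0) / bin_width_years)
        # odd bins alternate the extra participant, starting with train,
        # so that |n_train - n_test| <= 1 holds per site x sex cell
        extra_to_train = True
        for b in np.unique(bins):
            ids = controls.loc[bins == b, "participant_id"].to_numpy()
            perm = rng.permutation(len(ids))
            n_train = len(ids) // 2
            if len(ids) % 2:
                n_train += int(extra_to_train)
                extra_to_train = not extra_to_train
            stratum = f"{site_id}|{sex}|bin{int(b)}"
            for k, j in enumerate(perm):
                role = "train" if k < n_train else "test"
                records.append((ids[j], role, stratum))
        for pid in cell.loc[cell["dx"] == "MDD", "participant_id"]:
            records.append((pid, "test", f"{site_id}|{sex}|mdd"))

    out = pd.DataFrame(records, columns=["participant_id", "role", "stratum"])
    return out.sort_values("participant_id").reset_index(drop=True)


def summarize_split(assignment: pd.DataFrame,
                    cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-role, per-sex counts, age mean/SD and site count.

    The returned frame has one row per (role, sex, dx) combination present
    in the assignment.
    """
    merged = assignment.merge(cohort, on="participant_id", validate="1:1")
    rows = []
    for (role, sex, dx), g in merged.groupby(["role", "sex", "dx"], sort=True):
        rows.append(dict(role=role, sex=sex, dx=dx, n=len(g),
                         age_mean=float(g["age"].mean()),
                         age_sd=float(g["age"].std(ddof=1)),
                         n_sites=int(g["site_id"].nunique())))
    return pd.DataFrame(rows)
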