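"""Synthetic multi-site cohort generator.

Produces a demographics/clinical table and a 153-column raw feature matrix
with the statistical structure the downstream analysis assumes: sex- and
diagnosis-specific truncated-normal age distributions, per-feature age
trajectories (linear + quadratic), sex offsets, head-size (ICV) coupling,
Gaussian per-site offsets, and a diagnosis effect expressed as a shift of
``delta_mdd`` years inside the feature mean function — an MDD patient's
brain measures are drawn as those of a control ``delta_mdd`` years older.

All randomness derives from ``config.seed`` through fixed-order
substreams, so identical (config, seed) yields byte-identical output.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from . import registry
from .archetypes import AGE_CENTER, ICV_REF, default_archetypes
from .config import SimulationConfig

# ICV distribution by sex, mm^3
ICV_PARAMS = {"male": (1.55e6, 1.3e5), "female": (1.38e6, 1.2e5)}

# onset-age windows (years) for the onset categories: early <26,
# middle adulthood 26-55, late adulthood >55
_ONSET_WINDOWS = {"early": (12.0, 26.0), "middle": (26.0, 56.0), "late": (56.0, 75.0)}

_CLINICAL_COLUMNS = (
    "recurrence",
    "remission",
    "ad_use",
    "onset_category",
    "onset_age",
    "hdrs17",
    "bdi2",
)


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent (loc, scale) of a truncated normal on [lo, hi] whose
    *observed* (post-truncation) mean and SD match the targets.

    Truncation shrinks the SD, so using the observed moments as parent
    parameters directly would understate the age spread. The observed SD
    cannot exceed the uniform limit (hi - lo) / sqrt(12); targets near or
    beyond it resolve to a nearly flat distribution.
    """
    from scipy.optimize import least_squares

    def resid(theta):
        loc, log_scale = theta
        scale = float(np.exp(log_scale))
        a, b = (lo - loc) / scale, (hi - loc) / scale
        d = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [float(d.mean()) - mean, float(d.std()) - sd]

    sol = least_squares(resid, x0=[mean, np.log(sd)],
                        bounds=([lo - 200.0, np.log(1.0)],
                                [hi + 200.0, np.log(500.0)]))
    loc, log_scale = sol.x
    return float(loc), float(np.exp(log_scale))


def _truncnorm(rng, n, dist):
    loc, scale = _truncnorm_parent(dist.mean, dist.sd, dist.lo, dist.hi)
    a = (dist.lo - loc) / scale
    b = (dist.hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n,
                               random_state=rng)


def _rngs(config: SimulationConfig):
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in ss.spawn(4)]


def _demographics(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    for site in config.site_specs:
        counter = 0
        for dx, sex, n in (
            ("control", "male", site.n_control_m),
            ("control", "female", site.n_control_f),
            ("MDD", "male", site.n_mdd_m),
            ("MDD", "female", site.n_mdd_f),
        ):
            key = ("control_" if dx == "control" else "mdd_") + sex[0]
            ages = _truncnorm(rng, n, config.age_dist[key])
            for age in ages:
                rows.append((f"{site.site_id}_{counter:04d}", site.site_id,
                             sex, float(age), dx))
                counter += 1
    return pd.DataFrame(rows, columns=["participant_id", "site_id", "sex",
                                       "age", "dx"])


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and its 153-column raw feature matrix.

    Returns ``(cohort, features)``; ``features`` carries one row per
    participant (indexed like ``cohort``) with the raw left/right measures
    plus ICV, in registry column order.
    """
    config.validate()
    rng_demo, rng_site, rng_feat, rng_labels = _rngs(config)

    cohort = _demographics(config, rng_demo)
    n = len(cohort)

    # head size
    icv = np.empty(n)
    for sex, (m, s) in ICV_PARAMS.items():
        mask = (cohort["sex"] == sex).to_numpy()
        icv[mask] = rng_demo.normal(m, s, mask.sum())

    arch = default_archetypes()
    paired = arch.drop(index=registry.ICV_COLUMN)
    p = len(paired)  # 76 paired archetypes

    # per-site offsets u_fj, drawn in site order
    site_ids = [s.site_id for s in config.site_specs]
    u = {sid: rng_site.normal(0.0, 1.0, p) * paired["site_scale"].to_numpy()
         for sid in site_ids}
    u_rows = np.vstack([u[sid] for sid in cohort["site_id"]])

    t = (cohort["age"].to_numpy()
         + config.delta_mdd * (cohort["dx"] == "MDD").to_numpy()
         - AGE_CENTER)
    male = (cohort["sex"] == "male").to_numpy().astype(float)

    mu = paired["mu"].to_numpy()
    mean = (mu
            + np.outer(t, paired["slope"].to_numpy())
            + np.outer(t ** 2, paired["quad"].to_numpy())
            + np.outer(male, paired["sex_offset"].to_numpy())
            + np.outer(icv - ICV_REF, paired["icv_coupling"].to_numpy())
            + u_rows)
    eps = rng_feat.normal(0.0, 1.0, (n, p)) * (
        config.noise_multiplier * paired["noise_scale"].to_numpy())
    values = mean + eps
    # anatomical floor: measures cannot be negative (only the ventricle
    # tail is ever affected at default noise)
    values = np.maximum(values, 0.005 * mu)

    # split each averaged value into antisymmetric left/right measures so
    # that (L + R) / 2 recovers it exactly
    eta = rng_feat.normal(0.0, 1.0, (n, p)) * paired["lr_noise"].to_numpy()
    delta_lr = paired["lr_offset"].to_numpy() + eta
    cols: dict[str, np.ndarray] = {"participant_id": cohort["participant_id"]}
    for j, name in enumerate(paired.index):
        cols[f"L_{name}"] = values[:, j] + delta_lr[:, j]
        cols[f"R_{name}"] = values[:, j] - delta_lr[:, j]
    cols[registry.ICV_COLUMN] = icv
    features = pd.DataFrame(cols, index=cohort.index)
    features = features[["participant_id"] + registry.raw_columns()]

    cohort = _draw_clinical_labels(cohort, config, rng_labels)
    return cohort, features


def assign_clinical_labels(cohort: pd.DataFrame,
                           config: SimulationConfig) -> pd.DataFrame:
    """Draw clinical subgroup labels and severity scores for MDD rows.

    Labels follow ``config.subgroup_props`` (independent of the feature
    draw and of ``delta_mdd``: the packaged default is a homogeneous
    diagnosis effect); severity scores are drawn independent of the brain
    features. Controls receive missing values throughout. Deterministic
    in ``config.seed``: regenerating labels for the same cohort and
    config reproduces them exactly.
    """
    if "dx" not in cohort.columns:
        raise ValueError("cohort must have a populated 'dx' column")
    return _draw_clinical_labels(cohort, config, _rngs(config)[3])


def _draw_axis(rng, props: dict[str, float], n: int) -> np.ndarray:
    cats = sorted(props)
    pvec = np.array([props[c] for c in cats])
    return rng.choice(cats, size=n, p=pvec / pvec.sum())


def _draw_clinical_labels(cohort, config, rng) -> pd.DataFrame:
    config.validate()
    out = cohort.copy()
    for col in _CLINICAL_COLUMNS:
        out[col] = np.nan
        if col not in ("onset_age", "hdrs17", "bdi2"):
            out[col] = out[col].astype(object)

    mdd = out.index[out["dx"] == "MDD"]
    n = len(mdd)
    if n == 0:
        return out

    props = config.subgroup_props
    out.loc[mdd, "recurrence"] = _draw_axis(rng, props.recurrence, n)
    out.loc[mdd, "remission"] = _draw_axis(rng, props.remission, n)
    out.loc[mdd, "ad_use"] = _draw_axis(rng, props.ad_use, n)

    # onset: restrict to categories whose window starts at or below the
    # participant's current age, then renormalize
    cats = sorted(props.onset)
    pvec = np.array([props.onset[c] for c in cats])
    ages = out.loc[mdd, "age"].to_numpy()
    onset_cat = np.empty(n, dtype=object)
    onset_age = np.full(n, np.nan)
    for i, age in enumerate(ages):
        feas = np.array([c == "unknown" or _ONSET_WINDOWS[c][0] <= age
                         for c in cats])
        pv = pvec * feas
        cat = rng.choice(cats, p=pv / pv.sum())
        onset_cat[i] = cat
        if cat != "unknown":
            lo, hi = _ONSET_WINDOWS[cat]
            onset_age[i] = rng.uniform(lo, min(hi, age))
    out.loc[mdd, "onset_category"] = onset_cat
    out.loc[mdd, "onset_age"] = onset_age

    for col in ("hdrs17", "bdi2"):
        sc = config.severity[col]
        raw = np.rint(np.clip(rng.normal(sc.mean, sc.sd, n), sc.lo, sc.hi))
        zero = rng.random(n) < sc.zero_inflation
        raw[zero] = 0.0
        out.loc[mdd, col] = raw

    # label fields for controls stay missing; replace the object-NaN by NA
    for col in ("recurrence", "remission", "ad_use", "onset_category"):
        out[col] = out[col].where(out["dx"] == "MDD", other=pd.NA)
    return out
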