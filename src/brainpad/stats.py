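"""Case-control and clinical-subgroup inference on brain-PAD.

Brain-PAD is modelled with linear mixed models carrying a random
intercept per scanning site:

    brain_PAD_ij = b0 + b1 Dx + b2 sex + b3 age + b4 age^2
                   [+ b5 Dx*age + b6 Dx*sex + b7 age*sex + b8 Dx*age*sex]
                   + U_j + eps_ij,
    U_j ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma_e^2).

Age and age^2 enter as covariates to absorb the regression-to-the-mean
bias of the brain-age predictor. Interaction terms are pruned by
backward elimination; the diagnosis effect is summarized as Cohen's
d = b1 / sqrt(sigma_u^2 + sigma_e^2) with the standard two-sample SE.
Fixed effects are tested with two-sided Wald z tests (large samples);
subgroup and severity findings are Benjamini-Hochberg FDR corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

# fixed-effect terms, in canonical order
TERM_ORDER = ("dx", "sex", "age", "age2", "dx_age", "dx_sex", "age_sex",
              "dx_age_sex")

MODEL1_TERMS = TERM_ORDER
MODEL2_TERMS = ("dx", "sex", "age", "age2", "dx_age", "dx_sex")
MODEL3_TERMS = ("dx", "sex", "age", "age2")


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed-effect structure of a brain-PAD mixed model (random site
    intercept and residual are always present)."""

    fixed_terms: tuple[str, ...]

    def validate(self, columns: Sequence[str]) -> None:
        terms = set(self.fixed_terms)
        if "age2" in terms and "age" not in terms:
            raise InferenceError("age^2 requires the linear age term")
        parents = {"dx_age": ("dx", "age"), "dx_sex": ("dx", "sex"),
                   "age_sex": ("age", "sex"),
                   "dx_age_sex": ("dx", "sex", "age", "dx_age", "dx_sex",
                                  "age_sex")}
        for t in terms:
            for p in parents.get(t, ()):
                if p not in terms:
                    raise InferenceError(
                        f"interaction {t!r} requires main effect {p!r}")
            if t not in TERM_ORDER and t not in columns:
                raise InferenceError(f"unknown model term {t!r}")


@dataclass
class MixedModelResult:
    spec: MixedModelSpec
    params: pd.DataFrame  # index: term; columns: b, se, p
    sigma_u2: float
    sigma_e2: float
    loglike: float
    reml: bool
    n: int
    n1: int  # controls
    n2: int  # patients
    n_sites: int
    converged: bool
    boundary: bool  # sigma_u^2 estimated at (or numerically near) zero

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "b"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


@dataclass
class EffectSize:
    d: float
    se_d: float
    ci95: tuple[float, float]
    n1: int
    n2: int


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------
# data preparation

def prepare_analysis_frame(predictions: pd.DataFrame, cohort: pd.DataFrame,
                           age_range: Optional[tuple[float, float]] = None,
                           ) -> pd.DataFrame:
    """Merge predictions with cohort metadata and build model columns.

    Keeps test-role rows only (statistics are computed in the held-out
    samples). Age is centered at the pooled test-sample mean before
    squaring, to decorrelate the linear and quadratic terms; reported
    age coefficients are on this centered scale.
    """
    df = predictions.merge(cohort, on="participant_id", how="inner",
                           suffixes=("", "_cohort"), validate="1:1")
    if "role" in df.columns:
        df = df[df["role"] == "test"]
    if age_range is not None:
        lo, hi = age_range
        df = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if len(df) == 0:
        raise InferenceError("no test-role rows remain after filtering")
    df = df.copy()
    center = df["age"].mean()
    df["dx01"] = (df["dx"] == "MDD").astype(float)
    df["sex_male"] = (df["sex"] == "male").astype(float)
    df["age_c"] = df["age"] - center
    df["age_c2"] = df["age_c"] ** 2
    df.attrs["age_center"] = float(center)
    return df


def _design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {
        "dx": df.get("dx01"),
        "sex": df.get("sex_male"),
        "age": df.get("age_c"),
        "age2": df.get("age_c2"),
    }
    x = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for t in terms:
        if t in cols and cols[t] is not None:
            x[t] = cols[t]
        elif t == "dx_age":
            x[t] = df["dx01"] * df["age_c"]
        elif t == "dx_sex":
            x[t] = df["dx01"] * df["sex_male"]
        elif t == "age_sex":
            x[t] = df["age_c"] * df["sex_male"]
        elif t == "dx_age_sex":
            x[t] = df["dx01"] * df["age_c"] * df["sex_male"]
        elif t in df.columns:
            x[t] = df[t].astype(float)
        else:
            raise InferenceError(f"unknown model term {t!r}")
    return x


# ---------------------------------------------------------------------
# model fitting

def fit_mixed_model(data: pd.DataFrame, terms: Sequence[str] = MODEL3_TERMS,
                    outcome: str = "brain_pad", group: str = "site_id",
                    reml: bool = True) -> MixedModelResult:
    """REML (default) or ML fit of the site-random-intercept model.

    With a single site the random intercept is not identifiable and the
    fit degenerates to ordinary least squares with ``sigma_u^2 = 0``
    (flagged as boundary). A variance component estimated at zero is
    likewise flagged, not fatal.
    """
    spec = MixedModelSpec(tuple(terms))
    spec.validate(data.columns)
    y = data[outcome].astype(float)
    if y.isna().any():
        raise InferenceError(f"missing values in outcome {outcome!r}")
    x = _design(data, terms)
    groups = data[group]
    n_sites = groups.nunique()
    n1 = int((data["dx01"] == 0).sum()) if "dx01" in data else 0
    n2 = int((data["dx01"] == 1).sum()) if "dx01" in data else 0

    if np.allclose(y.std(ddof=0), 0.0):
        params = pd.DataFrame(
            {"b": np.zeros(len(x.columns)), "se": np.nan, "p": np.nan},
            index=x.columns)
        params.loc["const", "b"] = y.iloc[0]
        return MixedModelResult(spec, params, 0.0, 0.0, np.nan, reml,
                                len(y), n1, n2, n_sites, True, True)

    if n_sites < 2:
        ols = sm.OLS(y, x).fit()
        params = pd.DataFrame({"b": ols.params, "se": ols.bse,
                               "p": ols.pvalues})
        return MixedModelResult(spec, params, 0.0, float(ols.scale),
                                float(ols.llf), False, len(y), n1, n2,
                                n_sites, True, True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # statsmodels flags a boundary sigma_u^2 via UserWarning; we
        # surface it through the `boundary` field instead
        warnings.simplefilter("ignore", UserWarning)
        mod = MixedLM(y, x, groups=groups)
        fitted = None
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                res = mod.fit(reml=reml, method=method, maxiter=500)
                se = res.bse_fe
                ok = (np.isfinite(res.llf)
                      and np.all(np.isfinite(res.fe_params))
                      and np.all(np.isfinite(se)))
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                ok = False
            if ok:
                fitted = (res, se)
                break
    if fitted is None:
        # sigma_u^2 pinned at the boundary and the mixed fit degenerate:
        # the zero-site-variance model is exactly OLS
        ols = sm.OLS(y, x).fit()
        params = pd.DataFrame({"b": ols.params, "se": ols.bse,
                               "p": ols.pvalues})
        return MixedModelResult(spec, params, 0.0, float(ols.scale),
                                float(ols.llf), False, len(y), n1, n2,
                                int(n_sites), False, True)
    res, se = fitted
    sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
    # Wald z tests (normal approximation; n in the thousands)
    pz = 2.0 * sps.norm.sf(np.abs(res.fe_params / se))
    params = pd.DataFrame({"b": res.fe_params, "se": se,
                           "p": pd.Series(pz, index=res.fe_params.index)})
    return MixedModelResult(
        spec, params, sigma_u2, float(res.scale), float(res.llf), reml,
        len(y), n1, n2, int(n_sites), bool(res.converged),
        boundary=sigma_u2 < 1e-8 * float(res.scale),
    )


def backward_eliminate(data: pd.DataFrame, alpha: float = 0.05,
                       outcome: str = "brain_pad", group: str = "site_id",
                       ) -> tuple[MixedModelSpec, MixedModelResult]:
    """Prune diagnosis/age/sex interactions top-down.

    Fit the full model; if the three-way Dx x age x sex term is
    nonsignificant (p >= alpha), refit with the two-way Dx interactions
    only; if both of those are nonsignificant as well, keep the
    main-effects model (Dx + sex + age + age^2).
    """
    res1 = fit_mixed_model(data, MODEL1_TERMS, outcome, group)
    if res1.pvalue("dx_age_sex") < alpha:
        return res1.spec, res1
    res2 = fit_mixed_model(data, MODEL2_TERMS, outcome, group)
    if (res2.pvalue("dx_age") < alpha) or (res2.pvalue("dx_sex") < alpha):
        return res2.spec, res2
    res3 = fit_mixed_model(data, MODEL3_TERMS, outcome, group)
    return res3.spec, res3


def compare_nested(data: pd.DataFrame, small_terms: Sequence[str],
                   big_terms: Sequence[str], outcome: str = "brain_pad",
                   group: str = "site_id") -> LRTResult:
    """Likelihood-ratio test of nested fixed-effect structures.

    Both models are refit by ML on identical rows;
    chi^2 = 2 (ll_big - ll_small) with df = the number of added fixed
    parameters (reported explicitly, never assumed).
    """
    if not set(small_terms) <= set(big_terms):
        raise InferenceError("models are not nested")
    small = fit_mixed_model(data, small_terms, outcome, group, reml=False)
    big = fit_mixed_model(data, big_terms, outcome, group, reml=False)
    chi2 = max(0.0, 2.0 * (big.loglike - small.loglike))
    df = len(big_terms) - len(small_terms)
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    return LRTResult(chi2=float(chi2), df=df, p=p)


def compare_age_terms(data: pd.DataFrame, outcome: str = "brain_pad",
                      group: str = "site_id") -> LRTResult:
    """Does a quadratic age covariate improve on a linear one?"""
    return compare_nested(data, ("dx", "sex", "age"), MODEL3_TERMS,
                          outcome, group)


# ---------------------------------------------------------------------
# effect sizes and multiplicity

def cohens_d_from_model(result: MixedModelResult,
                        term: str = "dx") -> EffectSize:
    """Standardize the group coefficient by the model's total residual
    SD: d = b / sqrt(sigma_u^2 + sigma_e^2), with the standard
    two-sample SE  sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)))  and a
    normal 95% CI d +- 1.96 SE."""
    total_var = result.sigma_u2 + result.sigma_e2
    if total_var <= 0:
        raise InferenceError("total residual variance is zero")
    if result.n1 < 2 or result.n2 < 2:
        raise InferenceError("need n1, n2 >= 2 for the SE of d")
    d = result.coef(term) / np.sqrt(total_var)
    n1, n2 = result.n1, result.n2
    se = float(np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2))))
    return EffectSize(d=float(d), se_d=se,
                      ci95=(float(d - 1.96 * se), float(d + 1.96 * se)),
                      n1=n1, n2=n2)


def cohens_d_se(d: float, n1: int, n2: int) -> float:
    """Standard error of a two-sample Cohen's d."""
    return float(np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2))))


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------
# high-level analyses

def analyze_case_control(predictions: pd.DataFrame, cohort: pd.DataFrame,
                         age_range: Optional[tuple[float, float]] = None,
                         backward: bool = True,
                         ) -> tuple[MixedModelResult, EffectSize]:
    """Pooled (both sexes) case-control contrast on held-out brain-PAD.

    Runs backward elimination from the full interaction model (or fits
    the main-effects model directly with ``backward=False``); an optional
    chronological age filter is applied before fitting.
    """
    df = prepare_analysis_frame(predictions, cohort, age_range)
    if df["dx01"].nunique() < 2:
        raise InferenceError("both diagnostic groups required after filtering")
    if backward:
        _, result = backward_eliminate(df)
    else:
        result = fit_mixed_model(df, MODEL3_TERMS)
    return result, cohens_d_from_model(result)


#: Table-style subgroup comparisons vs. controls: label -> (column, value)
SUBGROUP_DEFS = {
    "All MDD": ("dx", "MDD"),
    "First-episode MDD": ("recurrence", "first"),
    "Recurrent episode MDD": ("recurrence", "recurrent"),
    "Current MDD": ("remission", "current"),
    "Remitted MDD": ("remission", "remitted"),
    "AD medication-free": ("ad_use", "free"),
    "AD user": ("ad_use", "user"),
    "Early-onset MDD": ("onset_category", "early"),
    "Middle adult-onset MDD": ("onset_category", "middle"),
    "Late adult-onset MDD": ("onset_category", "late"),
}

_POSTHOC_PAIRS = (
    ("recurrence", "first", "recurrent"),
    ("ad_use", "free", "user"),
    ("remission", "remitted", "current"),
    ("onset_category", "early", "middle"),
    ("onset_category", "early", "late"),
    ("onset_category", "middle", "late"),
)


@dataclass
class SubgroupAnalysis:
    subgroups: pd.DataFrame  # one row per comparison vs. controls
    severity: pd.DataFrame  # continuous HDRS-17 / BDI-II slopes in MDD
    posthoc: pd.DataFrame  # patient-only pairwise contrasts


def analyze_subgroups(predictions: pd.DataFrame, cohort: pd.DataFrame,
                      low_n: int = 10) -> SubgroupAnalysis:
    """Clinical-subgroup inference on brain-PAD.

    Each subgroup is contrasted against all test controls with the
    main-effects mixed model; severity slopes are fit within patients.
    The 10 subgroup contrasts and 2 severity slopes form one BH-FDR
    family. Patient-only pairwise contrasts are reported post hoc
    (uncorrected). Subgroups below ``low_n`` members are flagged.
    """
    df = prepare_analysis_frame(predictions, cohort)
    controls = df[df["dx01"] == 0]
    patients = df[df["dx01"] == 1]
    if len(controls) == 0 or len(patients) == 0:
        raise InferenceError("need both controls and patients in test data")

    rows = []
    for label, (col, value) in SUBGROUP_DEFS.items():
        if col == "dx":
            sub = patients
        else:
            sub = patients[patients[col].eq(value).fillna(False)]
        flagged = len(sub) < low_n
        rec = dict(label=label, n=len(sub), low_n=flagged)
        if len(sub) >= 2:
            frame = pd.concat([controls, sub])
            res = fit_mixed_model(frame, MODEL3_TERMS)
            eff = cohens_d_from_model(res)
            rec.update(b=res.coef("dx"), se_b=res.se("dx"),
                       p=res.pvalue("dx"), d=eff.d, se_d=eff.se_d,
                       ci95_lo=eff.ci95[0], ci95_hi=eff.ci95[1])
        else:
            rec.update(b=np.nan, se_b=np.nan, p=np.nan, d=np.nan,
                       se_d=np.nan, ci95_lo=np.nan, ci95_hi=np.nan)
        rows.append(rec)
    subgroups = pd.DataFrame(rows)

    sev_rows = []
    for scale in ("hdrs17", "bdi2"):
        sub = patients[patients[scale].notna()].copy()
        if len(sub) >= 10 and sub[scale].std() > 0:
            res = fit_mixed_model(sub, ("sex", "age", "age2", scale))
            sev_rows.append(dict(scale=scale, n=len(sub),
                                 b=res.coef(scale), se_b=res.se(scale),
                                 p=res.pvalue(scale)))
        else:
            sev_rows.append(dict(scale=scale, n=len(sub), b=np.nan,
                                 se_b=np.nan, p=np.nan))
    severity = pd.DataFrame(sev_rows)

    # joint FDR family: 10 subgroup contrasts + 2 severity slopes
    family = np.concatenate([subgroups["p"].to_numpy(),
                             severity["p"].to_numpy()])
    ok = ~np.isnan(family)
    adj = np.full(family.shape, np.nan)
    if ok.any():
        adj[ok] = fdr_adjust(family[ok])
    subgroups["p_fdr"] = adj[: len(subgroups)]
    severity["p_fdr"] = adj[len(subgroups):]

    ph_rows = []
    for col, a, b_ in _POSTHOC_PAIRS:
        sub = patients[patients[col].isin([a, b_])].copy()
        rec = dict(contrast=f"{a} vs {b_}", axis=col, n=len(sub))
        if len(sub) >= 4 and sub[col].nunique() == 2:
            sub["contrast01"] = (sub[col] == b_).astype(float)
            res = fit_mixed_model(sub, ("sex", "age", "age2", "contrast01"))
            rec.update(b=res.coef("contrast01"), se_b=res.se("contrast01"),
                       p=res.pvalue("contrast01"))
        else:
            rec.update(b=np.nan, se_b=np.nan, p=np.nan)
        ph_rows.append(rec)
    posthoc = pd.DataFrame(ph_rows)

    return SubgroupAnalysis(subgroups=subgroups, severity=severity,
                            posthoc=posthoc)
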