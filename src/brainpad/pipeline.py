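"""End-to-end orchestration: simulate -> QC -> split -> train -> predict
-> inference -> interpretation, with manifest logging.

One global seed (``config.seed``) fans out to per-stage seeds by fixed
offsets, so any stage can be rerun in isolation and reproduce its part
of a full run. All stage outputs are pure functions of (inputs, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import features as ft
from . import importance as imp
from . import model as bm
from . import split as sp
from . import stats as st
from .config import SimulationConfig, default_config
from .simulate import generate_cohort

# fixed per-stage seed offsets
SPLIT_SEED_OFFSET = 101
CV_SEED_OFFSET = 202


@dataclass
class StudyResult:
    """In-memory result of one simulated study run."""

    config: SimulationConfig
    cohort: pd.DataFrame
    features77: pd.DataFrame
    qc_report: ft.QCReport
    assignment: pd.DataFrame
    models: dict  # sex -> BrainAgeModel
    cv_metrics: dict  # sex -> CVMetrics
    predictions: pd.DataFrame  # pooled test-role predictions
    case_control: Optional[st.MixedModelResult] = None
    effect: Optional[st.EffectSize] = None


def _sex_frames(cohort, features77, assignment):
    merged = assignment.merge(cohort[["participant_id", "sex", "age", "dx"]],
                              on="participant_id", validate="1:1")
    feats = features77.set_index("participant_id")
    return merged, feats


def run_study(config: SimulationConfig, bin_width_years: float = 5.0,
              lam: float = bm.DEFAULT_LAMBDA, qc_threshold: float = 6.0,
              folds: int = 10, crossvalidate: bool = False,
              backward: bool = True, fit_stats: bool = True) -> StudyResult:
    """Run the full study on one simulated cohort.

    Sex-specific models are trained on the training controls of each sex
    and applied, without refitting, to every test-role participant of
    that sex; the resulting brain-PAD values are pooled for inference.
    """
    cohort, raw = generate_cohort(config)
    avg = ft.average_hemispheres(raw)
    sex_by_id = cohort.set_index("participant_id")["sex"]
    avg77, qc_report = ft.qc_outliers(
        avg, sex_by_id.loc[avg["participant_id"]].reset_index(drop=True),
        threshold_z=qc_threshold)
    kept = cohort[cohort["participant_id"].isin(avg77["participant_id"])]

    assignment = sp.split_controls(kept, seed=config.seed + SPLIT_SEED_OFFSET,
                                   bin_width_years=bin_width_years)
    merged, feats = _sex_frames(kept, avg77, assignment)

    models, cvm, preds = {}, {}, []
    for sex in ("male", "female"):
        tr = merged[(merged["sex"] == sex) & (merged["role"] == "train")]
        te = merged[(merged["sex"] == sex) & (merged["role"] == "test")]
        if len(tr) == 0:
            continue
        xtr = feats.loc[tr["participant_id"]].reset_index()
        m = bm.fit_model(xtr, tr["age"].to_numpy(), lam=lam, sex=sex,
                         metadata={"seed": config.seed})
        models[sex] = m
        if crossvalidate:
            cvm[sex] = bm.crossvalidate(xtr, tr["age"].to_numpy(), lam=lam,
                                        folds=folds,
                                        seed=config.seed + CV_SEED_OFFSET)
        xte = feats.loc[te["participant_id"]].reset_index()
        preds.append(bm.predict(m, xte, te["age"].to_numpy(),
                                participant_ids=te["participant_id"].to_numpy()))
    predictions = pd.concat(preds, ignore_index=True)

    result = effect = None
    if fit_stats:
        result, effect = st.analyze_case_control(predictions, kept,
                                                 backward=backward)
    return StudyResult(config=config, cohort=kept, features77=avg77,
                       qc_report=qc_report, assignment=assignment,
                       models=models, cv_metrics=cvm,
                       predictions=predictions, case_control=result,
                       effect=effect)


def case_control_replicate(seed: int, delta: float = 1.08,
                           backward: bool = False) -> tuple[float, float]:
    """One full-pipeline replicate at the default study composition.

    Returns ``(b_dx, cohens_d)`` from the main-effects mixed model
    (age, age^2, sex covariates; site random intercept) on the pooled
    held-out brain-PAD values.
    """
    cfg = default_config(delta_mdd=delta, seed=seed)
    res = run_study(cfg, backward=backward)
    return res.case_control.coef("dx"), res.effect.d


# ---------------------------------------------------------------------
# file-based pipeline

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    outputs: dict = field(default_factory=dict)  # name -> path
    row_counts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def run_pipeline(config: SimulationConfig | str | Path, outdir: str | Path,
                 crossvalidate: bool = True) -> RunManifest:
    """Execute every stage and write CSV/JSON artifacts to ``outdir``.

    Emits the cohort, QC report, split assignment and summary, per-sex
    model files and CV metrics, pooled predictions, the case-control
    result, the subgroup table (10 rows), severity slopes, posthoc
    contrasts, structure coefficients, perturbation and single-modality
    comparisons, and a run manifest. Rerunning with the same config
    reproduces identical numerics.
    """
    from . import __version__

    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        seed=config.seed, package_version=__version__)

    def emit(name, obj, as_json=False):
        path = outdir / (f"{name}.json" if as_json else f"{name}.csv")
        if as_json:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        else:
            obj.to_csv(path, index=False)
            manifest.row_counts[name] = len(obj)
        manifest.outputs[name] = str(path)
        manifest.timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    config.to_yaml(outdir / "config.yaml")
    manifest.outputs["config"] = str(outdir / "config.yaml")

    study = run_study(config, crossvalidate=crossvalidate)
    emit("cohort", study.cohort)
    study.qc_report.to_json(outdir / "qc_report.json")
    manifest.outputs["qc_report"] = str(outdir / "qc_report.json")
    emit("split_assignment", study.assignment)
    emit("split_summary", sp.summarize_split(study.assignment, study.cohort))
    for sex, m in study.models.items():
        p = outdir / f"model_{sex}.json"
        bm.save_model(m, p)
        manifest.outputs[f"model_{sex}"] = str(p)
    if study.cv_metrics:
        emit("cv_metrics", {s: vars(c) for s, c in study.cv_metrics.items()},
             as_json=True)
    emit("predictions", study.predictions)

    res, eff = study.case_control, study.effect
    emit("case_control", pd.DataFrame([dict(
        term=t, b=res.coef(t), se=res.se(t), p=res.pvalue(t))
        for t in res.params.index]))
    emit("effect_size", dict(d=eff.d, se_d=eff.se_d, ci95=list(eff.ci95),
                             n_controls=eff.n1, n_patients=eff.n2,
                             sigma_u2=res.sigma_u2, sigma_e2=res.sigma_e2),
         as_json=True)

    sub = st.analyze_subgroups(study.predictions, study.cohort)
    emit("subgroup_table", sub.subgroups)
    emit("severity", sub.severity)
    emit("posthoc", sub.posthoc)

    # interpretation on the pooled held-out sample
    feats = study.features77.set_index("participant_id")
    te = study.predictions
    xte = feats.loc[te["participant_id"]].reset_index()
    dx = study.cohort.set_index("participant_id").loc[
        te["participant_id"], "dx"].reset_index(drop=True)
    emit("structure_coefficients",
         imp.structure_coefficients(te, xte, group_labels=dx))

    # per-sex perturbation of the female model (largest sample), plus
    # single-modality comparison on the female split
    sex = "female" if "female" in study.models else next(iter(study.models))
    merged, feats_ix = _sex_frames(study.cohort, study.features77,
                                   study.assignment)
    tr = merged[(merged["sex"] == sex) & (merged["role"] == "train")]
    tes = merged[(merged["sex"] == sex) & (merged["role"] == "test")]
    xtr = feats_ix.loc[tr["participant_id"]].reset_index()
    xtes = feats_ix.loc[tes["participant_id"]].reset_index()
    pert = [vars(imp.perturb_modality(study.models[sex], xtes,
                                      tes["age"].to_numpy(), m))
            for m in imp.PERTURBABLE + ("none",)]
    emit("perturbation", pd.DataFrame(pert))
    emit("single_modality", imp.single_modality_models(
        xtr, tr["age"].to_numpy(), xtes, tes["age"].to_numpy(),
        seed=config.seed + CV_SEED_OFFSET, sex=sex))

    manifest.save(outdir / "manifest.json")
    return manifest
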