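"""Synthetic cohort generator: composition, determinism, label and
trajectory structure."""

import numpy as np
import pandas as pd
import pytest

import brainpad as bp
from brainpad import registry
from brainpad.archetypes import AGE_CENTER, default_archetypes
from brainpad.config import ConfigurationError, SiteSpec
from brainpad.features import average_hemispheres


class TestComposition:
    def test_default_counts(self):
        cfg = bp.default_config()
        assert cfg.n_total == 6989
        assert cfg.n_controls == 4314
        assert cfg.n_mdd == 2675

    def test_generated_counts_by_sex(self, default_study):
        g = default_study.cohort.groupby(["dx", "sex"]).size()
        assert g[("control", "male")] == 1879
        assert g[("control", "female")] == 2435
        assert g[("MDD", "male")] == 986
        assert g[("MDD", "female")] == 1689

    def test_ages_within_support(self, small_cohort):
        cohort, _ = small_cohort
        assert cohort["age"].between(18.0, 75.0).all()


class TestDeterminism:
    def test_identical_config_identical_cohort(self, small_config):
        c1, f1 = bp.generate_cohort(small_config)
        c2, f2 = bp.generate_cohort(small_config)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_seed_changes_output(self, small_config):
        cfg2 = bp.SimulationConfig.from_dict(
            {**small_config.to_dict(), "seed": small_config.seed + 1})
        _, f1 = bp.generate_cohort(small_config)
        _, f2 = bp.generate_cohort(cfg2)
        assert not np.allclose(f1["L_hippocampus_vol"], f2["L_hippocampus_vol"])

    def test_relabeling_reproduces_labels(self, small_config, small_cohort):
        cohort, _ = small_cohort
        again = bp.assign_clinical_labels(cohort.drop(
            columns=["recurrence", "remission", "ad_use", "onset_category",
                     "onset_age", "hdrs17", "bdi2"]), small_config)
        pd.testing.assert_frame_equal(cohort, again)


class TestClinicalLabels:
    def test_controls_all_missing(self, small_cohort):
        cohort, _ = small_cohort
        ctl = cohort[cohort["dx"] == "control"]
        for col in ("recurrence", "remission", "ad_use", "onset_category",
                    "onset_age", "hdrs17", "bdi2"):
            assert ctl[col].isna().all()

    def test_onset_category_consistent_with_onset_age(self, small_cohort):
        cohort, _ = small_cohort
        mdd = cohort[cohort["dx"] == "MDD"]
        known = mdd[mdd["onset_category"] != "unknown"]
        early = known[known["onset_category"] == "early"]
        middle = known[known["onset_category"] == "middle"]
        late = known[known["onset_category"] == "late"]
        assert (early["onset_age"] < 26).all()
        assert middle["onset_age"].between(26, 56, inclusive="left").all()
        assert (late["onset_age"] >= 56).all()
        assert (known["onset_age"] <= known["age"] + 1e-9).all()

    def test_remitted_count_matches_expectation(self):
        # expected 298 of 2675; allow 4 binomial SDs (~= 65)
        cohort, _ = bp.generate_cohort(bp.default_config(seed=9))
        n_rem = (cohort["remission"] == "remitted").sum()
        assert abs(n_rem - 298) < 65

    def test_all_control_cohort_has_no_labels(self):
        specs = (SiteSpec("only", 15, 15, 0, 0),)
        cohort, _ = bp.generate_cohort(
            bp.default_config(seed=3, site_specs=specs))
        assert (cohort["dx"] == "control").all()
        assert cohort["recurrence"].isna().all()

    def test_severity_within_scale_bounds(self, small_cohort):
        cohort, _ = small_cohort
        mdd = cohort[cohort["dx"] == "MDD"]
        assert mdd["hdrs17"].between(0, 52).all()
        assert mdd["bdi2"].between(0, 63).all()


class TestConfigValidation:
    def test_negative_count_names_field(self):
        with pytest.raises(ConfigurationError, match="site_specs"):
            SiteSpec("bad", -1, 5, 5, 5).validate()

    def test_empty_site_rejected(self):
        with pytest.raises(ConfigurationError, match="empty"):
            SiteSpec("bad", 0, 0, 0, 0).validate()

    def test_bad_proportions_named(self):
        cfg = bp.default_config()
        d = cfg.to_dict()
        d["subgroup_props"]["remission"] = {"current": 0.9, "remitted": 0.9,
                                            "unknown": -0.8}
        with pytest.raises(ConfigurationError, match="remission"):
            bp.SimulationConfig.from_dict(d)

    def test_nonpositive_noise_rejected(self):
        d = bp.default_config().to_dict()
        d["noise_multiplier"] = 0.0
        with pytest.raises(ConfigurationError, match="noise"):
            bp.SimulationConfig.from_dict(d)

    def test_yaml_round_trip(self, small_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        again = bp.SimulationConfig.from_yaml(p)
        assert again == small_config


@pytest.fixture(scope="module")
def control_features():
    # a single large one-site control sample isolates the age signal
    specs = (SiteSpec("big", 1500, 1500, 0, 0),)
    cfg = bp.default_config(seed=5, site_specs=specs)
    cohort, raw = bp.generate_cohort(cfg)
    return cohort, average_hemispheres(raw)


class TestTrajectoryStructure:
    @staticmethod
    def _fitted_slopes(cohort, avg):
        t = cohort["age"].to_numpy() - AGE_CENTER
        x = np.column_stack([np.ones_like(t), t, t ** 2,
                             (cohort["sex"] == "male").to_numpy(float),
                             avg["ICV"].to_numpy() - avg["ICV"].mean()])
        slopes = {}
        for f in registry.averaged_columns():
            if f == "ICV":
                continue
            beta, *_ = np.linalg.lstsq(x, avg[f].to_numpy(), rcond=None)
            slopes[f] = beta[1]
        return pd.Series(slopes)

    def test_regression_recovers_generative_slopes(self, control_features):
        cohort, avg = control_features
        fitted = self._fitted_slopes(cohort, avg)
        arch = default_archetypes().drop(index="ICV")
        resid_sd = arch["noise_scale"]
        # standardized discrepancy per feature; simulation error only
        zdiff = ((fitted - arch["slope"]) * np.sqrt(len(cohort))
                 / resid_sd).abs()
        assert (zdiff < 5).all()

    def test_sign_structure(self, control_features):
        cohort, avg = control_features
        fitted = self._fitted_slopes(cohort, avg)
        arch = default_archetypes().drop(index="ICV")
        std_slope = fitted / arch["noise_scale"]
        thickness = std_slope[arch["modality"] == registry.THICKNESS]
        positive = [f"{r}_thickavg" for r in registry.POSITIVE_SLOPE_THICKNESS]
        assert (thickness.drop(index=positive) < 0).all()
        assert (thickness[positive] > 0).all()
        assert std_slope["lateralventricle_vol"] > 0

    def test_thickness_slopes_strongest(self, control_features):
        cohort, avg = control_features
        fitted = self._fitted_slopes(cohort, avg)
        arch = default_archetypes().drop(index="ICV")
        mean_abs = (fitted / arch["noise_scale"]).abs().groupby(
            arch["modality"]).mean()
        assert mean_abs[registry.THICKNESS] > mean_abs[registry.SURFACE_AREA]
        assert mean_abs[registry.THICKNESS] > mean_abs[
            registry.SUBCORTICAL_VOLUME]

    def test_mdd_shift_moves_features_like_added_age(self):
        # delta enters as an age shift: group feature-mean difference
        # matches slope * delta for strongly sloped features
        specs = (SiteSpec("big", 0, 4000, 0, 4000),)
        d = bp.default_config(seed=7, site_specs=specs).to_dict()
        d["age_dist"]["mdd_f"] = d["age_dist"]["control_f"]
        cfg = bp.SimulationConfig.from_dict({**d, "delta_mdd": 20.0})
        cohort, raw = bp.generate_cohort(cfg)
        avg = average_hemispheres(raw)
        arch = default_archetypes()
        f = "superiorfrontal_thickavg"
        mdd = (cohort["dx"] == "MDD").to_numpy()
        t = (cohort["age"] + 20.0 * mdd - AGE_CENTER).to_numpy()
        diff = avg.loc[mdd, f].mean() - avg.loc[~mdd, f].mean()
        expected = (arch.loc[f, "slope"] * (t[mdd].mean() - t[~mdd].mean())
                    + arch.loc[f, "quad"]
                    * ((t[mdd] ** 2).mean() - (t[~mdd] ** 2).mean()))
        mc_err = 4 * arch.loc[f, "noise_scale"] * np.sqrt(2.0 / 4000)
        assert diff == pytest.approx(expected, abs=mc_err)
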