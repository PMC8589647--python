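"""Shared fixtures: a scaled-down simulated study for fast unit tests
and one full-size study reused by the integration tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import brainpad as bp
from brainpad.config import SiteSpec


def small_site_specs() -> tuple[SiteSpec, ...]:
    """Six sites, male participants at five of them (~560 participants)."""
    specs = []
    for i in range(6):
        has_m = i < 5
        specs.append(SiteSpec(f"s{i:02d}",
                              n_control_m=32 if has_m else 0,
                              n_control_f=36,
                              n_mdd_m=12 if has_m else 0,
                              n_mdd_f=20))
    return tuple(specs)


@pytest.fixture(scope="session")
def small_config():
    return bp.default_config(seed=42, site_specs=small_site_specs())


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return bp.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    return bp.run_study(small_config, backward=False)


@pytest.fixture(scope="session")
def default_study():
    """One full-size study at the default composition (6989 participants)."""
    return bp.run_study(bp.default_config(seed=1), crossvalidate=True)


def simulate_pad_frame(n_sites=6, n_per_site=40, b_dx=0.0, site_sd=1.5,
                       resid_sd=7.0, age_slope=0.0, age_quad=0.0,
                       seed=0) -> pd.DataFrame:
    """Direct mixed-model data generator (outcome level, no imaging):
    an independent oracle for the inference module's operating
    characteristics."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_sites):
        u = rng.normal(0.0, site_sd)
        for i in range(n_per_site):
            dx = float(rng.random() < 0.5)
            sex = float(rng.random() < 0.5)
            age_c = rng.uniform(-22.0, 22.0)
            y = (b_dx * dx + age_slope * age_c + age_quad * age_c ** 2
                 + u + rng.normal(0.0, resid_sd))
            rows.append(dict(brain_pad=y, dx01=dx, sex_male=sex,
                             age_c=age_c, age_c2=age_c ** 2,
                             site_id=f"site{j}"))
    return pd.DataFrame(rows)
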