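"""Simulation configuration: cohort composition, age distributions,
diagnosis effect, clinical subgroup proportions and severity scales.

The packaged defaults reproduce the composition of a 22-site
case-control mega-analysis of 6989 adults (4314 controls: 1879 male,
2435 female; 2675 MDD patients: 986 male, 1689 female), with male
participants present at 16 of the 22 sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SiteSpec:
    """Participant counts for one scanning site, by sex and diagnosis."""

    site_id: str
    n_control_m: int
    n_control_f: int
    n_mdd_m: int
    n_mdd_f: int

    def validate(self) -> None:
        counts = (self.n_control_m, self.n_control_f, self.n_mdd_m, self.n_mdd_f)
        if any(c < 0 for c in counts):
            raise ConfigurationError(
                f"site_specs: negative count in site {self.site_id!r}"
            )
        if sum(counts) == 0:
            raise ConfigurationError(f"site_specs: site {self.site_id!r} is empty")


@dataclass(frozen=True)
class AgeDistribution:
    """Truncated-normal age distribution on [lo, hi] years.

    ``mean`` and ``sd`` are the *observed* (post-truncation) moments;
    the generator solves for the parent parameters that reproduce them.
    """

    mean: float
    sd: float
    lo: float = 18.0
    hi: float = 75.0

    def validate(self) -> None:
        if not (self.lo < self.hi):
            raise ConfigurationError("age_dist: lo must be < hi")
        if self.sd <= 0:
            raise ConfigurationError("age_dist: sd must be positive")


@dataclass(frozen=True)
class SeverityScale:
    """Zero-inflated discretized-normal severity score within scale bounds."""

    mean: float
    sd: float
    lo: int
    hi: int
    zero_inflation: float = 0.0

    def validate(self, name: str) -> None:
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ConfigurationError(f"{name}: zero_inflation outside [0, 1]")
        if self.sd <= 0 or self.hi <= self.lo:
            raise ConfigurationError(f"{name}: invalid scale parameters")


def _check_props(props: dict[str, float], name: str) -> None:
    if not props:
        raise ConfigurationError(f"subgroup_props.{name}: empty")
    for k, v in props.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(
                f"subgroup_props.{name}[{k!r}] = {v} outside [0, 1]"
            )
    if abs(sum(props.values()) - 1.0) > 1e-6:
        raise ConfigurationError(f"subgroup_props.{name}: proportions must sum to 1")


@dataclass(frozen=True)
class SubgroupProportions:
    """Clinical subgroup label proportions among MDD patients.

    Each axis maps category -> proportion (including an ``unknown`` share
    for unrecorded labels); each axis must sum to 1.
    """

    recurrence: dict[str, float]
    remission: dict[str, float]
    ad_use: dict[str, float]
    onset: dict[str, float]

    _LEVELS = {
        "recurrence": {"first", "recurrent", "unknown"},
        "remission": {"current", "remitted", "unknown"},
        "ad_use": {"user", "free", "unknown"},
        "onset": {"early", "middle", "late", "unknown"},
    }

    def validate(self) -> None:
        for axis in ("recurrence", "remission", "ad_use", "onset"):
            props = getattr(self, axis)
            _check_props(props, axis)
            extra = set(props) - self._LEVELS[axis]
            if extra:
                raise ConfigurationError(
                    f"subgroup_props.{axis}: unknown categories {sorted(extra)}"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic multi-site cohort."""

    site_specs: tuple[SiteSpec, ...]
    age_dist: dict[str, AgeDistribution]  # keys: control_m/control_f/mdd_m/mdd_f
    delta_mdd: float  # MDD shift, in brain-age years
    noise_multiplier: float
    subgroup_props: SubgroupProportions
    severity: dict[str, SeverityScale]  # keys: hdrs17, bdi2
    seed: int = 0

    def validate(self) -> None:
        if not self.site_specs:
            raise ConfigurationError("site_specs: no sites")
        ids = [s.site_id for s in self.site_specs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("site_specs: duplicate site ids")
        for s in self.site_specs:
            s.validate()
        for key in ("control_m", "control_f", "mdd_m", "mdd_f"):
            if key not in self.age_dist:
                raise ConfigurationError(f"age_dist: missing stratum {key!r}")
            self.age_dist[key].validate()
        if self.noise_multiplier <= 0:
            raise ConfigurationError("noise_multiplier must be positive")
        self.subgroup_props.validate()
        for key in ("hdrs17", "bdi2"):
            if key not in self.severity:
                raise ConfigurationError(f"severity: missing scale {key!r}")
            self.severity[key].validate(key)

    # -- totals -------------------------------------------------------
    @property
    def n_controls(self) -> int:
        return sum(s.n_control_m + s.n_control_f for s in self.site_specs)

    @property
    def n_mdd(self) -> int:
        return sum(s.n_mdd_m + s.n_mdd_f for s in self.site_specs)

    @property
    def n_total(self) -> int:
        return self.n_controls + self.n_mdd

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(
            site_specs=tuple(SiteSpec(**s) for s in d["site_specs"]),
            age_dist={k: AgeDistribution(**v) for k, v in d["age_dist"].items()},
            delta_mdd=float(d["delta_mdd"]),
            noise_multiplier=float(d["noise_multiplier"]),
            subgroup_props=SubgroupProportions(**d["subgroup_props"]),
            severity={k: SeverityScale(**v) for k, v in d["severity"].items()},
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------
# packaged defaults

_TOTALS = dict(control_m=1879, control_f=2435, mdd_m=986, mdd_f=1689)
_N_SITES = 22
_N_MALE_SITES = 16  # male participants present at 16 of the 22 sites


def _spread(total: int, n_sites: int) -> list[int]:
    base, extra = divmod(total, n_sites)
    return [base + (1 if i < extra else 0) for i in range(n_sites)]


def default_site_specs() -> tuple[SiteSpec, ...]:
    """22-site composition totalling 4314 controls and 2675 MDD patients."""
    cf = _spread(_TOTALS["control_f"], _N_SITES)
    mf = _spread(_TOTALS["mdd_f"], _N_SITES)
    cm = _spread(_TOTALS["control_m"], _N_MALE_SITES) + [0] * (_N_SITES - _N_MALE_SITES)
    mm = _spread(_TOTALS["mdd_m"], _N_MALE_SITES) + [0] * (_N_SITES - _N_MALE_SITES)
    return tuple(
        SiteSpec(f"site{i + 1:02d}", cm[i], cf[i], mm[i], mf[i])
        for i in range(_N_SITES)
    )


def default_subgroup_props() -> SubgroupProportions:
    """Clinical label proportions among 2675 MDD patients (unknown =
    unrecorded share): 903 first / 1648 recurrent; 1786 current / 298
    remitted; 1717 AD users / 939 AD-free; onset 1035 early / 1218
    middle / 259 late."""
    n = 2675.0

    def p(*counts):
        vals = [c / n for c in counts]
        return vals + [1.0 - sum(vals)]

    r = p(903, 1648)
    s = p(1786, 298)
    a = p(1717, 939)
    o = p(1035, 1218, 259)
    return SubgroupProportions(
        recurrence={"first": r[0], "recurrent": r[1], "unknown": r[2]},
        remission={"current": s[0], "remitted": s[1], "unknown": s[2]},
        ad_use={"user": a[0], "free": a[1], "unknown": a[2]},
        onset={"early": o[0], "middle": o[1], "late": o[2], "unknown": o[3]},
    )


def default_config(
    delta_mdd: float = 1.08,
    seed: int = 0,
    noise_multiplier: Optional[float] = None,
    site_specs: Optional[tuple[SiteSpec, ...]] = None,
) -> SimulationConfig:
    """The default study conditions: 22-site composition, sex- and
    diagnosis-specific truncated-normal ages on [18, 75], an MDD
    brain-age shift of ``delta_mdd`` years, and the calibrated global
    noise multiplier."""
    from .archetypes import DEFAULT_NOISE_MULTIPLIER

    cfg = SimulationConfig(
        site_specs=site_specs if site_specs is not None else default_site_specs(),
        age_dist={
            "control_m": AgeDistribution(43.1, 15.3),
            "control_f": AgeDistribution(39.4, 15.7),
            "mdd_m": AgeDistribution(42.8, 13.1),
            "mdd_f": AgeDistribution(43.2, 14.0),
        },
        delta_mdd=delta_mdd,
        noise_multiplier=(
            DEFAULT_NOISE_MULTIPLIER if noise_multiplier is None else noise_multiplier
        ),
        subgroup_props=default_subgroup_props(),
        severity={
            "hdrs17": SeverityScale(mean=14.0, sd=7.0, lo=0, hi=52, zero_inflation=0.08),
            "bdi2": SeverityScale(mean=18.0, sd=10.0, lo=0, hi=63, zero_inflation=0.08),
        },
        seed=seed,
    )
    cfg.validate()
    return cfg
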