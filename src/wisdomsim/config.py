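"""Trial configuration: risk strata, accrual, natural-history and scheduling parameters.

The default configuration describes the randomized cohort of the WISDOM
personalized breast-cancer screening trial: 65 000 women accrued over four
years, randomized 1:1 between annual mammography and a risk-stratified
("personalized") screening schedule, followed for a total trial time of
4.5 years with stage IIB-or-higher cancer as the safety endpoint.

All times are in years, measured from trial start (t = 0); per-woman event
times are absolute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import os
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional

import yaml

__all__ = [
    "ConfigError",
    "StratumSpec",
    "TrialConfig",
    "default_wisdom_config",
    "load_config",
    "serialize_config",
    "sensitivity_variant",
    "ARM_ANNUAL",
    "ARM_PERSONALIZED",
    "STRATUM_NAMES",
]

ARM_ANNUAL = 0
ARM_PERSONALIZED = 1

#: Canonical stratum order, lowest to highest risk.
STRATUM_NAMES = ("lowest", "average", "elevated", "highest")

# Per-screen detection probabilities for the reduced-sensitivity analysis,
# lowest to highest risk (sensitivity differs across strata because risk
# strata associate with different BI-RADS breast-density categories).
SENSITIVITY_ANALYSIS_VALUES = {
    "lowest": 0.93,
    "average": 0.86,
    "elevated": 0.76,
    "highest": 0.86,
}

_PROB_TOL = 1e-12


class ConfigError(ValueError):
    """Raised when a configuration fails validation; the message names the field."""


@dataclass(frozen=True)
class StratumSpec:
    """One risk stratum.

    Parameters
    ----------
    name:
        One of ``lowest``, ``average``, ``elevated``, ``highest``.
    probability:
        Fraction of the cohort in this stratum (multinomial probability).
    annual_hazard:
        Exponential onset rate per year on the probability scale
        (e.g. ``0.000414`` for an annual hazard of 0.0414%).
    personalized_interval_years:
        Screening interval assigned in the personalized arm; ``None`` means
        no screening (the lowest-risk recommendation).
    sensitivity:
        Per-screen probability that a mammogram detects a cancer that is in
        its screen-detectable window.
    """

    name: str
    probability: float
    annual_hazard: float
    personalized_interval_years: Optional[float]
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in STRATUM_NAMES:
            raise ConfigError(f"stratum name {self.name!r} not in {STRATUM_NAMES}")
        if not (0.0 < self.probability < 1.0):
            raise ConfigError(f"stratum {self.name}: probability must be in (0,1)")
        if not self.annual_hazard > 0.0:
            raise ConfigError(f"stratum {self.name}: annual_hazard must be > 0")
        if not (0.0 < self.sensitivity <= 1.0):
            raise ConfigError(f"stratum {self.name}: sensitivity must be in (0,1]")
        if self.personalized_interval_years is not None and not (
            self.personalized_interval_years > 0.0
        ):
            raise ConfigError(
                f"stratum {self.name}: personalized_interval_years must be > 0 or None"
            )


def _default_strata() -> tuple[StratumSpec, ...]:
    return (
        StratumSpec("lowest", 0.289, 0.000198, None),
        StratumSpec("average", 0.404, 0.000414, 2.0),
        StratumSpec("elevated", 0.282, 0.000774, 1.0),
        StratumSpec("highest", 0.025, 0.002808, 0.5),
    )


@dataclass(frozen=True)
class TrialConfig:
    """Every parameter of one virtual trial.

    Defaults are the WISDOM design values.  Parameters the trial protocol
    leaves open are fixed here as explicit conventions:

    * ``prevalence_model`` — ``"incidence"`` runs the onset clock from trial
      start so that prevalent (already screen-detectable) cancers at study
      entry emerge with probability proportional to the stratum hazard;
      ``"seeded"`` instead flags prevalent cancers by a Bernoulli draw with
      ``prevalence_prob`` and starts the onset clock at entry.
    * ``last_premammogram_max_years`` — upper bound of the uniform draw for
      time since the last pre-study mammogram.  The default 0 schedules the
      first on-study screen one full interval after entry.
    * ``symptomatic_detection`` — ``"within_schedule"`` observes symptomatic
      (clinically detected) cancers only while the woman is still within her
      screening schedule; ``"until_trial_end"`` observes them any time before
      trial end.
    """

    n_total: int = 65_000
    accrual_counts: tuple[int, ...] = (5_000, 25_000, 20_000, 15_000)
    accrual_period_bounds: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    randomization_ratio: float = 0.5
    trial_end_years: float = 4.5
    prevalence_model: str = "incidence"
    prevalence_prob: float = 0.0005
    sojourn_median_years: float = 1.5
    noncompliance_sd_months: float = 4.0
    annual_arm_interval_years: float = 1.0
    exit_mammogram_min_enrollment_years: float = 2.0
    last_premammogram_max_years: float = 0.0
    symptomatic_detection: str = "within_schedule"
    forced_balance: bool = False
    strata: tuple[StratumSpec, ...] = field(default_factory=_default_strata)
    noninferiority_margin: float = 0.0005
    seed: Optional[int] = None

    # -- validation ----------------------------------------------------

    def __post_init__(self) -> None:
        object.__setattr__(self, "accrual_counts", tuple(int(c) for c in self.accrual_counts))
        object.__setattr__(
            self, "accrual_period_bounds", tuple(float(b) for b in self.accrual_period_bounds)
        )
        object.__setattr__(self, "strata", tuple(self.strata))
        if self.n_total < 0:
            raise ConfigError("n_total: must be >= 0")
        if len(self.accrual_period_bounds) != len(self.accrual_counts) + 1:
            raise ConfigError(
                "accrual_period_bounds: need exactly one more bound than accrual periods"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.accrual_period_bounds, self.accrual_period_bounds[1:])):
            raise ConfigError("accrual_period_bounds: must be strictly increasing")
        if sum(self.accrual_counts) != self.n_total:
            raise ConfigError(
                f"accrual_counts: sum {sum(self.accrual_counts)} != n_total {self.n_total}"
            )
        if any(c < 0 for c in self.accrual_counts):
            raise ConfigError("accrual_counts: must be nonnegative")
        if not self.accrual_period_bounds[-1] < self.trial_end_years:
            raise ConfigError("accrual_period_bounds: accrual must end before trial_end_years")
        if not (0.0 < self.randomization_ratio < 1.0):
            raise ConfigError("randomization_ratio: must be in (0,1)")
        for name in (
            "trial_end_years",
            "sojourn_median_years",
            "noncompliance_sd_months",
            "annual_arm_interval_years",
            "exit_mammogram_min_enrollment_years",
        ):
            if not getattr(self, name) > 0.0:
                raise ConfigError(f"{name}: must be > 0")
        if self.last_premammogram_max_years < 0.0:
            raise ConfigError("last_premammogram_max_years: must be >= 0")
        if not (0.0 <= self.prevalence_prob < 1.0):
            raise ConfigError("prevalence_prob: must be in [0,1)")
        if self.prevalence_model not in ("incidence", "seeded"):
            raise ConfigError("prevalence_model: must be 'incidence' or 'seeded'")
        if self.symptomatic_detection not in ("within_schedule", "until_trial_end"):
            raise ConfigError(
                "symptomatic_detection: must be 'within_schedule' or 'until_trial_end'"
            )
        if not self.strata:
            raise ConfigError("strata: at least one stratum required")
        total_p = sum(s.probability for s in self.strata)
        if abs(total_p - 1.0) > _PROB_TOL:
            raise ConfigError(f"strata: probabilities sum to {total_p!r}, expected 1")
        n_unscreened = sum(1 for s in self.strata if s.personalized_interval_years is None)
        if n_unscreened > 1:
            raise ConfigError("strata: at most one stratum may have no personalized screening")
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            raise ConfigError("strata: duplicate stratum names")

    # -- convenience accessors ------------------------------------------

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def stratum_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.strata)

    @property
    def stratum_probabilities(self) -> tuple[float, ...]:
        return tuple(s.probability for s in self.strata)

    @property
    def stratum_hazards(self) -> tuple[float, ...]:
        return tuple(s.annual_hazard for s in self.strata)

    @property
    def sojourn_mean_years(self) -> float:
        """Mean of the exponential sojourn distribution (median / ln 2)."""
        return self.sojourn_median_years / math.log(2.0)

    @property
    def noncompliance_sd_years(self) -> float:
        return self.noncompliance_sd_months / 12.0

    def stratum_index(self, name: str) -> int:
        for i, s in enumerate(self.strata):
            if s.name == name:
                return i
        raise KeyError(name)

    def config_hash(self) -> str:
        """Stable short hash of the serialized configuration (for logging)."""
        return hashlib.sha256(serialize_config(self).encode()).hexdigest()[:12]


def default_wisdom_config() -> TrialConfig:
    """The WISDOM design configuration.

    Strata (lowest to highest risk): cohort fractions 28.9/40.4/28.2/2.5%,
    annual onset hazards 0.0198/0.0414/0.0774/0.2808%, personalized-arm
    screening intervals none/biennial/annual/6-monthly, per-screen
    sensitivity 1.
    """
    return TrialConfig()


def sensitivity_variant(config: TrialConfig) -> TrialConfig:
    """Copy of ``config`` with per-stratum sensitivities set to the
    reduced-sensitivity analysis values (93/86/76/86% lowest to highest)."""
    strata = tuple(
        replace(s, sensitivity=SENSITIVITY_ANALYSIS_VALUES.get(s.name, s.sensitivity))
        for s in config.strata
    )
    return replace(config, strata=strata)


# ---------------------------------------------------------------------------
# serialization


_SCALAR_FIELDS = tuple(
    f.name for f in dataclasses.fields(TrialConfig) if f.name not in ("strata",)
)


def serialize_config(config: TrialConfig) -> str:
    """YAML document reproducing every field of ``config`` exactly."""
    doc: dict[str, Any] = {}
    for name in _SCALAR_FIELDS:
        value = getattr(config, name)
        doc[name] = list(value) if isinstance(value, tuple) else value
    doc["strata"] = [
        {
            "name": s.name,
            "probability": s.probability,
            "annual_hazard": s.annual_hazard,
            "personalized_interval_years": s.personalized_interval_years,
            "sensitivity": s.sensitivity,
        }
        for s in config.strata
    ]
    return yaml.safe_dump(doc, sort_keys=False)


def load_config(source: Any = None) -> TrialConfig:
    """Build a validated :class:`TrialConfig` from YAML text, a file path, an
    open file, or a mapping.  Unspecified keys take the default values;
    unknown keys are rejected.  An empty document gives the defaults."""
    if source is None:
        return default_wisdom_config()
    if isinstance(source, Mapping):
        doc: Any = dict(source)
    else:
        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source, "r") as fh:
                text = fh.read()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config parse error: {exc}") from exc
    if doc is None:
        return default_wisdom_config()
    if not isinstance(doc, Mapping):
        raise ConfigError("config: top level must be a mapping")
    doc = dict(doc)
    unknown = set(doc) - set(_SCALAR_FIELDS) - {"strata"}
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name in _SCALAR_FIELDS:
        if name in doc:
            kwargs[name] = tuple(doc[name]) if isinstance(doc[name], (list, tuple)) else doc[name]
    if "strata" in doc:
        kwargs["strata"] = tuple(_parse_stratum(item) for item in doc["strata"])
    return TrialConfig(**kwargs)


def _parse_stratum(item: Any) -> StratumSpec:
    if isinstance(item, StratumSpec):
        return item
    if not isinstance(item, Mapping):
        raise ConfigError("strata: each stratum must be a mapping")
    allowed = {"name", "probability", "annual_hazard", "personalized_interval_years", "sensitivity"}
    unknown = set(item) - allowed
    if unknown:
        raise ConfigError(f"strata: unknown keys {sorted(unknown)}")
    return StratumSpec(**dict(item))
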