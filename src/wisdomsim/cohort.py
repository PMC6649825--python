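"""Virtual cohort generation: accrual, randomization, risk strata, and the
breast-cancer natural-history clocks.

The natural-history model is deliberately minimal.  Each woman may develop a
single stage IIB-or-higher cancer.  Two absolute times describe it:

``t_detectable``
    when the cancer becomes detectable by mammography (onset), drawn from an
    exponential distribution with the stratum's annual hazard;
``t_clinical``
    when it would surface symptomatically, ``t_detectable`` plus an
    exponential sojourn time with median 18 months.

Under the default ``prevalence_model="incidence"`` the onset clock runs in
calendar time from trial start, so a woman accrued in a later year may
already harbor a screen-detectable cancer when she enters: these are the
prevalent cancers, and their frequency scales with the stratum hazard.
Women whose cancer would already have surfaced symptomatically before entry
are ineligible for a screening trial and are kept as cancer-free
participants.  Under ``prevalence_model="seeded"`` prevalent status is
instead a Bernoulli flag at entry and the onset clock starts at entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ARM_ANNUAL, ARM_PERSONALIZED, TrialConfig

__all__ = [
    "Cohort",
    "simulate_entry_times",
    "assign_arms",
    "assign_strata",
    "simulate_natural_history",
]


@dataclass
class Cohort:
    """Per-woman arrays for one virtual trial.

    ``t_detectable`` and ``t_clinical`` are ``inf`` for women who never
    develop a cancer on the simulated horizon.
    """

    entry_time: np.ndarray  # float, absolute years
    arm: np.ndarray  # int8, ARM_ANNUAL / ARM_PERSONALIZED
    stratum: np.ndarray  # int8 index into config.strata
    prevalent: np.ndarray  # bool: screen-detectable at entry
    t_detectable: np.ndarray  # float, absolute years
    t_clinical: np.ndarray  # float, absolute years

    @property
    def n(self) -> int:
        return int(self.entry_time.size)

    def validate(self) -> None:
        n = self.n
        for name in ("arm", "stratum", "prevalent", "t_detectable", "t_clinical"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"cohort field {name} has wrong shape")
        has_cancer = np.isfinite(self.t_detectable)
        if not np.all(self.t_clinical[has_cancer] > self.t_detectable[has_cancer]):
            raise ValueError("t_clinical must exceed t_detectable (sojourn > 0)")
        if not np.all(self.t_detectable[self.prevalent] <= self.entry_time[self.prevalent]):
            raise ValueError("prevalent cancers must be detectable at entry")
        incident = has_cancer & ~self.prevalent
        if not np.all(self.t_detectable[incident] > self.entry_time[incident]):
            raise ValueError("non-prevalent onsets must follow entry")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "entry_time": self.entry_time,
                "arm": np.where(self.arm == ARM_PERSONALIZED, "personalized", "annual"),
                "stratum": self.stratum,
                "prevalent": self.prevalent,
                "t_detectable": self.t_detectable,
                "t_clinical": self.t_clinical,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        return cls(
            entry_time=frame["entry_time"].to_numpy(float),
            arm=np.where(frame["arm"].to_numpy() == "personalized", ARM_PERSONALIZED, ARM_ANNUAL).astype(np.int8),
            stratum=frame["stratum"].to_numpy(np.int8),
            prevalent=frame["prevalent"].to_numpy(bool),
            t_detectable=frame["t_detectable"].to_numpy(float),
            t_clinical=frame["t_clinical"].to_numpy(float),
        )


def simulate_entry_times(config: TrialConfig, rng: np.random.Generator) -> np.ndarray:
    """Entry times: exactly ``accrual_counts[j]`` women uniform in accrual
    period *j*.  Order is by period (not sorted within the cohort)."""
    bounds = config.accrual_period_bounds
    parts = [
        rng.uniform(bounds[j], bounds[j + 1], size=count)
        for j, count in enumerate(config.accrual_counts)
    ]
    if not parts:
        return np.empty(0, dtype=float)
    return np.concatenate(parts)


def assign_arms(
    n: int,
    ratio: float,
    rng: np.random.Generator,
    forced_balance: bool = False,
) -> np.ndarray:
    """Randomize women to arms.

    Simple randomization by default: each woman is personalized with
    probability ``ratio`` independently, so per-arm counts vary binomially
    (as in the trial's simple 1:1 randomization).  ``forced_balance`` deals
    out exactly ``round(n * ratio)`` personalized assignments instead.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0,1)")
    if forced_balance:
        n_pers = int(round(n * ratio))
        arms = np.full(n, ARM_ANNUAL, dtype=np.int8)
        arms[:n_pers] = ARM_PERSONALIZED
        return rng.permutation(arms)
    return (rng.random(n) < ratio).astype(np.int8)


def assign_strata(
    n: int, probabilities: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. multinomial stratum draws, independent of arm."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    return rng.choice(p.size, size=n, p=p).astype(np.int8)


def simulate_natural_history(
    entry_times: np.ndarray,
    arms: np.ndarray,
    strata: np.ndarray,
    config: TrialConfig,
    rng: np.random.Generator,
) -> Cohort:
    """Attach prevalence flags and the two natural-history clocks.

    Draw order (fixed for reproducibility): onset exponentials, sojourn
    exponentials, then — in ``"seeded"`` mode only — the prevalence
    Bernoulli uniforms.
    """
    entry_times = np.asarray(entry_times, dtype=float)
    arms = np.asarray(arms, dtype=np.int8)
    strata = np.asarray(strata, dtype=np.int8)
    n = entry_times.size
    if arms.size != n or strata.size != n:
        raise ValueError("entry_times, arms and strata must have equal length")

    hazards = np.asarray(config.stratum_hazards, dtype=float)
    onset_from_clock_start = rng.exponential(1.0, size=n) / hazards[strata]
    sojourn = rng.exponential(config.sojourn_mean_years, size=n)

    if config.prevalence_model == "seeded":
        prevalent = rng.random(n) < config.prevalence_prob
        t_detectable = entry_times + onset_from_clock_start
        # prevalent cancers are detectable from entry; the sojourn draw is
        # the residual sojourn (memorylessness)
        t_detectable[prevalent] = entry_times[prevalent]
        t_clinical = t_detectable + sojourn
    else:  # incidence: calendar clock from trial start
        t_detectable = onset_from_clock_start
        t_clinical = t_detectable + sojourn
        # symptomatic before entry -> ineligible cancer; participant stays,
        # cancer-free
        ineligible = t_clinical <= entry_times
        t_detectable = np.where(ineligible, np.inf, t_detectable)
        t_clinical = np.where(ineligible, np.inf, t_clinical)
        prevalent = t_detectable <= entry_times

    cohort = Cohort(
        entry_time=entry_times,
        arm=arms,
        stratum=strata,
        prevalent=np.asarray(prevalent, dtype=bool),
        t_detectable=t_detectable,
        t_clinical=t_clinical,
    )
    cohort.validate()
    return cohort


def simulate_cohort(config: TrialConfig, rng: np.random.Generator) -> Cohort:
    """Entry times, arms, strata and natural history in the canonical draw
    order used by :func:`wisdomsim.screening.run_single_trial`."""
    entry = simulate_entry_times(config, rng)
    arms = assign_arms(entry.size, config.randomization_ratio, rng, config.forced_balance)
    strata = assign_strata(entry.size, config.stratum_probabilities, rng)
    return simulate_natural_history(entry, arms, strata, config, rng)
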