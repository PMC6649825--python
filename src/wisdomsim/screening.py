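"""Screening schedules, noncompliance, detection, and the single-trial engine.

Scheduling convention: a woman's first on-study mammogram is planned at
``entry + max(0, interval - time_since_last_mammogram)``; by default the time
since the last pre-study mammogram is 0, i.e. the first screen comes one full
interval after entry.  Each planned screen is delayed by a nonnegative
half-normal noncompliance draw, and the *next* screen is planned one interval
after the *actual* (delayed) screen, so delays compound.  A screen whose
actual time exceeds the trial horizon does not occur.

Detection: every mammogram falling in a cancer's screen-detectable window
``[t_detectable, t_clinical)`` detects it independently with the stratum's
per-screen sensitivity; the first success is a screen detection and stops
further screening.  An undetected cancer surfaces symptomatically at
``t_clinical`` provided the woman is still under observation: by default
(``symptomatic_detection="within_schedule"``) that means ``t_clinical`` does
not fall after her last scheduled screen — cancers surfacing in the
unscreened tail between the final screen and trial end are not ascertained.
Women with no screening schedule (or none realized) can present
symptomatically any time up to trial end.

Personalized-arm women with a no-screening recommendation receive an exit
mammogram at trial end if they were enrolled at least 2 years and have not
already been diagnosed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import ARM_ANNUAL, ARM_PERSONALIZED, TrialConfig
from .cohort import Cohort, simulate_cohort

__all__ = [
    "MODE_NONE",
    "MODE_SCREEN",
    "MODE_CLINICAL",
    "ScreeningRealization",
    "Outcome",
    "TrialData",
    "TrialRandomness",
    "assigned_interval",
    "simulate_first_planned_screen",
    "simulate_noncompliance_delay",
    "simulate_screen_times",
    "exit_mammogram_time",
    "exit_mammogram_eligible",
    "detect_cancer",
    "draw_screening_randomness",
    "run_single_trial",
    "as_generator",
]

MODE_NONE = 0
MODE_SCREEN = 1
MODE_CLINICAL = 2

MODE_LABELS = {MODE_NONE: "none", MODE_SCREEN: "screen", MODE_CLINICAL: "clinical"}


def as_generator(seed: Union[int, np.random.SeedSequence, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ScreeningRealization:
    """Realized screening schedules for the whole cohort.

    ``screen_times`` is an ``(n, K)`` array of the full schedule of actual
    mammogram times within ``(entry, trial_end]``, NaN-padded.  The schedule
    is generated to the horizon irrespective of detection: it defines the
    screening-cycle structure used by the analysis.  ``n_mammograms`` counts
    only mammograms that actually happen, i.e. screens up to and including
    detection, plus the exit mammogram when one occurs.
    """

    first_planned: np.ndarray  # (n,) absolute years; NaN if no schedule
    screen_times: np.ndarray  # (n, K) actual schedule times, NaN padded
    n_screens_schedule: np.ndarray  # (n,) int
    last_screen_time: np.ndarray  # (n,) NaN if no screens
    exit_mammogram_time: np.ndarray  # (n,) NaN unless an exit mammogram occurred
    n_mammograms: np.ndarray  # (n,) int


@dataclass
class Outcome:
    detected: np.ndarray  # (n,) bool
    mode: np.ndarray  # (n,) int8, MODE_*
    detection_time: np.ndarray  # (n,) NaN if undetected
    detected_at_first_screen: np.ndarray  # (n,) bool
    prevalent_at_detection: np.ndarray  # (n,) bool


@dataclass
class TrialData:
    """One complete virtual trial: cohort, screening realization, outcomes."""

    cohort: Cohort
    screening: ScreeningRealization
    outcome: Outcome
    trial_end: float
    config: TrialConfig

    @property
    def n(self) -> int:
        return self.cohort.n

    def to_frame(self) -> pd.DataFrame:
        frame = self.cohort.to_frame()
        st = self.screening.screen_times
        frame["screen_times"] = [
            ";".join(format(t, ".17g") for t in row[np.isfinite(row)]) for row in st
        ]
        frame["first_planned"] = self.screening.first_planned
        frame["last_screen_time"] = self.screening.last_screen_time
        frame["exit_mammogram_time"] = self.screening.exit_mammogram_time
        frame["n_mammograms"] = self.screening.n_mammograms
        frame["detected"] = self.outcome.detected
        frame["mode"] = [MODE_LABELS[int(m)] for m in self.outcome.mode]
        frame["detection_time"] = self.outcome.detection_time
        frame["detected_at_first_screen"] = self.outcome.detected_at_first_screen
        frame["prevalent_at_detection"] = self.outcome.prevalent_at_detection
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: TrialConfig) -> "TrialData":
        cohort = Cohort.from_frame(frame)
        lists = [
            np.array([float(x) for x in s.split(";")] if s else [], dtype=float)
            for s in frame["screen_times"].fillna("").astype(str)
        ]
        k = max((len(v) for v in lists), default=0)
        st = np.full((len(lists), max(k, 1)), np.nan)
        for i, v in enumerate(lists):
            st[i, : len(v)] = v
        label_to_mode = {v: k for k, v in MODE_LABELS.items()}
        screening = ScreeningRealization(
            first_planned=frame["first_planned"].to_numpy(float),
            screen_times=st,
            n_screens_schedule=np.array([len(v) for v in lists]),
            last_screen_time=frame["last_screen_time"].to_numpy(float),
            exit_mammogram_time=frame["exit_mammogram_time"].to_numpy(float),
            n_mammograms=frame["n_mammograms"].to_numpy(int),
        )
        outcome = Outcome(
            detected=frame["detected"].to_numpy(bool),
            mode=np.array([label_to_mode[m] for m in frame["mode"]], dtype=np.int8),
            detection_time=frame["detection_time"].to_numpy(float),
            detected_at_first_screen=frame["detected_at_first_screen"].to_numpy(bool),
            prevalent_at_detection=frame["prevalent_at_detection"].to_numpy(bool),
        )
        return cls(cohort, screening, outcome, config.trial_end_years, config)


@dataclass
class TrialRandomness:
    """Pre-drawn screening/detection randomness for one trial.

    Both the vectorized engine and the per-woman reference implementation
    consume these arrays, so their outputs are comparable draw for draw.
    Row ``i`` belongs to woman ``i``; column ``k`` to her ``k``-th scheduled
    screen.
    """

    time_since_last: np.ndarray  # (n,)
    delays: np.ndarray  # (n, K) noncompliance delays, years
    detect_u: np.ndarray  # (n, K) uniforms for per-screen detection
    exit_u: np.ndarray  # (n,) uniform for exit-mammogram detection


def max_screens(config: TrialConfig) -> int:
    intervals = [config.annual_arm_interval_years] + [
        s.personalized_interval_years
        for s in config.strata
        if s.personalized_interval_years is not None
    ]
    shortest = min(intervals)
    return int(math.ceil(config.trial_end_years / shortest)) + 1


def draw_screening_randomness(
    n: int, config: TrialConfig, rng: np.random.Generator
) -> TrialRandomness:
    """Draw order (fixed): time-since-last-mammogram uniforms, delay matrix,
    detection uniform matrix, exit-mammogram uniforms."""
    k = max_screens(config)
    t_last = rng.uniform(0.0, 1.0, size=n) * config.last_premammogram_max_years
    delays = np.abs(rng.normal(0.0, config.noncompliance_sd_years, size=(n, k)))
    detect_u = rng.random((n, k))
    exit_u = rng.random(n)
    return TrialRandomness(t_last, delays, detect_u, exit_u)


# ---------------------------------------------------------------------------
# per-woman operations (also the building blocks of the reference engine)


def assigned_interval(arm: int, stratum: int, config: TrialConfig) -> Optional[float]:
    """Screening interval for a woman: the annual-arm interval for everyone in
    the annual arm; the stratum's personalized interval (possibly ``None``,
    meaning no screening) in the personalized arm."""
    if arm == ARM_ANNUAL:
        return config.annual_arm_interval_years
    return config.strata[stratum].personalized_interval_years


def simulate_noncompliance_delay(
    n: int, sd_months: float, rng: np.random.Generator
) -> np.ndarray:
    """Half-normal noncompliance delays in years: ``|N(0, sd)|``.

    The protocol models noncompliance as a delay beyond the planned date, so
    the normal is truncated at zero.  With sd = 4 months this puts ~55% of
    mammograms within 3 months and ~87% within 6 months of schedule.
    """
    if not sd_months > 0:
        raise ValueError("sd_months must be > 0")
    return np.abs(rng.normal(0.0, sd_months / 12.0, size=n))


def simulate_first_planned_screen(
    entry: float,
    interval: float,
    config: TrialConfig,
    rng: Optional[np.random.Generator] = None,
    time_since_last: Optional[float] = None,
) -> float:
    """First planned screen: ``entry + max(0, interval - T_last)`` where
    ``T_last`` is the time since the woman's most recent pre-study mammogram
    (uniform on ``[0, last_premammogram_max_years]``; 0 by default, giving a
    first screen one full interval after entry)."""
    if interval is None:
        raise ValueError("no screening interval assigned")
    if time_since_last is None:
        if config.last_premammogram_max_years == 0.0 or rng is None:
            time_since_last = 0.0
        else:
            time_since_last = rng.uniform(0.0, config.last_premammogram_max_years)
    return entry + max(0.0, interval - time_since_last)


def simulate_screen_times(
    entry: float,
    interval: float,
    trial_end: float,
    config: TrialConfig,
    rng: Optional[np.random.Generator] = None,
    delays: Optional[Sequence[float]] = None,
    time_since_last: Optional[float] = None,
) -> np.ndarray:
    """Full schedule of actual screen times for one woman.

    Iterates ``actual_k = planned_k + delay_k``, ``planned_{k+1} = actual_k +
    interval`` and stops when an actual time exceeds ``trial_end`` (that
    screen does not occur).  ``delays`` may supply the noncompliance draws
    explicitly (deterministic scheduling, used by tests and the reference
    engine); otherwise they are drawn from ``rng``.
    """
    planned = simulate_first_planned_screen(entry, interval, config, rng, time_since_last)
    times = []
    delay_iter = iter(delays) if delays is not None else None
    while True:
        if delay_iter is not None:
            try:
                delay = float(next(delay_iter))
            except StopIteration as exc:
                raise ValueError("ran out of supplied delays before the horizon") from exc
        else:
            if rng is None:
                raise ValueError("either rng or delays must be supplied")
            delay = float(
                simulate_noncompliance_delay(1, config.noncompliance_sd_months, rng)[0]
            )
        actual = planned + delay
        if actual > trial_end:
            break
        times.append(actual)
        planned = actual + interval
    return np.asarray(times, dtype=float)


def exit_mammogram_time(
    entry: float, arm: int, stratum: int, config: TrialConfig
) -> Optional[float]:
    """Exit-mammogram rule: personalized-arm women with a no-screening
    recommendation get an end-of-study mammogram at ``trial_end`` if enrolled
    at least ``exit_mammogram_min_enrollment_years``; everyone else none."""
    if arm != ARM_PERSONALIZED:
        return None
    if config.strata[stratum].personalized_interval_years is not None:
        return None
    if config.trial_end_years - entry >= config.exit_mammogram_min_enrollment_years:
        return config.trial_end_years
    return None


def detect_cancer(
    t_detectable: float,
    t_clinical: float,
    screen_times: Sequence[float],
    exit_time: Optional[float],
    sensitivity: float,
    trial_end: float,
    rng: Optional[np.random.Generator] = None,
    screen_uniforms: Optional[Sequence[float]] = None,
    exit_uniform: Optional[float] = None,
    symptomatic_detection: str = "within_schedule",
) -> tuple[int, float]:
    """Detection outcome ``(mode, detection_time)`` for one woman.

    Scans scheduled screens in time order; each screen ``s`` with
    ``t_detectable <= s < t_clinical`` detects independently with probability
    ``sensitivity``.  Without a screen detection, the cancer surfaces
    symptomatically at ``t_clinical`` if the woman is still under observation
    (see module docstring); the exit mammogram, when present, is a final
    screening opportunity at trial end.
    """
    screen_times = np.asarray(screen_times, dtype=float)

    def _uniform(k: Optional[int] = None) -> float:
        if k is not None and screen_uniforms is not None:
            return float(screen_uniforms[k])
        if k is None and exit_uniform is not None:
            return float(exit_uniform)
        if rng is None:
            raise ValueError("either rng or explicit uniforms must be supplied")
        return float(rng.random())

    for k, s in enumerate(screen_times):
        if t_clinical <= s:
            break  # symptomatic before this screen; handled below
        if t_detectable <= s and _uniform(k) < sensitivity:
            return MODE_SCREEN, float(s)

    if symptomatic_detection == "within_schedule" and screen_times.size > 0:
        symptomatic_bound = float(screen_times[-1])
    else:
        symptomatic_bound = trial_end
    if t_clinical <= min(trial_end, symptomatic_bound):
        return MODE_CLINICAL, float(t_clinical)

    if exit_time is not None and t_detectable <= exit_time < t_clinical:
        if _uniform(None) < sensitivity:
            return MODE_SCREEN, float(exit_time)
    return MODE_NONE, math.nan


# ---------------------------------------------------------------------------
# vectorized engine


def _simulate_screening(
    cohort: Cohort, config: TrialConfig, rand: TrialRandomness
) -> tuple[ScreeningRealization, Outcome]:
    n = cohort.n
    t_end = config.trial_end_years
    k = rand.delays.shape[1] if n else max_screens(config)

    pint = np.array(
        [
            s.personalized_interval_years if s.personalized_interval_years is not None else np.inf
            for s in config.strata
        ]
    )
    sens = np.array([s.sensitivity for s in config.strata])[cohort.stratum] if n else np.empty(0)
    interval = np.where(
        cohort.arm == ARM_PERSONALIZED, pint[cohort.stratum], config.annual_arm_interval_years
    ) if n else np.empty(0)
    has_schedule = np.isfinite(interval)

    offset = np.maximum(0.0, interval - rand.time_since_last)
    first_planned = np.where(has_schedule, cohort.entry_time + offset, np.nan)
    # actual_0 = first_planned + delay_0; planned_{j+1} = actual_j + interval;
    # accumulated column by column in the same order as the per-woman loop so
    # both engines agree bitwise
    times = np.empty((n, k))
    planned = first_planned
    for j in range(k):
        actual = planned + rand.delays[:, j]
        times[:, j] = actual
        planned = actual + interval
    occurs = np.isfinite(times) & (times <= t_end)
    screen_times = np.where(occurs, times, np.nan)
    n_screens = occurs.sum(axis=1)
    masked = np.where(occurs, times, -np.inf)
    last_screen = np.where(n_screens > 0, masked.max(axis=1, initial=-np.inf), np.nan)

    t_det = cohort.t_detectable
    t_clin = cohort.t_clinical
    with np.errstate(invalid="ignore"):
        in_window = occurs & (t_det[:, None] <= screen_times) & (screen_times < t_clin[:, None])
    success = in_window & (rand.detect_u < sens[:, None])
    screen_detected = success.any(axis=1)
    first_hit = success.argmax(axis=1)
    screen_det_time = np.where(
        screen_detected, screen_times[np.arange(n), first_hit] if n else np.nan, np.nan
    )

    if config.symptomatic_detection == "within_schedule":
        symptomatic_bound = np.where(has_schedule & (n_screens > 0), last_screen, t_end)
    else:
        symptomatic_bound = np.full(n, t_end)
    clinical = ~screen_detected & (t_clin <= np.minimum(t_end, symptomatic_bound))

    eligible = exit_mammogram_eligible(cohort, config)
    exit_occurs = eligible & ~screen_detected & ~clinical
    exit_detects = (
        exit_occurs & (t_det <= t_end) & (t_clin > t_end) & (rand.exit_u < sens)
    )

    detected = screen_detected | clinical | exit_detects
    mode = np.full(n, MODE_NONE, dtype=np.int8)
    mode[screen_detected | exit_detects] = MODE_SCREEN
    mode[clinical] = MODE_CLINICAL
    detection_time = np.where(
        screen_detected, screen_det_time, np.where(clinical, t_clin, np.where(exit_detects, t_end, np.nan))
    )

    # mammograms actually performed: schedule screens up to detection, plus
    # the exit mammogram when it occurs
    cutoff = np.where(detected, detection_time, np.inf)
    with np.errstate(invalid="ignore"):
        n_mammo = (occurs & (screen_times <= cutoff[:, None])).sum(axis=1) + exit_occurs

    first_screen_time = np.where(
        n_screens > 0, screen_times[:, 0] if k else np.nan, np.where(exit_occurs, t_end, np.nan)
    )
    with np.errstate(invalid="ignore"):
        at_first = (mode == MODE_SCREEN) & (detection_time == first_screen_time)

    screening = ScreeningRealization(
        first_planned=first_planned,
        screen_times=screen_times,
        n_screens_schedule=n_screens.astype(int),
        last_screen_time=last_screen,
        exit_mammogram_time=np.where(exit_occurs, t_end, np.nan),
        n_mammograms=n_mammo.astype(int),
    )
    outcome = Outcome(
        detected=detected,
        mode=mode,
        detection_time=detection_time,
        detected_at_first_screen=at_first,
        prevalent_at_detection=detected & cohort.prevalent,
    )
    return screening, outcome


def exit_mammogram_eligible(cohort: Cohort, config: TrialConfig) -> np.ndarray:
    """Boolean mask of women covered by the exit-mammogram rule (personalized
    arm, no-screening stratum, enrolled long enough), irrespective of whether
    the mammogram ends up happening."""
    pint_none = np.array(
        [s.personalized_interval_years is None for s in config.strata]
    )
    return (
        (cohort.arm == ARM_PERSONALIZED)
        & pint_none[cohort.stratum]
        & (config.trial_end_years - cohort.entry_time >= config.exit_mammogram_min_enrollment_years)
    )


def run_single_trial(
    config: TrialConfig,
    rng: Union[int, np.random.SeedSequence, np.random.Generator, None] = None,
) -> TrialData:
    """Simulate one complete virtual trial (vectorized engine).

    Deterministic for a fixed seed: the draw order is cohort randomness
    (entry, arms, strata, natural history) followed by screening randomness
    (see :func:`draw_screening_randomness`).
    """
    rng = as_generator(rng if rng is not None else config.seed)
    cohort = simulate_cohort(config, rng)
    rand = draw_screening_randomness(cohort.n, config, rng)
    screening, outcome = _simulate_screening(cohort, config, rand)
    return TrialData(cohort, screening, outcome, config.trial_end_years, config)
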