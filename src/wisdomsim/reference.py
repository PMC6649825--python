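"""Straightforward per-woman event-loop implementation of the trial engine.

This mirrors :func:`wisdomsim.screening.run_single_trial` woman by woman
using the scalar operations, consuming the same pre-drawn randomness arrays.
It is deliberately simple and slow, and serves as the validation oracle for
the vectorized engine: both must produce identical :class:`TrialData` for
the same seed.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .config import TrialConfig
from .cohort import Cohort, simulate_cohort
from .screening import (
    MODE_CLINICAL,
    MODE_NONE,
    MODE_SCREEN,
    Outcome,
    ScreeningRealization,
    TrialData,
    TrialRandomness,
    as_generator,
    assigned_interval,
    detect_cancer,
    draw_screening_randomness,
    exit_mammogram_time,
    simulate_first_planned_screen,
    simulate_screen_times,
)

__all__ = ["run_single_trial_reference", "simulate_screening_reference"]


def simulate_screening_reference(
    cohort: Cohort, config: TrialConfig, rand: TrialRandomness
) -> tuple[ScreeningRealization, Outcome]:
    n = cohort.n
    k = rand.delays.shape[1]
    t_end = config.trial_end_years

    first_planned = np.full(n, np.nan)
    screen_times = np.full((n, k), np.nan)
    n_screens = np.zeros(n, dtype=int)
    last_screen = np.full(n, np.nan)
    exit_time_arr = np.full(n, np.nan)
    n_mammo = np.zeros(n, dtype=int)
    detected = np.zeros(n, dtype=bool)
    mode = np.full(n, MODE_NONE, dtype=np.int8)
    det_time = np.full(n, np.nan)
    at_first = np.zeros(n, dtype=bool)

    for i in range(n):
        arm = int(cohort.arm[i])
        stratum = int(cohort.stratum[i])
        entry = float(cohort.entry_time[i])
        interval = assigned_interval(arm, stratum, config)
        sensitivity = config.strata[stratum].sensitivity

        if interval is not None:
            first_planned[i] = simulate_first_planned_screen(
                entry, interval, config, time_since_last=float(rand.time_since_last[i])
            )
            screens = simulate_screen_times(
                entry,
                interval,
                t_end,
                config,
                delays=rand.delays[i],
                time_since_last=float(rand.time_since_last[i]),
            )
        else:
            screens = np.empty(0)
        n_screens[i] = screens.size
        screen_times[i, : screens.size] = screens
        if screens.size:
            last_screen[i] = screens[-1]

        exit_rule_time = exit_mammogram_time(entry, arm, stratum, config)

        m, t = detect_cancer(
            float(cohort.t_detectable[i]),
            float(cohort.t_clinical[i]),
            screens,
            exit_rule_time,
            sensitivity,
            t_end,
            screen_uniforms=rand.detect_u[i],
            exit_uniform=float(rand.exit_u[i]),
            symptomatic_detection=config.symptomatic_detection,
        )
        mode[i] = m
        detected[i] = m != MODE_NONE
        det_time[i] = t

        # the exit mammogram happens whenever the rule applies and the woman
        # reaches trial end undiagnosed
        exit_occurs = exit_rule_time is not None and not (
            m == MODE_SCREEN and t < t_end or m == MODE_CLINICAL
        )
        if exit_occurs:
            exit_time_arr[i] = exit_rule_time

        # mammograms performed: schedule screens up to detection, plus exit
        count = int(np.sum(screens <= t)) if detected[i] else screens.size
        n_mammo[i] = count + int(exit_occurs)

        if m == MODE_SCREEN:
            first_mammo = screens[0] if screens.size else exit_rule_time
            at_first[i] = first_mammo is not None and t == first_mammo

    screening = ScreeningRealization(
        first_planned=first_planned,
        screen_times=screen_times,
        n_screens_schedule=n_screens,
        last_screen_time=last_screen,
        exit_mammogram_time=exit_time_arr,
        n_mammograms=n_mammo,
    )
    outcome = Outcome(
        detected=detected,
        mode=mode,
        detection_time=det_time,
        detected_at_first_screen=at_first,
        prevalent_at_detection=detected & cohort.prevalent,
    )
    return screening, outcome


def run_single_trial_reference(
    config: TrialConfig,
    rng: Union[int, np.random.SeedSequence, np.random.Generator, None] = None,
) -> TrialData:
    """Event-loop counterpart of :func:`wisdomsim.screening.run_single_trial`
    under the identical seed policy."""
    rng = as_generator(rng if rng is not None else config.seed)
    cohort = simulate_cohort(config, rng)
    rand = draw_screening_randomness(cohort.n, config, rng)
    screening, outcome = simulate_screening_reference(cohort, config, rand)
    return TrialData(cohort, screening, outcome, config.trial_end_years, config)
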