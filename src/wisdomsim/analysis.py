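"""Candidate primary-analysis estimators on one simulated trial.

Four ways of counting events and person-time are implemented:

``total_time``
    exposure from study entry to detection or trial end; every detected
    cancer counts.
``complete_cycles``
    exposure and events only within complete screening cycles: a screened
    woman contributes from entry to her detection if she is diagnosed no
    later than her last scheduled screen, otherwise to her last realized
    screen (zero screens, zero contribution).  Personalized-arm women with
    a no-screening recommendation are included only if covered by the
    exit-mammogram rule; their single cycle runs from entry to the exit
    mammogram at trial end.
``complete_cycles_entry_mammo``
    complete cycles with prevalent cancers excluded from the event counts in
    both arms — analytically equivalent to giving every screened woman a
    study entry mammogram (which is also added to the mammogram tally).
    Excluded women keep contributing their complete-cycles exposure.
``hybrid``
    complete cycles for the strata that are screened in the personalized
    arm, total trial time for the no-screening stratum (both arms) — the
    combination adopted for the trial's primary analysis.

Hazards are events per 100 person-years.  The stratum risk difference is
``R = hazard_annual - hazard_personalized``; ``R < 0`` means the annual arm
shows the lower hazard.  Overall results are reported both pooled (summed
events and exposure per arm) and with inverse-exposure stratum weighting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ARM_ANNUAL, ARM_PERSONALIZED, TrialConfig
from .screening import MODE_CLINICAL, MODE_SCREEN, TrialData, exit_mammogram_eligible

__all__ = [
    "METHODS",
    "StratumArmSummary",
    "AnalysisResult",
    "exposure_total_time",
    "exposure_complete_cycles",
    "apply_entry_mammogram_variant",
    "summarize_trial",
    "analyze_trial",
]

METHODS = ("total_time", "complete_cycles", "complete_cycles_entry_mammo", "hybrid")

ARM_LABELS = {ARM_ANNUAL: "annual", ARM_PERSONALIZED: "personalized"}

# field order in the numeric per-method summary arrays, shape (n_strata, 2, NF)
F_EVENTS = 0
F_EVENTS_SCREEN = 1
F_EVENTS_CLINICAL = 2
F_EVENTS_PREVALENT = 3
F_EXPOSURE = 4
F_N_INCLUDED = 5
F_N_MAMMOGRAMS = 6
NF = 7


# ---------------------------------------------------------------------------
# per-woman exposure rules


def exposure_total_time(entry_time, detection_time, trial_end):
    """Person-years under total-trial-time accounting: entry to detection
    (NaN detection = undetected) or to trial end."""
    entry_time = np.asarray(entry_time, dtype=float)
    detection_time = np.asarray(detection_time, dtype=float)
    return np.where(np.isfinite(detection_time), detection_time, trial_end) - entry_time


def exposure_complete_cycles(
    entry_time,
    detection_time,
    last_screen_time,
    screened,
    exit_eligible,
    trial_end,
):
    """Complete-screening-cycles accounting.

    Returns ``(included, exposure, event_counted)``.  ``last_screen_time``
    is NaN for women without a realized screen.  ``screened`` marks women
    with a screening schedule (both arms except the personalized-arm
    no-screening stratum); ``exit_eligible`` marks women covered by the
    exit-mammogram rule.
    """
    entry_time = np.asarray(entry_time, dtype=float)
    detection_time = np.asarray(detection_time, dtype=float)
    last_screen_time = np.asarray(last_screen_time, dtype=float)
    screened = np.asarray(screened, dtype=bool)
    exit_eligible = np.asarray(exit_eligible, dtype=bool)
    detected = np.isfinite(detection_time)
    has_screen = np.isfinite(last_screen_time)

    with np.errstate(invalid="ignore"):
        counted_screened = screened & detected & (detection_time <= last_screen_time)
    counted_unscreened = ~screened & detected & exit_eligible
    event_counted = counted_screened | counted_unscreened

    exposure_screened = np.where(
        counted_screened,
        detection_time - entry_time,
        np.where(has_screen, last_screen_time - entry_time, 0.0),
    )
    exposure_unscreened = np.where(
        exit_eligible,
        np.where(detected, detection_time, trial_end) - entry_time,
        0.0,
    )
    exposure = np.where(screened, exposure_screened, exposure_unscreened)
    included = np.where(screened, has_screen, exit_eligible)
    return included, exposure, event_counted


def apply_entry_mammogram_variant(trialdata: TrialData) -> TrialData:
    """Variant in which every screened woman also receives a study entry
    mammogram: prevalent cancers are excluded from event counts in both arms
    (the women keep contributing exposure as non-cases), and one entry
    mammogram per screened woman is added to the mammogram tally."""
    screened = _screened_mask(trialdata)
    screening = dataclasses.replace(
        trialdata.screening,
        n_mammograms=trialdata.screening.n_mammograms + screened.astype(int),
    )
    out = dataclasses.replace(trialdata, screening=screening)
    out.entry_mammogram_variant = True  # type: ignore[attr-defined]
    return out


def _screened_mask(td: TrialData) -> np.ndarray:
    pint_none = np.array(
        [s.personalized_interval_years is None for s in td.config.strata]
    )
    return ~((td.cohort.arm == ARM_PERSONALIZED) & pint_none[td.cohort.stratum])


# ---------------------------------------------------------------------------
# trial-level summaries


def summarize_trial(td: TrialData, config: Optional[TrialConfig] = None) -> dict[str, np.ndarray]:
    """Numeric per-method summaries, shape ``(n_strata, 2 arms, NF fields)``.

    This is the fast path used by the replication driver; ``analyze_trial``
    wraps the same numbers in labelled results.
    """
    config = config or td.config
    n_strata = config.n_strata
    cohort, outcome, screening = td.cohort, td.outcome, td.screening
    screened = _screened_mask(td)
    exit_elig = exit_mammogram_eligible(cohort, config)
    detected = outcome.detected
    det_time = outcome.detection_time
    entry = cohort.entry_time
    trial_end = td.trial_end

    expo_tt = exposure_total_time(entry, det_time, trial_end)
    incl_cc, expo_cc, counted_cc = exposure_complete_cycles(
        entry, det_time, screening.last_screen_time, screened, exit_elig, trial_end
    )
    counted_c = counted_cc & ~cohort.prevalent

    idx = cohort.stratum.astype(int) * 2 + (cohort.arm == ARM_PERSONALIZED).astype(int)
    nbin = 2 * n_strata

    def acc(values) -> np.ndarray:
        return np.bincount(idx, weights=values, minlength=nbin).reshape(n_strata, 2)

    is_screen = outcome.mode == MODE_SCREEN
    is_clin = outcome.mode == MODE_CLINICAL
    prev = cohort.prevalent
    mammo = screening.n_mammograms
    entry_mammo = bool(getattr(td, "entry_mammogram_variant", False))

    def pack(event_mask, exposure, included, extra_mammo=0) -> np.ndarray:
        out = np.empty((n_strata, 2, NF))
        out[:, :, F_EVENTS] = acc(event_mask)
        out[:, :, F_EVENTS_SCREEN] = acc(event_mask & is_screen)
        out[:, :, F_EVENTS_CLINICAL] = acc(event_mask & is_clin)
        out[:, :, F_EVENTS_PREVALENT] = acc(event_mask & prev)
        out[:, :, F_EXPOSURE] = acc(exposure)
        out[:, :, F_N_INCLUDED] = acc(included)
        out[:, :, F_N_MAMMOGRAMS] = acc(mammo + extra_mammo)
        return out

    ones = np.ones(td.n, dtype=bool)
    summaries = {
        "total_time": pack(detected, expo_tt, ones),
        "complete_cycles": pack(counted_cc, expo_cc, incl_cc),
        "complete_cycles_entry_mammo": pack(
            counted_c, expo_cc, incl_cc, extra_mammo=0 if entry_mammo else screened.astype(int)
        ),
    }
    # hybrid: complete cycles for screened strata, total time for the
    # no-screening stratum (both arms)
    hybrid = summaries["complete_cycles"].copy()
    for s, spec in enumerate(config.strata):
        if spec.personalized_interval_years is None:
            hybrid[s] = summaries["total_time"][s]
    summaries["hybrid"] = hybrid
    return summaries


def detection_mode_counts(td: TrialData) -> np.ndarray:
    """Counts by stratum and arm of prevalent-detected, screen-detected,
    clinically detected and total detected cancers (shape ``(S, 2, 4)``)."""
    config = td.config
    n_strata = config.n_strata
    idx = td.cohort.stratum.astype(int) * 2 + (td.cohort.arm == ARM_PERSONALIZED).astype(int)

    def acc(mask) -> np.ndarray:
        return np.bincount(idx, weights=mask, minlength=2 * n_strata).reshape(n_strata, 2)

    out = np.empty((n_strata, 2, 4))
    out[:, :, 0] = acc(td.outcome.prevalent_at_detection)
    out[:, :, 1] = acc(td.outcome.mode == MODE_SCREEN)
    out[:, :, 2] = acc(td.outcome.mode == MODE_CLINICAL)
    out[:, :, 3] = acc(td.outcome.detected)
    return out


# ---------------------------------------------------------------------------
# labelled results


@dataclass
class StratumArmSummary:
    stratum: str
    arm: str
    events: float
    events_screen: float
    events_clinical: float
    events_prevalent: float
    exposure: float
    hazard: float
    n_women_included: float
    n_mammograms: float
    degenerate: bool


@dataclass
class AnalysisResult:
    """One estimator applied to one trial."""

    method: str
    summaries: list[StratumArmSummary]
    risk_difference: "pd.Series"  # per stratum, annual minus personalized
    overall_hazard_annual: float
    overall_hazard_personalized: float
    overall_risk_difference: float  # pooled events/exposure
    overall_risk_difference_weighted: float  # inverse-exposure stratum weights

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([dataclasses.asdict(s) for s in self.summaries])
        frame.insert(0, "method", self.method)
        frame["risk_difference"] = frame["stratum"].map(self.risk_difference)
        return frame


def hazard_per_100py(events: np.ndarray, exposure: np.ndarray) -> np.ndarray:
    """Events per 100 person-years; defined as 0 where exposure is 0 (the
    degenerate case is flagged separately)."""
    events = np.asarray(events, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    return np.divide(
        100.0 * events, exposure, out=np.zeros_like(events, dtype=float), where=exposure > 0
    )


def overall_risk_differences(summary: np.ndarray) -> tuple[float, float, float, float]:
    """(hazard_annual, hazard_personalized, pooled R, weighted R) from one
    ``(S, 2, NF)`` method summary.  Strata with zero exposure in either arm
    get weight zero in the weighted combination."""
    ev = summary[:, :, F_EVENTS]
    ex = summary[:, :, F_EXPOSURE]
    hz_a = float(hazard_per_100py(ev[:, 0].sum(), ex[:, 0].sum()))
    hz_p = float(hazard_per_100py(ev[:, 1].sum(), ex[:, 1].sum()))
    pooled = hz_a - hz_p

    ok = (ex[:, 0] > 0) & (ex[:, 1] > 0)
    if ok.any():
        rs = hazard_per_100py(ev[:, 0], ex[:, 0]) - hazard_per_100py(ev[:, 1], ex[:, 1])
        w = np.where(ok, 1.0 / np.where(ok, ex.sum(axis=1), 1.0), 0.0)
        weighted = float(np.sum(w * rs) / np.sum(w))
    else:
        weighted = 0.0
    return hz_a, hz_p, pooled, weighted


def analyze_trial(td: TrialData, config: Optional[TrialConfig] = None) -> list[AnalysisResult]:
    """All four estimators on one trial, in labelled form."""
    config = config or td.config
    base = summarize_trial(td, config)
    names = config.stratum_names
    results = []
    for method in METHODS:
        summary = base[method]
        ev = summary[:, :, F_EVENTS]
        ex = summary[:, :, F_EXPOSURE]
        hz = hazard_per_100py(ev, ex)
        rows = []
        for s, name in enumerate(names):
            for a, arm_label in ARM_LABELS.items():
                rows.append(
                    StratumArmSummary(
                        stratum=name,
                        arm=arm_label,
                        events=summary[s, a, F_EVENTS],
                        events_screen=summary[s, a, F_EVENTS_SCREEN],
                        events_clinical=summary[s, a, F_EVENTS_CLINICAL],
                        events_prevalent=summary[s, a, F_EVENTS_PREVALENT],
                        exposure=ex[s, a],
                        hazard=hz[s, a],
                        n_women_included=summary[s, a, F_N_INCLUDED],
                        n_mammograms=summary[s, a, F_N_MAMMOGRAMS],
                        degenerate=bool(ex[s, a] == 0),
                    )
                )
        risk_diff = pd.Series(hz[:, 0] - hz[:, 1], index=list(names), name="risk_difference")
        hz_a, hz_p, pooled, weighted = overall_risk_differences(summary)
        results.append(
            AnalysisResult(
                method=method,
                summaries=rows,
                risk_difference=risk_diff,
                overall_hazard_annual=hz_a,
                overall_hazard_personalized=hz_p,
                overall_risk_difference=pooled,
                overall_risk_difference_weighted=weighted,
            )
        )
    return results
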