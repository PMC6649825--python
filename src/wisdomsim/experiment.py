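"""Replication driver: many virtual trials, Monte Carlo operating
characteristics, and the two report tables.

Replicates are seeded from a master seed through ``numpy``'s
``SeedSequence.spawn``, so a run is reproducible and prefix-stable:
replicates ``1..k`` are identical regardless of the total replicate count.

For every estimator the driver tracks, per stratum and overall, the mean
event counts (by detection mode), exposure, hazard, and the distribution of
the per-replicate risk difference ``R = hazard_annual - hazard_personalized``:
its mean, 2.5/97.5 percentile interval, and ``P(R < 0)``, the fraction of
replicates favoring the annual arm (replicates with ``R = 0`` exactly are
split evenly between the two sides).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .analysis import (
    F_EVENTS,
    F_EVENTS_CLINICAL,
    F_EVENTS_PREVALENT,
    F_EVENTS_SCREEN,
    F_EXPOSURE,
    F_N_MAMMOGRAMS,
    METHODS,
    detection_mode_counts,
    hazard_per_100py,
    overall_risk_differences,
    summarize_trial,
)
from .config import TrialConfig
from .screening import run_single_trial

__all__ = ["AggregateResult", "run_experiment", "make_detection_table", "make_analysis_table"]

logger = logging.getLogger("wisdomsim")

OVERALL_POOLED = "overall"
OVERALL_WEIGHTED = "overall_weighted"


@dataclass
class AggregateResult:
    """Across-replicate aggregate of a replicated virtual trial."""

    config: TrialConfig
    n_replicates: int
    #: per method: replicate summaries, shape (R, n_strata, 2 arms, NF)
    replicate_summaries: dict[str, np.ndarray]
    #: replicate detection-mode counts (prevalent/screen/clinical/total),
    #: shape (R, n_strata, 2, 4)
    replicate_mode_counts: np.ndarray
    #: per method: replicate risk differences per stratum plus the two
    #: overall conventions, columns = strata + [overall, overall_weighted]
    replicate_risk: dict[str, pd.DataFrame]

    # -- derived ---------------------------------------------------------

    def mean_summary(self, method: str) -> np.ndarray:
        return self.replicate_summaries[method].mean(axis=0)

    def risk_table(self) -> pd.DataFrame:
        """Tidy frame: method, stratum, mean risk difference, percentile CI,
        P(R<0)."""
        rows = []
        for method in METHODS:
            risk = self.replicate_risk[method]
            for column in risk.columns:
                values = risk[column].to_numpy()
                rows.append(
                    {
                        "method": method,
                        "stratum": column,
                        "mean_risk_difference": values.mean(),
                        "ci_low": float(np.percentile(values, 2.5)),
                        "ci_high": float(np.percentile(values, 97.5)),
                        "p_R_lt_0": p_below_zero(values),
                    }
                )
        return pd.DataFrame(rows)

    def p_r_lt_0(self, method: str, stratum: str = OVERALL_POOLED) -> float:
        return p_below_zero(self.replicate_risk[method][stratum].to_numpy())

    def mean_mammograms(self) -> np.ndarray:
        """Mean realized mammogram counts by stratum and arm (S, 2)."""
        return self.mean_summary("total_time")[:, :, F_N_MAMMOGRAMS]


def p_below_zero(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan")
    return float(((values < 0).sum() + 0.5 * (values == 0).sum()) / values.size)


def run_experiment(
    config: TrialConfig,
    n_replicates: int,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> AggregateResult:
    """Simulate and analyze ``n_replicates`` independent virtual trials."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)

    n_strata = config.n_strata
    sums = {m: np.empty((n_replicates, n_strata, 2, 7)) for m in METHODS}
    modes = np.empty((n_replicates, n_strata, 2, 4))
    risk_cols = list(config.stratum_names) + [OVERALL_POOLED, OVERALL_WEIGHTED]
    risk = {m: np.empty((n_replicates, len(risk_cols))) for m in METHODS}

    t0 = time.perf_counter()
    for r, child in enumerate(children):
        td = run_single_trial(config, np.random.default_rng(child))
        summaries = summarize_trial(td, config)
        modes[r] = detection_mode_counts(td)
        for m in METHODS:
            summary = summaries[m]
            sums[m][r] = summary
            hz = hazard_per_100py(summary[:, :, F_EVENTS], summary[:, :, F_EXPOSURE])
            _, _, pooled, weighted = overall_risk_differences(summary)
            risk[m][r, :n_strata] = hz[:, 0] - hz[:, 1]
            risk[m][r, n_strata] = pooled
            risk[m][r, n_strata + 1] = weighted
        if (r + 1) % 200 == 0:
            logger.info("replicate %d/%d (%.1fs)", r + 1, n_replicates, time.perf_counter() - t0)
    logger.info(
        "experiment done: %d replicates of %d women in %.1fs",
        n_replicates,
        config.n_total,
        time.perf_counter() - t0,
    )
    return AggregateResult(
        config=config,
        n_replicates=n_replicates,
        replicate_summaries=sums,
        replicate_mode_counts=modes,
        replicate_risk={m: pd.DataFrame(risk[m], columns=risk_cols) for m in METHODS},
    )


# ---------------------------------------------------------------------------
# report tables


def _screening_group_label(interval: Optional[float]) -> str:
    if interval is None:
        return "No screening at this time"
    if interval == 0.5:
        return "Every 6 months"
    if interval == 1.0:
        return "Annual"
    if interval == 2.0:
        return "Biennial"
    return f"Every {interval:g} y"


def _stratum_order(config: TrialConfig) -> list[int]:
    """Highest to lowest risk, as in the report tables."""
    return sorted(range(config.n_strata), key=lambda s: -config.strata[s].annual_hazard)


def make_detection_table(agg: AggregateResult) -> pd.DataFrame:
    """Mean numbers of detected cancers by mode of detection, risk group and
    arm.  Rows are the personalized-arm screening groups (highest risk
    first) plus an all-groups total; the prevalent column is the subset of
    detected cancers already screen-detectable at study entry."""
    config = agg.config
    mode_mean = agg.replicate_mode_counts.mean(axis=0)  # (S, 2, 4)
    order = _stratum_order(config)
    columns = pd.MultiIndex.from_product(
        [["prevalent", "screen_detected", "clinically_detected", "total"], ["personalized", "annual"]]
    )
    rows, index = [], []
    for s in order:
        index.append(_screening_group_label(config.strata[s].personalized_interval_years))
        rows.append(
            [mode_mean[s, arm, f] for f in range(4) for arm in (1, 0)]
        )
    index.append("All risk groups")
    total = mode_mean.sum(axis=0)
    rows.append([total[arm, f] for f in range(4) for arm in (1, 0)])
    return pd.DataFrame(rows, index=index, columns=columns)


def make_analysis_table(agg: AggregateResult) -> pd.DataFrame:
    """Expected trial results by analysis method: events, exposure, hazard
    rate, mean risk difference with 95% percentile interval, P(R<0), and
    mammogram counts, per stratum (highest risk first) and overall."""
    config = agg.config
    order = _stratum_order(config)
    names = config.stratum_names
    risk_table = agg.risk_table().set_index(["method", "stratum"])
    rows = []
    for method in METHODS:
        mean = agg.mean_summary(method)
        for s in order + [None]:
            if s is None:
                stratum = "Overall"
                ev = mean[:, :, F_EVENTS].sum(axis=0)
                ex = mean[:, :, F_EXPOSURE].sum(axis=0)
                mam = mean[:, :, F_N_MAMMOGRAMS].sum(axis=0)
                risk_row = risk_table.loc[(method, OVERALL_POOLED)]
            else:
                stratum = names[s]
                ev = mean[s, :, F_EVENTS]
                ex = mean[s, :, F_EXPOSURE]
                mam = mean[s, :, F_N_MAMMOGRAMS]
                risk_row = risk_table.loc[(method, names[s])]
            hz = hazard_per_100py(ev, ex)
            rows.append(
                {
                    "method": method,
                    "stratum": stratum,
                    "events_personalized": ev[1],
                    "events_annual": ev[0],
                    "exposure_personalized": ex[1],
                    "exposure_annual": ex[0],
                    "hazard_personalized": hz[1],
                    "hazard_annual": hz[0],
                    "mean_risk_difference": risk_row["mean_risk_difference"],
                    "ci_low": risk_row["ci_low"],
                    "ci_high": risk_row["ci_high"],
                    "p_R_lt_0": risk_row["p_R_lt_0"],
                    "mammograms_personalized": mam[1],
                    "mammograms_annual": mam[0],
                }
            )
    return pd.DataFrame(rows)
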