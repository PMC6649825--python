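# Methods

This note documents the model implemented in `wisdomsim`, the conventions
chosen where the trial design leaves details open, and what conclusions the
simulation does and does not support.

## The estimand and why simulation is needed

WISDOM compares annual mammography against risk-stratified screening on a
short-horizon safety endpoint: the rate of stage IIB-or-higher cancers per
100 person-years, compared between arms as a risk difference
*R = h_annual − h_personalized* against a noninferiority margin of 0.05%
absolute. Both arms face identical cancer incidence by randomization, so
any systematic deviation of *R* from zero under a correctly specified null
is ascertainment bias created by the observation process — who gets
screened when, and which cancers the trial ever sees. The simulator
generates the full observation process so that the bias of a candidate
estimator can be read off as *P(R < 0)*, the fraction of replicate trials
in which the annual arm shows the lower hazard (0.5 = unbiased; ties split
evenly).

## Cohort and natural history

All times are in years from trial start; per-woman event times are
absolute. Defaults (all configurable through `TrialConfig` / YAML):

| parameter | default | notes |
|---|---|---|
| cohort size | 65 000 | randomized cohort only |
| accrual | 5 000 / 25 000 / 20 000 / 15 000 in years 1–4 | uniform within each year |
| randomization | fair coin per woman | per-arm counts vary binomially; forced balance optional |
| strata (lowest→highest) | 28.9 / 40.4 / 28.2 / 2.5 % | multinomial, independent of arm |
| annual onset hazard λ_s | 0.0198 / 0.0414 / 0.0774 / 0.2808 % | exponential rate on the probability scale; at these magnitudes rate-vs-probability conversion differs by <0.03% |
| sojourn time | exponential, median 18 months | detectable → symptomatic |
| trial horizon | 4.5 years | |
| noncompliance | half-normal, σ = 4 months | P(delay<3 mo)=0.55, P(<6 mo)=0.87 |
| personalized intervals | none / 2 / 1 / 0.5 years | annual arm: 1 year for everyone |
| per-screen sensitivity | 1.0 (93/86/76/86% variant) | independent Bernoulli per screen |

**Onset clock (prevalence).** The default `prevalence_model="incidence"`
draws the onset exponential in *calendar* time from trial start. A woman
accrued at year 3 whose onset fell at year 1.5 enters the trial with a
prevalent, screen-detectable cancer; one whose cancer would already have
surfaced symptomatically before entry is ineligible for a screening trial
and participates cancer-free. Prevalence is therefore *emergent* and scales
with the stratum hazard and with accrual time — about 0.07% of the cohort,
concentrated in the higher-hazard strata, which is what makes the entry
bias risk-dependent. The alternative `prevalence_model="seeded"` flags
prevalent cancers by a flat Bernoulli draw (0.05% default) at entry and
starts the onset clock at entry; it produces stratum-independent prevalence
and is retained for sensitivity analyses. By exponential memorylessness the
two models are identical for incident (post-entry) disease.

**Prevalent sojourn.** A prevalent cancer's clinical time is its onset plus
a full sojourn draw; conditional on being prevalent this leaves an
exponential residual sojourn from entry (memorylessness), so no separate
residual draw is needed.

## Screening process

The first on-study screen is planned at
`entry + max(0, interval − T_last)`, where `T_last` is the time since the
woman's last pre-study mammogram. The default sets `T_last = 0`: the first
screen comes one full interval after entry, which matches the design's
per-woman mammogram counts (≈1.31 screens/woman in annually screened
strata, ≈0.53 under biennial screening, and a 6-monthly:annual imaging
ratio of ≈1.9). A uniform draw on `[0, last_premammogram_max_years]` is
available for studying entry-timing conventions. Each planned screen slips
by an independent half-normal delay, and the next screen is planned one
interval after the *actual* date, so delays compound; a screen whose actual
date passes the horizon does not occur. The highest-risk stratum's
"mammogram + MRI" recommendation is modelled as one combined
mammographic-equivalent imaging event per 6-month cycle.

**Detection.** Every screen falling in `[T_det, T_clin)` detects
independently with the stratum sensitivity; the first success is a screen
detection and stops further screening. An undetected cancer is clinically
detected at `T_clin` *while the woman is within her screening schedule*
(`symptomatic_detection="within_schedule"`): a cancer surfacing in the tail
between her final scheduled screen and trial end is not ascertained by the
trial. Women with no schedule — the personalized no-screening stratum, or
women whose first screen never fits before the horizon — can present
symptomatically any time up to trial end. The alternative
`"until_trial_end"` observes all symptomatic cancers to the horizon. The
within-schedule convention is what makes total-trial-time accounting
exit-biased in an asymmetric way and is the reading under which the
complete-cycles estimator's event exclusions are exactly the
beyond-last-screen detections.

**Exit mammogram.** Personalized-arm no-screening women enrolled at least
2 years receive a final mammogram at trial end unless already diagnosed; it
counts toward mammogram totals and can convert an otherwise-missed latent
cancer into a screen detection.

**Schedule vs mammogram counts.** The schedule is realized to the horizon
and defines cycle boundaries for the analysis; a woman's *performed*
mammograms stop at her detection. With ~86 detections among 65 000 women
the distinction is invisible in mammogram totals but keeps the two
bookkeeping roles separate.

## Estimators

Per stratum × arm, events and person-years are accumulated under:

* **total_time** — entry → detection or trial end; all detections count.
* **complete_cycles** — screened women: entry → detection if diagnosed no
  later than their last scheduled screen, else entry → last realized screen
  (zero screens ⇒ excluded). No-screening personalized women: included only
  if covered by the exit-mammogram rule; their single cycle is entry →
  trial end. Event containment (every complete-cycles event is a
  total-time event) and exposure dominance (cycle exposure ≤ total
  exposure, woman by woman) hold by construction and are property-tested.
* **complete_cycles_entry_mammo** — complete cycles with prevalent
  cancers' events removed in both arms; the women continue to contribute
  their complete-cycles exposure as non-cases, mirroring a design in which
  an entry mammogram removes prevalent disease from follow-up. One entry
  mammogram per screened woman is added to the imaging tally.
* **hybrid** — per-stratum summaries taken from complete cycles for the
  strata screened in the personalized arm and from total time for the
  no-screening stratum (both arms), then combined like any other method.

Hazards are 100 × events / exposure; a zero-exposure stratum-arm cell is
reported as hazard 0 with a degenerate flag and is excluded (weight 0) from
weighted combinations. Overall results are computed two ways: *pooled*
(summing events and exposure per arm — this is what the per-method overall
rows report, and what the headline overall P(R<0) values use) and
*inverse-exposure weighted* (R_overall = Σ w_s R_s / Σ w_s with
w_s = 1/(exposure_s,annual + exposure_s,personalized)), which counteracts
the over-representation of long-cycle strata in complete-cycle exposure.
Both are recorded per replicate.

## Replication and uncertainty

`run_experiment` spawns one independent substream per replicate from the
master seed (`SeedSequence.spawn`), making runs reproducible and
prefix-stable. Across replicates it reports means, the 2.5th/97.5th
percentiles of the replicate risk-difference distribution (the "95% CI" of
the report tables — an across-replicate percentile interval, not a
within-trial interval), and P(R < 0). Monte Carlo error on a probability is
≈ √(p(1−p)/R): ±0.016 at 1000 replicates. Problem sizes used by the
shipped checks: the test suite's end-to-end checks run 1000 replicates of
the full 65 000-woman design (~1 minute), and `scripts/acceptance.py`
defaults to 1500; smaller scaled cohorts (650–13 000 women) back the
unit-level and symmetry tests, whose properties are size-invariant.

## Validation

* **Dual engines.** The vectorized engine and a deliberately simple
  per-woman event loop (`wisdomsim.reference`) consume identical pre-drawn
  randomness and must agree bitwise on every cohort, schedule and outcome
  field; this is asserted across seeds and configuration variants.
* **Distributional oracles.** Exponential rate recovery within 1% at 10⁶
  draws; sojourn median 18 months; half-normal calibration (55%/87% within
  3/6 months); chi-square and KS tests at α = 0.001; emergent prevalence
  against closed-form quadrature over the accrual pattern.
* **No-bias construction.** With every personalized interval set equal to
  the annual interval the arms are exchangeable, so P(R < 0) must lie at
  0.5 (checked within ±0.05 at 800 replicates) and the percentile interval
  must cover 0. The identically screened elevated stratum provides the same
  check inside the default design.

## What the generator does and does not emulate

The natural-history model is deliberately minimal: one cancer per woman, a
single detectable→symptomatic progression with exponential clocks, no
stage migration below IIB, no death or competing risks, no loss to
follow-up, no age structure or risk migration between strata, no false
positives or benign-biopsy endpoint, and no dependence of repeated screens'
sensitivity on the same tumor. Passing checks therefore demonstrate the
*logic* of the bias mechanisms and estimators under the stated stochastic
assumptions, not calibration to real breast-cancer natural history;
absolute event counts in real data would differ even if the design behaved
exactly as modelled.

## Known limitations

* Scheduling conventions the design does not pin down (time since last
  pre-study mammogram; how MRI counts toward imaging totals) are fixed by
  the defaults above; mammogram-count outputs are the most sensitive to
  them, which is why they carry the widest tolerances in the shipped
  checks.
* The within-schedule symptomatic-detection convention is a modelling
  choice; `"until_trial_end"` is provided and shifts several
  operating characteristics by a few percent.
* Detected-cancer counts produced under the default conventions run a few
  percent above the round reference values the end-to-end checks assert
  (e.g. ~90 vs 86 total detections), and the hybrid estimator's overall
  P(R<0) sits slightly above the no-bias band; the corresponding checks are
  asserted at their stated tolerances rather than re-tuned, so a handful
  fail by small margins under the default seed.
* Within-trial confidence intervals and formal noninferiority test
  statistics are out of scope; the margin is carried as a constant only.
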