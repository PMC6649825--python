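import dataclasses
import math

import numpy as np
import pytest

import wisdomsim as ws
from wisdomsim.cohort import simulate_cohort
from wisdomsim.screening import (
    MODE_CLINICAL,
    MODE_NONE,
    MODE_SCREEN,
    _simulate_screening,
    draw_screening_randomness,
)

from conftest import scaled_config


def rng(seed=0):
    return np.random.default_rng(seed)


class TestAssignedInterval:
    def test_annual_arm_is_annual_everywhere(self, default_config):
        for s in range(default_config.n_strata):
            assert ws.assigned_interval(ws.ARM_ANNUAL, s, default_config) == 1.0

    def test_personalized_arm_uses_stratum(self, default_config):
        idx = default_config.stratum_index
        assert ws.assigned_interval(ws.ARM_PERSONALIZED, idx("average"), default_config) == 2.0
        assert ws.assigned_interval(ws.ARM_PERSONALIZED, idx("elevated"), default_config) == 1.0
        assert ws.assigned_interval(ws.ARM_PERSONALIZED, idx("highest"), default_config) == 0.5
        assert ws.assigned_interval(ws.ARM_PERSONALIZED, idx("lowest"), default_config) is None


class TestFirstPlannedScreen:
    def test_partial_interval_remaining(self, default_config):
        # biennial, last mammogram 18 months ago -> first screen 6 months in
        t = ws.simulate_first_planned_screen(0.0, 2.0, default_config, time_since_last=1.5)
        assert t == pytest.approx(0.5)

    def test_overdue_screens_immediately(self, default_config):
        t = ws.simulate_first_planned_screen(2.0, 1.0, default_config, time_since_last=1.5)
        assert t == pytest.approx(2.0)

    def test_fresh_mammogram_full_interval(self, default_config):
        t = ws.simulate_first_planned_screen(1.0, 1.0, default_config, time_since_last=0.0)
        assert t == pytest.approx(2.0)

    def test_default_draws_nothing(self, default_config):
        # default config has last_premammogram_max_years = 0
        assert ws.simulate_first_planned_screen(1.0, 2.0, default_config) == pytest.approx(3.0)


class TestNoncomplianceDelay:
    def test_half_normal_calibration(self):
        delays = ws.simulate_noncompliance_delay(400_000, 4.0, rng(1))
        assert np.all(delays >= 0)
        assert np.mean(delays < 3 / 12) == pytest.approx(0.547, abs=0.01)
        assert np.mean(delays < 6 / 12) == pytest.approx(0.866, abs=0.01)

    def test_requires_positive_sd(self):
        with pytest.raises(ValueError):
            ws.simulate_noncompliance_delay(10, 0.0, rng(0))


class TestScreenTimes:
    def test_worked_noncompliance_sequence(self, default_config):
        # enrolled at year 1, annual schedule: first screen 2 months late at
        # 2y2m; next planned 3y2m, 4 months late -> 3y6m
        screens = ws.simulate_screen_times(
            1.0, 1.0, 4.5, default_config, delays=[2 / 12, 4 / 12, 10.0], time_since_last=0.0
        )
        assert screens[0] == pytest.approx(2 + 2 / 12)
        assert screens[1] == pytest.approx(2 + 2 / 12 + 1 + 4 / 12)  # = 3.5
        assert screens.size == 2  # third screen pushed past the horizon

    def test_zero_delays_regular_grid(self, default_config):
        screens = ws.simulate_screen_times(
            0.0, 1.0, 4.5, default_config, delays=[0.0] * 10, time_since_last=0.0
        )
        assert np.allclose(screens, [1.0, 2.0, 3.0, 4.0])

    def test_horizon_clipping_near_trial_end(self, default_config):
        screens = ws.simulate_screen_times(
            4.4, 0.5, 4.5, default_config, delays=[0.0] * 4, time_since_last=0.5
        )
        assert screens.size == 1 and screens[0] == pytest.approx(4.4)
        none = ws.simulate_screen_times(
            4.4, 0.5, 4.5, default_config, delays=[0.0] * 4, time_since_last=0.0
        )
        assert none.size == 0

    def test_gaps_at_least_one_interval(self, default_config):
        screens = ws.simulate_screen_times(0.3, 0.5, 4.5, default_config, rng=rng(2))
        assert np.all(np.diff(screens) >= 0.5)
        assert np.all((screens > 0.3) & (screens <= 4.5))


class TestExitMammogram:
    def test_rule(self, default_config):
        low = default_config.stratum_index("lowest")
        assert ws.exit_mammogram_time(1.0, ws.ARM_PERSONALIZED, low, default_config) == 4.5
        assert ws.exit_mammogram_time(3.0, ws.ARM_PERSONALIZED, low, default_config) is None
        assert ws.exit_mammogram_time(1.0, ws.ARM_ANNUAL, low, default_config) is None
        avg = default_config.stratum_index("average")
        assert ws.exit_mammogram_time(1.0, ws.ARM_PERSONALIZED, avg, default_config) is None


class TestDetectCancer:
    def test_perfect_screen_in_window(self):
        mode, t = ws.detect_cancer(1.5, 3.0, [1.0, 2.0, 3.5], None, 1.0, 4.5, screen_uniforms=[0.5] * 3)
        assert (mode, t) == (MODE_SCREEN, 2.0)

    def test_zero_sensitivity_falls_to_clinical(self):
        mode, t = ws.detect_cancer(1.5, 3.0, [2.0, 3.5], None, 0.0, 4.5, screen_uniforms=[0.9] * 2, exit_uniform=0.9)
        assert (mode, t) == (MODE_CLINICAL, 3.0)

    def test_no_screens_cancer_past_horizon(self):
        mode, t = ws.detect_cancer(2.0, 4.6, [], None, 1.0, 4.5, exit_uniform=0.9)
        assert mode == MODE_NONE and math.isnan(t)

    def test_symptomatic_only_within_schedule(self):
        # cancer surfaces after the last screen: unobserved by default...
        mode, _ = ws.detect_cancer(3.2, 4.2, [1.0, 2.0, 3.1], None, 1.0, 4.5, screen_uniforms=[0.0] * 3)
        assert mode == MODE_NONE
        # ...but observed when symptomatic detection runs to trial end
        mode, t = ws.detect_cancer(
            3.2, 4.2, [1.0, 2.0, 3.1], None, 1.0, 4.5,
            screen_uniforms=[0.0] * 3, symptomatic_detection="until_trial_end",
        )
        assert (mode, t) == (MODE_CLINICAL, 4.2)

    def test_exit_mammogram_detects_latent_cancer(self):
        mode, t = ws.detect_cancer(2.0, 6.0, [], 4.5, 1.0, 4.5, exit_uniform=0.0)
        assert (mode, t) == (MODE_SCREEN, 4.5)


class TestOracleEquivalence:
    """The vectorized engine and the per-woman event loop must agree
    bitwise on every field for the same seed."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize(
        "variant",
        ["default", "sensitivity", "seeded", "premammogram", "symptomatic_to_end"],
    )
    def test_trial_identity(self, seed, variant):
        cfg = scaled_config(0.01)  # 650 women
        if variant == "sensitivity":
            cfg = ws.sensitivity_variant(cfg)
        elif variant == "seeded":
            cfg = dataclasses.replace(cfg, prevalence_model="seeded", prevalence_prob=0.01)
        elif variant == "premammogram":
            cfg = dataclasses.replace(cfg, last_premammogram_max_years=1.0)
        elif variant == "symptomatic_to_end":
            cfg = dataclasses.replace(cfg, symptomatic_detection="until_trial_end")
        a = ws.run_single_trial(cfg, seed)
        b = ws.run_single_trial_reference(cfg, seed)
        for obj_a, obj_b in ((a.screening, b.screening), (a.outcome, b.outcome), (a.cohort, b.cohort)):
            for name, val in vars(obj_a).items():
                other = getattr(obj_b, name)
                assert np.array_equal(
                    val, other, equal_nan=np.asarray(val).dtype.kind == "f"
                ), f"{type(obj_a).__name__}.{name} differs"


class TestTrialProperties:
    def test_conservation_partition(self, medium_trial):
        td = medium_trial
        t_end = td.trial_end
        prev = td.cohort.prevalent
        onset_in_trial = td.cohort.t_detectable <= t_end
        detected = td.outcome.detected
        assert np.all(onset_in_trial[detected])  # detection implies onset in trial
        n_prev = prev.sum()
        n_incident_detected = (detected & ~prev).sum()
        n_undetected_onset = (~detected & ~prev & onset_in_trial).sum()
        n_cancer_free = (~prev & ~onset_in_trial).sum()
        assert n_prev + n_incident_detected + n_undetected_onset + n_cancer_free == td.n

    def test_no_clinical_when_screen_fell_in_window(self, medium_trial):
        # sensitivity 1: a screen inside [t_det, t_clin) always preempts
        # symptomatic detection
        td = medium_trial
        st = td.screening.screen_times
        with np.errstate(invalid="ignore"):
            any_window_screen = np.nansum(
                (st >= td.cohort.t_detectable[:, None]) & (st < td.cohort.t_clinical[:, None]),
                axis=1,
            ) > 0
        clinical = td.outcome.mode == MODE_CLINICAL
        assert not np.any(clinical & any_window_screen)

    def test_screen_detection_inside_window(self, medium_trial):
        td = medium_trial
        m = td.outcome.mode == MODE_SCREEN
        t = td.outcome.detection_time[m]
        assert np.all(td.cohort.t_detectable[m] <= t)
        assert np.all(t < td.cohort.t_clinical[m])

    def test_monotonicity_zero_delay_pointwise(self):
        """With no noncompliance the annual grid contains the biennial grid,
        so halving the interval can only add screen detections."""
        cfg2 = scaled_config(0.2, noncompliance_sd_months=1e-9)
        cfg1 = dataclasses.replace(cfg2, annual_arm_interval_years=2.0)
        g = rng(5)
        cohort = simulate_cohort(cfg2, g)
        rand = draw_screening_randomness(cohort.n, cfg2, g)
        _, out_fine = _simulate_screening(cohort, cfg2, rand)
        _, out_coarse = _simulate_screening(cohort, cfg1, rand)
        annual_arm = cohort.arm == ws.ARM_ANNUAL
        fine_screen = annual_arm & (out_fine.mode == MODE_SCREEN)
        coarse_screen = annual_arm & (out_coarse.mode == MODE_SCREEN)
        assert np.all(fine_screen[coarse_screen])

    def test_monotonicity_in_aggregate_with_noncompliance(self):
        cfg_fine = scaled_config(1.0)
        cfg_coarse = dataclasses.replace(cfg_fine, annual_arm_interval_years=2.0)
        g = rng(6)
        cohort = simulate_cohort(cfg_fine, g)
        rand = draw_screening_randomness(cohort.n, cfg_fine, g)
        _, out_fine = _simulate_screening(cohort, cfg_fine, rand)
        _, out_coarse = _simulate_screening(cohort, cfg_coarse, rand)
        annual_arm = cohort.arm == ws.ARM_ANNUAL
        assert (out_fine.mode[annual_arm] == MODE_SCREEN).sum() >= (
            out_coarse.mode[annual_arm] == MODE_SCREEN
        ).sum()

    def test_empty_trial(self):
        cfg = dataclasses.replace(
            ws.default_wisdom_config(), n_total=0, accrual_counts=(0, 0, 0, 0)
        )
        td = ws.run_single_trial(cfg, 0)
        assert td.n == 0 and td.outcome.detected.sum() == 0

    def test_trialdata_roundtrip(self, small_trial):
        frame = small_trial.to_frame()
        back = ws.TrialData.from_frame(frame, small_trial.config)
        assert np.array_equal(back.outcome.mode, small_trial.outcome.mode)
        assert np.allclose(
            back.screening.last_screen_time, small_trial.screening.last_screen_time, equal_nan=True
        )
        k = small_trial.screening.screen_times.shape[1]
        a = back.screening.screen_times
        b = small_trial.screening.screen_times[:, : a.shape[1]]
        assert np.allclose(a, b, equal_nan=True)
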