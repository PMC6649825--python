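"""Walk through the screening-schedule rules on one deterministic woman.

Noncompliance delays are supplied explicitly so the arithmetic is visible:
each screen slips past its planned date, and the next screen is planned one
interval after the *actual* date, so delays accumulate over the trial.
"""

import wisdomsim as ws

config = ws.default_wisdom_config()

# A woman enrolled at year 1 on an annual schedule: planned screens one
# interval after entry. She is 2 months late to the first, 4 months late to
# the second.
screens = ws.simulate_screen_times(
    entry=1.0, interval=1.0, trial_end=4.5, config=config,
    delays=[2 / 12, 4 / 12, 0.0, 0.0], time_since_last=0.0,
)
print("annual schedule, entry at year 1, delays 2 and 4 months:")
for i, t in enumerate(screens, 1):
    years, months = int(t), round((t - int(t)) * 12)
    print(f"  screen {i}: year {years} month {months}  (t = {t:.3f})")
print("  -> first screen at 2y2m; next planned 3y2m, actually 3y6m\n")

# The personalized arm honours the date of the last pre-study mammogram:
# a biennial woman whose last mammogram was 18 months ago is screened
# 6 months after enrolling.
first = ws.simulate_first_planned_screen(0.0, 2.0, config, time_since_last=1.5)
print(f"biennial, last mammogram 18 months before entry: first screen at {first:.1f} y")

# No-screening women in the personalized arm get an exit mammogram at trial
# end, but only if enrolled at least 2 years.
low = config.stratum_index("lowest")
print("exit mammogram, entry year 1:", ws.exit_mammogram_time(1.0, ws.ARM_PERSONALIZED, low, config))
print("exit mammogram, entry year 3:", ws.exit_mammogram_time(3.0, ws.ARM_PERSONALIZED, low, config))
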