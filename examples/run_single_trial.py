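"""Simulate one virtual trial and summarize what the trial would observe.

Builds the default 65 000-woman design, runs a single replicate, and prints
the detected stage IIB+ cancers by risk stratum, arm and mode of detection.
"""

import numpy as np

import wisdomsim as ws
from wisdomsim.screening import MODE_CLINICAL, MODE_SCREEN

config = ws.default_wisdom_config()
trial = ws.run_single_trial(config, rng=1)

print(f"simulated {trial.n} women, trial horizon {trial.trial_end} years")
print(f"prevalent (screen-detectable at entry): {int(trial.cohort.prevalent.sum())}")
print(f"detected stage IIB+ cancers:            {int(trial.outcome.detected.sum())}\n")

print(f"{'stratum':>9} {'arm':>13} {'screen':>7} {'clinical':>9} {'mammograms':>11}")
for s, name in enumerate(config.stratum_names):
    for arm, label in ((ws.ARM_PERSONALIZED, "personalized"), (ws.ARM_ANNUAL, "annual")):
        mask = (trial.cohort.stratum == s) & (trial.cohort.arm == arm)
        n_screen = int(np.sum(mask & (trial.outcome.mode == MODE_SCREEN)))
        n_clin = int(np.sum(mask & (trial.outcome.mode == MODE_CLINICAL)))
        n_mammo = int(trial.screening.n_mammograms[mask].sum())
        print(f"{name:>9} {label:>13} {n_screen:>7} {n_clin:>9} {n_mammo:>11}")

print(
    "\nScreen-detected cancers were caught by a mammogram inside the"
    "\ndetectable window; clinical ones surfaced symptomatically between"
    "\nscreens. Any single replicate is noisy - averages over replicates"
    "\n(see compare_analysis_methods.py) carry the operating characteristics."
)
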