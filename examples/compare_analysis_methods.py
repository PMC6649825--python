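"""Compare the candidate primary-analysis estimators across replicates.

Runs a moderate number of replicate trials at the full design size and
prints, per estimator, the overall per-arm hazards and the bias metric
P(R < 0): the fraction of replicates in which the annual arm shows the lower
hazard. Both arms have identical cancer risk by construction, so values far
from 0.5 expose ascertainment bias introduced at study entry and exit.
"""

import wisdomsim as ws
from wisdomsim.analysis import F_EVENTS, F_EXPOSURE

N_REPLICATES = 200  # increase for tighter Monte Carlo error

config = ws.default_wisdom_config()
agg = ws.run_experiment(config, N_REPLICATES, seed=5)

print(f"{N_REPLICATES} replicates of {config.n_total} women\n")
print(f"{'method':>28} {'hz pers':>8} {'hz ann':>7} {'P(R<0)':>7}")
for method in ws.METHODS:
    mean = agg.mean_summary(method)
    ev, ex = mean[:, :, F_EVENTS].sum(axis=0), mean[:, :, F_EXPOSURE].sum(axis=0)
    print(
        f"{method:>28} {100 * ev[1] / ex[1]:>8.3f} {100 * ev[0] / ex[0]:>7.3f}"
        f" {agg.p_r_lt_0(method):>7.2f}"
    )

print("\nper-stratum bias under total trial time (exit bias):")
for stratum in ("highest", "average"):
    print(f"  {stratum:>8}: P(R<0) = {agg.p_r_lt_0('total_time', stratum):.2f}")
print(
    "\nTotal-trial-time accounting favours the annual arm in the 6-monthly"
    "\nscreened highest-risk stratum (P > .5) and the personalized arm in"
    "\nthe biennial average-risk stratum (P < .5); complete-cycle accounting"
    "\npulls both back toward .5 at the price of discarding some exposure."
)
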