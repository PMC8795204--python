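"""Run the whole campaign: simulate the CCD experiment, fit every model,
maximize overall desirability per 7-day interval by basin-hopping, and
collapse the optima into a three-stage protocol.

The synthetic ground truth switches cytokine regimes at days 7 and 21, so
the partition search should return t1 = 7, t2 = 21.
"""

import numpy as np

from tcellopt import run_synthetic_campaign

res = run_synthetic_campaign(seed=1, noise_sd=0.5, n_iter=40)

print("per-interval optima (overall desirability at the best point):")
for r in res.interval_optima:
    conc = ", ".join(f"{n}={v:.1f}" for n, v in r.best_natural.items())
    print(f"  days {r.interval[0]:2d}-{r.interval[1]:2d}: D = {r.D:.4f}  ({conc} ng/ml)")

p = res.protocol
print(f"\nbest three-stage protocol: t1 = {p.t1}, t2 = {p.t2}")
print(f"average overall desirability = {p.average_D:.4f}")
for stage, (days, conc) in enumerate(zip(
        ((0, p.t1), (p.t1, p.t2), (p.t2, 42)), p.stage_concentrations)):
    mix = ", ".join(f"{n}={v:.1f}" for n, v in conc.items())
    print(f"  stage {stage+1} days {days[0]:2d}-{days[1]:2d}: {mix} ng/ml")

retention = p.average_D / np.mean([r.D for r in res.interval_optima])
print(f"\nthe staged protocol retains {100*retention:.1f}% of the "
      f"unconstrained per-interval desirability")

# Three media formulations approximate six weekly optima almost without
# loss because the underlying dose-response regimes are piecewise-constant;
# a wrongly placed boundary would average concentrations across regimes and
# lower the desirability of every interval in the mixed stage.
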