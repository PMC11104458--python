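"""Mortality risk stratification on a simulated cohort.

Simulates survival outcomes under a proportional-hazards model, then
recovers the planted hazard ratios with Kaplan-Meier curves and Cox fits —
the same pipeline one would run on phenotypes predicted from ECGs.
"""

import numpy as np
import pandas as pd

from cardiolens.survival import SurvivalData, cox_fit, cumulative_events, km_estimate
from cardiolens.synthgen import simulate_survival, tune_baseline_hazard

rng = np.random.default_rng(0)
n = 20_000
age = rng.normal(54, 17, n)
hyp = rng.binomial(1, 0.32, n).astype(float)
st = rng.binomial(1, 0.05, n).astype(float)
x = np.column_stack([age - 54, hyp, st])
beta = np.array([0.03, np.log(1.7), np.log(2.24)])

lam0 = tune_baseline_hazard(x, beta, target_event_rate=0.033, seed=0)
time, event = simulate_survival(x, beta, lam0, seed=1)
print(f"cohort n={n}, events={event.sum()} ({100 * event.mean():.2f}% over "
      "7 years)")

data = SurvivalData(time=time, event=event,
                    covariates=pd.DataFrame(x, columns=["age", "hypertension",
                                                        "ST"]))
t_curve, frac = cumulative_events(data)
print(f"cumulative event fraction at end of follow-up: {frac[-1]:.4f}")

km = km_estimate(data, group=hyp)
print("Kaplan-Meier S(5y): "
      f"normotensive {km['0.0'].probability_at(5):.4f}, "
      f"hypertensive {km['1.0'].probability_at(5):.4f}")

fit = cox_fit(data)
for name, true_hr in [("hypertension", 1.70), ("ST", 2.24)]:
    r = fit[name]
    print(f"adjusted HR[{name}] = {r.hr:.3f} "
          f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}; planted {true_hr})")
print("a single cohort's 95% CI misses its planted value ~5% of the time; "
      "cardiolens.experiments.recover_hazard_ratio averages replicates")
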