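"""Evaluation statistics on simulated scores: AUC with bootstrap CI,
G-mean operating point, diagnostic odds ratio, and age-group stratification.
"""

import numpy as np

from cardiolens import evalstats as es

rng = np.random.default_rng(0)
n = 2000
y = rng.integers(0, 2, n)
ages = rng.uniform(20, 90, n)
# scores more informative for younger subjects
noise = np.where(ages < 45, 0.5, 1.2)
scores = 1 / (1 + np.exp(-(2 * y - 1 + noise * rng.normal(size=n))))

ci = es.bootstrap_ci(es.roc_auc, (scores, y), n_boot=1000, seed=0, name="AUC")
print(f"AUC {ci.point:.3f} (95% CI {ci.lower:.3f}-{ci.upper:.3f})")

thr, sens, spec = es.gmean_cutoff(scores, y)
print(f"G-mean cutoff {thr:.3f}: sensitivity {sens:.3f}, "
      f"specificity {spec:.3f}")

pred = scores >= thr
c = es.ConfusionCounts(tp=int(np.sum(pred & (y == 1))),
                       fp=int(np.sum(pred & (y == 0))),
                       fn=int(np.sum(~pred & (y == 1))),
                       tn=int(np.sum(~pred & (y == 0))))
dor = es.diagnostic_odds_ratio(c)
print(f"diagnostic odds ratio {dor.point:.1f} "
      f"(95% CI {dor.lower:.1f}-{dor.upper:.1f})")

print("per age group (scores were built sharper for <45):")
for name, m in es.subgroup_metrics(scores, y, {"age": ages}, "age",
                                   n_boot=500, seed=1).items():
    if m is not None:
        print(f"  {name}: AUC {m.point:.3f} ({m.lower:.3f}-{m.upper:.3f})")
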