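"""Train the isolation-integration network on a planted-signal task and
verify that its saliency maps point at the planted lead and window.

Half of the records carry a short 25 Hz transient in lead V1; the model
learns to detect it, and the per-lead gradient heatmaps should concentrate
their mass in V1 inside the planted window — ground truth no real dataset
can offer.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from cardiolens.leadrank import dominant_distribution, select_lead_subset
from cardiolens.model import ModelConfig, TrainConfig, build_model, predict, train
from cardiolens.saliency import explain
from cardiolens.synthgen import make_planted_benchmark

xtr, ytr, plant = make_planted_benchmark(200, t_samples=1024, seed=11)
xte, yte, _ = make_planted_benchmark(100, t_samples=1024, seed=12)

cfg = ModelConfig(n_leads=12, input_length=1024, enc_channels=4,
                  enc_kernel=17, trunk_channels=8, trunk_kernel=9,
                  trunk_strides=(4, 4), n_labels=1, seed=0)
model = build_model(cfg)
hist = train(model, xtr, ytr,
             TrainConfig(max_epochs=12, patience=3, seed=0))
print(f"trained {len(hist['val_loss'])} epochs; "
      f"best val loss {min(hist['val_loss']):.4f}")

scores = np.array([p.probabilities[0] for p in predict(model, xte)])
print(f"test AUC: {roc_auc_score(yte, scores):.3f} (1.0 = planted signal "
      "perfectly detected)")

dist = dominant_distribution(model, xte, label=0, tau=0.8, n_boot=500, seed=0)
v1 = dist.lead_names.index("V1")
print(f"dominant-lead share of V1 among confident records: "
      f"{dist.percentages[v1]:.1f}% "
      f"(bootstrap {dist.boot_mean[v1]:.1f} +/- {dist.boot_std[v1]:.1f} counts)")
print("leads above the 10% dominance rule:", select_lead_subset(dist))

hm = explain(model, xte[1], label=0)
fs = 400.0
in_window = hm.values[v1, int(0.9 * fs):int(1.6 * fs)].sum()
print(f"single-record heatmap: P(signal)={hm.probability:.3f}, "
      f"{100 * in_window / hm.values[v1].sum():.0f}% of V1 mass inside the "
      "planted window +/-0.1 s")
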