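# cardiolens

Interpretable deep learning for 12-lead electrocardiograms: a
channel-isolated convolutional classifier whose saliency maps attribute each
diagnosis to specific leads and time windows, dominant-lead derivation for
reduced-lead ECG devices, and Cox-based mortality risk stratification from
the predicted phenotypes. A synthetic ECG/cohort simulator plants verifiable
ground truth — which lead carries the signal, which hazard ratio governs
survival — so every stage of the pipeline can be validated end to end
without access to clinical data.

It is written for researchers in computational cardiology and biomedical
signal analysis who want a fully testable, CPU-scale reference
implementation of per-lead ECG attribution and its downstream epidemiology.

## The method

**Isolation–integration network.** Each lead *ℓ* of an input
X ∈ ℝ^(12×T) is encoded by its own small convolutional encoder
f_ℓ (no weight sharing across leads), each downsampling time by exactly 2.
The per-lead activations are stacked into a concatenated feature matrix

    F = [f_1(x_1); …; f_12(x_12)] ∈ ℝ^(12C × T/2),

so channel block ℓ depends on lead ℓ *only* — an architectural guarantee,
not a hope. An integration trunk (strided convolutions, global average
pooling, linear head) maps F to per-label logits with sigmoid heads.

**Fine-grained saliency.** For a target label with logit z, the heatmap is

    α_c = mean_t ∂z/∂F[c,t]           (per-channel kernel weight)
    raw[ℓ,t] = ReLU( Σ_{c∈block ℓ} α_c · F[c,t] )
    H = upsample×2(raw) / max(H)      (aligned to the input, values in [0,1])

Because F is half the input length, a single ×2 magnification aligns the
map with the signal samples.

**Dominant leads.** Over records predicted with probability > 0.8, the lead
with the largest heatmap mass Σ_t H[ℓ,t] is the record's dominant lead;
occurrence percentages (with bootstrap mean ± sd) identify the leads a task
actually uses, and leads above a 10% share define a reduced lead subset that
is retrained from scratch.

**Risk stratification.** Phenotypes (recorded or ECG-predicted, binarized
at the G-mean operating point) enter Kaplan–Meier and Cox
proportional-hazards analyses, h(t|x) = h₀(t)·exp(xᵀβ), fitted by
Newton–Raphson on the partial likelihood (Efron ties; Wald CIs).

**Synthetic generator.** Beats are sums of Gaussian waves (P, Q, R, S, T, U)
mixed into 12 leads through a fixed table; injectors impose textbook
abnormality signatures (PR > 200 ms, QRS ≥ 120 ms with V1/V6 morphology,
rate bounds, absent-P irregular AF with fibrillatory waves), and cohorts
carry proportional-hazards survival times with uniform dropout. A
rule-based interval measurer recovers every injected abnormality from the
clean waveform, making label/morphology consistency machine-checkable.

## Worked example

`python examples/train_and_explain.py` trains the network on a planted-signal
task — half the records carry a 25 Hz, 0.35 mV transient in lead V1 at
1.0–1.5 s — and prints:

```
trained 12 epochs; best val loss 0.0000
test AUC: 1.000 (1.0 = planted signal perfectly detected)
dominant-lead share of V1 among confident records: 100.0% (bootstrap 50.0 +/- 0.0 counts)
leads above the 10% dominance rule: ['V1']
single-record heatmap: P(signal)=1.000, 69% of V1 mass inside the planted window +/-0.1 s
```

The model finds the planted signal (AUC 1.0), the saliency procedure
attributes every confident prediction to the correct lead (V1 = 100% of
dominant leads), and most of that lead's heatmap mass falls inside the
planted time window — the three claims the architecture is designed to make
verifiable. Other examples cover cohort simulation
(`examples/simulate_cohort.py`), evaluation statistics
(`examples/evaluate_metrics.py`) and survival analysis
(`examples/risk_stratification.py`).

A thin CLI wraps the same library calls:

```bash
cardiolens simulate --n 500 --out data.h5 --meta meta.csv --seed 1
cardiolens train --data data.h5 --meta meta.csv --task hypertension --out model.ckpt
cardiolens leads --model model.ckpt --data data.h5 --meta meta.csv --out dist.csv
cardiolens survival --meta meta.csv --mode adjusted --out hr_table.csv
```

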