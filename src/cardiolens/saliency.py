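"""Fine-grained per-lead saliency maps for the isolation–integration network.

The procedure:

1. gradient of the target label's pre-sigmoid logit with respect to the
   concatenated feature matrix (``feature_gradients``);
2. average each channel's gradient over time to get one kernel weight per
   channel (``kernel_weights``);
3. inside each lead's channel block, sum the weighted channels and apply a
   ReLU, giving a nonnegative raw map per lead at half temporal resolution
   (``lead_cam``);
4. magnify the raw map by exactly two (linear interpolation) to align it with
   the input signal (``align_heatmap``);
5. normalise by the global maximum across all leads so values live in [0, 1]
   and per-lead masses are comparable (``explain``).

Because the encoders are isolated, channel block *j* depends only on lead *j*,
so the heatmap row for a lead reflects that lead's samples alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import IsolationModel, _sigmoid

__all__ = ["KernelWeights", "Heatmap", "feature_gradients", "kernel_weights",
           "lead_cam", "align_heatmap", "explain", "explain_batch"]


@dataclass
class KernelWeights:
    """One scalar weight per feature-matrix channel (time-averaged gradient)."""

    alpha: np.ndarray


@dataclass
class Heatmap:
    """L x T nonnegative saliency in [0, 1], plus what it explains."""

    values: np.ndarray
    label: int
    probability: float


def feature_gradients(model: IsolationModel, ecg: np.ndarray, label: int) -> np.ndarray:
    """Gradient of the label's logit w.r.t. the (L*C) x T/2 feature matrix."""
    feats = model.encode(ecg)
    return model.feature_gradient_batch(feats, label)[0]


def kernel_weights(grad: np.ndarray) -> KernelWeights:
    """Average each channel's gradient over the temporal axis."""
    grad = np.asarray(grad, dtype=float)
    if grad.ndim != 2 or grad.shape[1] == 0:
        raise ValueError("gradient must be (channels, time) with time > 0")
    if not np.all(np.isfinite(grad)):
        raise ValueError("gradient contains non-finite values")
    return KernelWeights(alpha=grad.mean(axis=1))


def lead_cam(features: np.ndarray, weights: KernelWeights,
             block_map: list[tuple[int, int]]) -> np.ndarray:
    """ReLU of the per-lead weighted channel sums: raw map, L x T/2."""
    features = np.asarray(features, dtype=float)
    alpha = weights.alpha
    if features.shape[0] != alpha.shape[0]:
        raise ValueError("channel count mismatch between features and weights")
    lo_hi = np.asarray(block_map)
    if lo_hi[-1, 1] != features.shape[0]:
        raise ValueError("block_map does not partition the feature channels")
    weighted = alpha[:, None] * features
    raw = np.stack([weighted[lo:hi].sum(axis=0) for lo, hi in block_map])
    return np.maximum(raw, 0.0)


def align_heatmap(raw: np.ndarray, t: int) -> np.ndarray:
    """Upsample the half-resolution raw map by exactly 2 (linear interpolation)."""
    raw = np.asarray(raw, dtype=float)
    half = raw.shape[-1]
    if t != 2 * half:
        raise ValueError(f"target length {t} is not twice the raw length {half}")
    xs = np.linspace(0.0, half - 1.0, t)
    base = np.arange(half, dtype=float)
    out = np.stack([np.interp(xs, base, row) for row in raw])
    return np.maximum(out, 0.0)


def _upsample_nearest(raw: np.ndarray) -> np.ndarray:
    return np.repeat(raw, 2, axis=-1)


def explain(model: IsolationModel, ecg: np.ndarray, label: int | None = None,
            interpolation: str = "linear") -> Heatmap:
    """Full saliency pipeline for one record.

    ``label=None`` explains the argmax-probability label.  ``interpolation``
    may be ``"linear"`` (default) or ``"nearest"`` for bit-exact block maps.
    """
    ecg = np.asarray(ecg, dtype=float)
    feats = model.encode(ecg)
    logits = model.logits_from_features(feats)[0]
    probs = _sigmoid(logits)
    if label is None:
        label = int(np.argmax(probs))
    grad = model.feature_gradient_batch(feats, label)[0]
    w = kernel_weights(grad)
    raw = lead_cam(feats[0], w, model.block_map)
    t = model.config.input_length
    if interpolation == "linear":
        full = align_heatmap(raw, t)
    elif interpolation == "nearest":
        full = _upsample_nearest(raw)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    peak = full.max()
    if peak > 0:
        full = full / peak
    return Heatmap(values=full, label=label, probability=float(probs[label]))


def explain_batch(model: IsolationModel, batch: np.ndarray, label: int,
                  interpolation: str = "linear") -> list[Heatmap]:
    """Vectorised ``explain`` for a batch of records and one label."""
    batch = np.asarray(batch, dtype=float)
    if batch.ndim == 2:
        batch = batch[None]
    feats = model.encode(batch)
    logits = model.logits_from_features(feats)
    probs = _sigmoid(logits)
    grads = model.feature_gradient_batch(feats, label)
    out = []
    t = model.config.input_length
    for i in range(batch.shape[0]):
        w = kernel_weights(grads[i])
        raw = lead_cam(feats[i], w, model.block_map)
        full = align_heatmap(raw, t) if interpolation == "linear" else _upsample_nearest(raw)
        peak = full.max()
        if peak > 0:
            full = full / peak
        out.append(Heatmap(values=full, label=label, probability=float(probs[i, label])))
    return out
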