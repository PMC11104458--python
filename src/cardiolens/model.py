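"""Isolation–integration network for multilead ECG classification.

Each lead is encoded by its *own* small convolutional encoder (no parameter
sharing across leads), so every channel block of the concatenated feature
matrix depends on exactly one lead.  The encoders downsample time by exactly 2;
the concatenated feature matrix therefore has half the temporal length of the
input, and a saliency map computed on it only needs a x2 magnification to align
with the signal.  An integration trunk (strided convolutions, global average
pooling, linear head) mixes the per-lead features into label logits.

The network is pure numpy (see :mod:`cardiolens.nn`), sized to train in CPU
minutes on desk-scale synthetic cohorts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Adam, Conv1d, Dense, GlobalAvgPool, ReLU, Sequential

__all__ = ["ModelConfig", "TrainConfig", "FeatureMatrix", "Prediction",
           "IsolationModel", "build_model", "encode_isolated", "predict",
           "train", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The encoder must downsample time by exactly 2 in total; this is a hard
    architectural contract (feature matrix length = T/2), enforced at build.
    """

    n_leads: int = 12
    input_length: int = 4096
    enc_channels: int = 8
    enc_kernel: int = 17
    enc_strides: tuple[int, ...] = (1, 2)
    trunk_channels: int = 16
    trunk_kernel: int = 9
    trunk_strides: tuple[int, ...] = (4, 4)
    n_labels: int = 1
    seed: int = 0

    def __post_init__(self):
        if int(np.prod(self.enc_strides)) != 2:
            raise ValueError("encoder temporal downsample product must be exactly 2")
        if self.n_labels < 1:
            raise ValueError("n_labels must be >= 1")
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    val_fraction: float = 0.2
    pos_weight_cap: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class FeatureMatrix:
    """Concatenated per-lead encoder activations, (L*C) x T/2.

    ``block_map[l] = (lo, hi)`` gives the half-open channel range produced by
    lead ``l``'s encoder.
    """

    activations: np.ndarray
    block_map: list[tuple[int, int]]

    def lead_block(self, lead: int) -> np.ndarray:
        lo, hi = self.block_map[lead]
        return self.activations[lo:hi]


@dataclass
class Prediction:
    probabilities: np.ndarray
    logits: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class IsolationModel:
    """Per-lead isolated encoders + integration trunk + sigmoid label heads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.enc_channels
        self.encoders: list[Sequential] = []
        for _ in range(config.n_leads):
            layers: list = []
            c_in = 1
            for s in config.enc_strides:
                layers += [Conv1d(c_in, c, config.enc_kernel, stride=s, rng=rng), ReLU()]
                c_in = c
            self.encoders.append(Sequential(layers))
        trunk_layers: list = []
        c_in = config.n_leads * c
        for s in config.trunk_strides:
            trunk_layers += [Conv1d(c_in, config.trunk_channels, config.trunk_kernel,
                                    stride=s, rng=rng), ReLU()]
            c_in = config.trunk_channels
        trunk_layers.append(GlobalAvgPool())
        trunk_layers.append(Dense(c_in, config.n_labels, rng=rng))
        self.trunk = Sequential(trunk_layers)
        self.block_map = [(l * c, (l + 1) * c) for l in range(config.n_leads)]
        # per-lead standardisation statistics, set by train()
        self.norm_mean = np.zeros(config.n_leads)
        self.norm_std = np.ones(config.n_leads)
        self.history: dict[str, list[float]] = {}

    # -- parameter plumbing -------------------------------------------------
    def _stacks(self) -> list[Sequential]:
        return self.encoders + [self.trunk]

    def params(self) -> list[np.ndarray]:
        return [p for s in self._stacks() for p in s.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for s in self._stacks() for g in s.grads()]

    def zero_grad(self) -> None:
        for s in self._stacks():
            s.zero_grad()

    def state_dict(self) -> dict:
        return {"params": [p.copy() for p in self.params()],
                "norm_mean": self.norm_mean.copy(),
                "norm_std": self.norm_std.copy()}

    def load_state(self, state: dict) -> None:
        for p, saved in zip(self.params(), state["params"]):
            p[...] = saved
        self.norm_mean = np.asarray(state["norm_mean"], dtype=float)
        self.norm_std = np.asarray(state["norm_std"], dtype=float)

    # -- forward passes -----------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.n_leads:
            raise ValueError(f"expected {self.config.n_leads} leads, got {x.shape[1]}")
        if x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected input length {self.config.input_length}, got {x.shape[2]}")
        return x

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean[None, :, None]) / self.norm_std[None, :, None]

    def encode(self, x: np.ndarray, normalized: bool = False) -> np.ndarray:
        """Concatenated feature matrix for a batch: (N, L*C, T/2)."""
        x = self._check_input(x)
        if not normalized:
            x = self.normalize(x)
        feats = [enc.forward(x[:, l : l + 1, :]) for l, enc in enumerate(self.encoders)]
        return np.concatenate(feats, axis=1)

    def forward(self, x: np.ndarray, normalized: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logits, features) for a batch."""
        feats = self.encode(x, normalized=normalized)
        return self.trunk.forward(feats), feats

    def logits_from_features(self, feats: np.ndarray) -> np.ndarray:
        return self.trunk.forward(feats)

    def feature_gradient_batch(self, feats: np.ndarray, label: int) -> np.ndarray:
        """d logit[label] / d feature-matrix for each record in the batch.

        Runs the trunk forward on ``feats`` then backpropagates a one-hot
        upstream gradient; encoder parameters are untouched.
        """
        if not 0 <= label < self.config.n_labels:
            raise ValueError(f"label index {label} out of range")
        self.trunk.zero_grad()
        self.trunk.forward(feats)
        gy = np.zeros((feats.shape[0], self.config.n_labels))
        gy[:, label] = 1.0
        gfeat = self.trunk.backward(gy)
        self.trunk.zero_grad()
        return gfeat


def build_model(config: ModelConfig) -> IsolationModel:
    """Construct the network; deterministic parameter init given config.seed."""
    return IsolationModel(config)


def encode_isolated(model: IsolationModel, ecg: np.ndarray) -> FeatureMatrix:
    """Feature matrix for a single record (leads x T), with the lead block map."""
    feats = model.encode(ecg)
    return FeatureMatrix(activations=feats[0], block_map=model.block_map)


def predict(model: IsolationModel, batch: np.ndarray,
            return_features: bool = False):
    """Sigmoid probabilities per label for a batch of records (order preserved)."""
    x = batch if np.asarray(batch).ndim == 3 else np.asarray(batch)[None]
    logits, feats = model.forward(x)
    preds = [Prediction(probabilities=_sigmoid(z), logits=z) for z in logits]
    if return_features:
        return preds, feats
    return preds


def save_checkpoint(model: IsolationModel, path) -> None:
    """Bundle config, normalisation statistics and parameters into one .npz."""
    import json

    cfg = model.config.__dict__.copy()
    cfg["enc_strides"] = list(cfg["enc_strides"])
    cfg["trunk_strides"] = list(cfg["trunk_strides"])
    arrays = {f"param_{i}": p for i, p in enumerate(model.params())}
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
        np.savez(fh, config=json.dumps(cfg), norm_mean=model.norm_mean,
                 norm_std=model.norm_std, **arrays)


def load_checkpoint(path) -> IsolationModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        cfg["enc_strides"] = tuple(cfg["enc_strides"])
        cfg["trunk_strides"] = tuple(cfg["trunk_strides"])
        model = IsolationModel(ModelConfig(**cfg))
        params = [data[f"param_{i}"] for i in range(len(model.params()))]
        model.load_state({"params": params, "norm_mean": data["norm_mean"],
                          "norm_std": data["norm_std"]})
    return model


def _bce_with_logits(z: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy; returns (mean loss, d loss / d z)."""
    p = _sigmoid(z)
    eps = 1e-12
    per = -(w * y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    loss = float(per.mean())
    gz = (w * y * (p - 1) + (1 - y) * p) / z.size
    return loss, gz


def train(model: IsolationModel, x: np.ndarray, y: np.ndarray,
          tc: TrainConfig | None = None) -> dict[str, list[float]]:
    """Train with Adam + early stopping on validation loss.

    Inputs are standardised per lead using training-split statistics (stored on
    the model).  Positive-class loss weights n_neg/n_pos (capped) counter label
    imbalance.  Returns the loss history; the model is left holding the
    parameters of the best validation epoch.
    """
    tc = tc or TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[1] != model.config.n_labels:
        raise ValueError("label matrix width must equal n_labels")
    for j in range(y.shape[1]):
        if len(np.unique(y[:, j])) < 2:
            raise ValueError(f"label column {j} is single-class; cannot train")

    rng = np.random.default_rng(tc.seed)
    n = x.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(tc.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]

    # per-lead standardisation from the training split
    model.norm_mean = x[tr_idx].mean(axis=(0, 2))
    model.norm_std = x[tr_idx].std(axis=(0, 2))
    model.norm_std[model.norm_std < 1e-8] = 1.0

    pos = y[tr_idx].sum(axis=0)
    neg = len(tr_idx) - pos
    pos_w = np.minimum(np.where(pos > 0, neg / np.maximum(pos, 1), 1.0),
                       tc.pos_weight_cap)

    opt = Adam(model.params(), model.grads(), lr=tc.lr)
    xv = model.normalize(x[val_idx])
    yv = y[val_idx]
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, None, 0

    for _epoch in range(tc.max_epochs):
        perm = rng.permutation(len(tr_idx))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), tc.batch_size):
            idx = tr_idx[perm[start : start + tc.batch_size]]
            xb = model.normalize(x[idx])
            yb = y[idx]
            model.zero_grad()
            logits, feats = model.forward(xb, normalized=True)
            loss, gz = _bce_with_logits(logits, yb, pos_w[None, :])
            gfeat = model.trunk.backward(gz)
            c = model.config.enc_channels
            for l, enc in enumerate(model.encoders):
                enc.backward(gfeat[:, l * c : (l + 1) * c, :])
            opt.step()
            ep_loss += loss
            n_batches += 1
        zv, _ = model.forward(xv, normalized=True)
        val_loss, _ = _bce_with_logits(zv, yv, pos_w[None, :])
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss, best_state, since_best = val_loss, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break

    if best_state is not None:
        model.load_state(best_state)
    model.history = history
    return history
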