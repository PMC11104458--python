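"""Dominant-lead derivation and reduced-lead evaluation.

For records the classifier is confident about (probability strictly above a
threshold, default 0.8), the heatmap mass is summed per lead; the lead with
the largest mass is that record's *dominant lead*.  Occurrence counts and
percentages across records, with bootstrap dispersion, describe which leads
the model actually relies on for a given label.  Leads whose share exceeds a
percentage threshold (default 10%) form the reduced lead subset, which can be
evaluated by retraining a fresh model on those leads alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .leads import LEAD_NAMES, lead_indices
from .model import IsolationModel, ModelConfig, TrainConfig, build_model, predict, train
from .saliency import Heatmap, explain_batch

__all__ = ["LeadMass", "DominantLeadDistribution", "EmptyDistributionError",
           "confident_subset", "lead_mass", "dominant_lead",
           "dominant_distribution", "select_lead_subset", "reduced_lead_train"]


class EmptyDistributionError(RuntimeError):
    """No confident records: a dominant-lead distribution cannot be formed."""


@dataclass
class LeadMass:
    values: np.ndarray  # 12-vector, per-lead heatmap sum


@dataclass
class DominantLeadDistribution:
    lead_names: tuple[str, ...]
    counts: np.ndarray        # occurrences per lead among confident records
    percentages: np.ndarray   # counts / total * 100
    boot_mean: np.ndarray
    boot_std: np.ndarray
    n_replicates: int
    label: int


def confident_subset(probabilities: np.ndarray, tau: float = 0.8) -> np.ndarray:
    """Indices with prediction probability strictly greater than tau."""
    probabilities = np.asarray(probabilities, dtype=float)
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return np.where(probabilities > tau)[0]


def lead_mass(heatmap: Heatmap | np.ndarray) -> LeadMass:
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    return LeadMass(values=values.sum(axis=1))


def dominant_lead(mass: LeadMass | np.ndarray) -> str | None:
    """Lead name with the largest mass; ties go to the lowest lead index.

    Returns ``None`` for an all-zero mass vector (no attribution at all);
    such records are excluded from distributions.
    """
    values = mass.values if isinstance(mass, LeadMass) else np.asarray(mass)
    if np.any(values < 0):
        raise ValueError("lead masses must be nonnegative")
    if np.all(values == 0):
        return None
    return LEAD_NAMES[int(np.argmax(values))]


def dominant_distribution(model: IsolationModel, x: np.ndarray, label: int,
                          tau: float = 0.8, n_boot: int = 1000,
                          seed: int = 0) -> DominantLeadDistribution:
    """Dominant-lead occurrence distribution over confident records.

    Bootstrap resamples the confident records with replacement ``n_boot``
    times and reports the per-lead mean and standard deviation of the counts.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("dataset is empty")
    probs = np.array([p.probabilities[label] for p in predict(model, x)])
    keep = confident_subset(probs, tau)
    if len(keep) == 0:
        raise EmptyDistributionError(
            f"no records with probability > {tau} for label {label}")
    heatmaps = explain_batch(model, x[keep], label)
    doms = []
    for hm in heatmaps:
        name = dominant_lead(lead_mass(hm))
        if name is not None:
            doms.append(LEAD_NAMES.index(name))
    doms = np.asarray(doms, dtype=int)
    counts = np.bincount(doms, minlength=12).astype(float)
    pct = 100.0 * counts / counts.sum()

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 12))
    for b in range(n_boot):
        res = rng.choice(doms, size=len(doms), replace=True)
        boot[b] = np.bincount(res, minlength=12)
    return DominantLeadDistribution(
        lead_names=LEAD_NAMES, counts=counts, percentages=pct,
        boot_mean=boot.mean(axis=0), boot_std=boot.std(axis=0),
        n_replicates=n_boot, label=label)


def select_lead_subset(dist: DominantLeadDistribution,
                       threshold: float = 10.0) -> list[str]:
    """Leads whose dominant share is strictly above ``threshold`` percent,
    ordered by descending percentage."""
    order = np.argsort(dist.percentages)[::-1]
    return [dist.lead_names[i] for i in order if dist.percentages[i] > threshold]


def reduced_lead_train(x: np.ndarray, y: np.ndarray, subset: list[str],
                       config: ModelConfig, tc: TrainConfig | None = None
                       ) -> IsolationModel:
    """Retrain a fresh model from scratch on the selected leads only."""
    if not subset:
        raise ValueError("lead subset must be nonempty")
    idx = lead_indices(subset)
    if len(set(idx)) != len(idx):
        raise ValueError("lead subset contains duplicates")
    from dataclasses import replace as _replace
    reduced_cfg = _replace(config, n_leads=len(idx))
    model = build_model(reduced_cfg)
    train(model, np.asarray(x)[:, idx, :], y, tc)
    return model
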