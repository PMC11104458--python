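"""Classification evaluation statistics.

ROC/AUC, precision/recall/F1 with micro-averaging over labels, the diagnostic
odds ratio, the G-mean operating point, percentile-bootstrap confidence
intervals and paired model comparison, and age/sex subgroup stratification.
Conventions: positives are predicted when score >= threshold; micro averages
pool TP/FP/FN across labels before computing the ratios; DOR uses the
Haldane–Anscombe +0.5 correction when any confusion cell is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricWithCI", "roc_auc", "pr_f1", "micro_f1",
           "gmean_cutoff", "diagnostic_odds_ratio", "bootstrap_ci",
           "paired_bootstrap_pvalue", "subgroup_metrics", "AGE_BINS"]

AGE_BINS = ((0.0, 45.0), (45.0, 75.0), (75.0, np.inf))
AGE_BIN_NAMES = ("young (<45)", "middle (45-74)", "old (>=75)")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricWithCI:
    name: str
    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_replicates: int = 0


def _check_binary(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC; equals the Mann–Whitney pair statistic with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(roc_auc_score(labels, scores))


def pr_f1(scores: Sequence[float], labels: Sequence[int],
          threshold: float = 0.5) -> tuple[float, float, float]:
    """Precision, recall, F1 at a threshold (positive when score >= threshold).

    Precision with zero predicted positives is reported as 0 with a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


def micro_f1(per_label: Sequence[ConfusionCounts]) -> tuple[float, float, float]:
    """Micro-averaged P/R/F1: pool TP/FP/FN across labels, then compute."""
    tp = sum(c.tp for c in per_label)
    fp = sum(c.fp for c in per_label)
    fn = sum(c.fn for c in per_label)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


def gmean_cutoff(scores: Sequence[float], labels: Sequence[int]
                 ) -> tuple[float, float, float]:
    """Operating point maximizing sqrt(sensitivity * specificity).

    Candidate thresholds are the unique scores; positives are score >=
    threshold.  Ties on the G-mean go to the lowest threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = (-1.0, np.inf)  # (gmean, threshold)
    best_ss = (0.0, 0.0)
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        g = np.sqrt(sens * spec)
        if g > best[0] + 1e-12 or (abs(g - best[0]) <= 1e-12 and thr < best[1]):
            best = (g, thr)
            best_ss = (sens, spec)
    return float(best[1]), float(best_ss[0]), float(best_ss[1])


def diagnostic_odds_ratio(counts: ConfusionCounts, level: float = 0.95
                          ) -> MetricWithCI:
    """DOR = (TP*TN)/(FP*FN) with a log-normal Wald CI.

    Zero cells get the Haldane–Anscombe +0.5 added to every cell.
    """
    if counts.n == 0:
        raise ValueError("empty confusion counts")
    cells = np.array([counts.tp, counts.fp, counts.fn, counts.tn], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    tp, fp, fn, tn = cells
    dor = (tp * tn) / (fp * fn)
    se = np.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    z = norm.ppf(0.5 + level / 2)
    return MetricWithCI(name="DOR", point=float(dor),
                        lower=float(dor * np.exp(-z * se)),
                        upper=float(dor * np.exp(z * se)), level=level)


def bootstrap_ci(metric: Callable[..., float], data: tuple[np.ndarray, ...],
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                 name: str = "metric") -> MetricWithCI:
    """Percentile bootstrap over records: resample rows of all data arrays."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    point = float(metric(*arrays))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats[b] = metric(*(a[idx] for a in arrays))
        except ValueError:  # e.g. single-class resample
            stats[b] = np.nan
    stats = stats[np.isfinite(stats)]
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return MetricWithCI(name=name, point=point, lower=float(lo),
                        upper=float(hi), level=level, n_replicates=n_boot)


def paired_bootstrap_pvalue(metric: Callable[..., float],
                            scores_a: np.ndarray, scores_b: np.ndarray,
                            labels: np.ndarray, n_boot: int = 1000,
                            seed: int = 0) -> float:
    """Two-sided paired bootstrap p-value for metric(A) - metric(B).

    Resamples records jointly; p is twice the fraction of resampled
    differences whose sign opposes (or equals zero against) the observed
    difference, capped at 1.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    d0 = metric(scores_a, labels) - metric(scores_b, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    flips = 0
    valid = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            d = metric(scores_a[idx], labels[idx]) - metric(scores_b[idx], labels[idx])
        except ValueError:
            continue
        valid += 1
        if d * d0 <= 0:
            flips += 1
    if valid == 0:
        return 1.0
    return min(1.0, 2.0 * flips / valid)


def subgroup_metrics(scores: np.ndarray, labels: np.ndarray,
                     metadata, grouping: str = "age",
                     metric: Callable[..., float] = roc_auc,
                     n_boot: int = 1000, seed: int = 0
                     ) -> dict[str, MetricWithCI | None]:
    """Metric with bootstrap CI per subgroup.

    ``grouping`` is "age" (bins [0,45), [45,75), [75,inf) on column ``age``)
    or "sex" (column ``is_male``).  Empty groups are reported as ``None``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, MetricWithCI | None] = {}
    if grouping == "age":
        ages = np.asarray(metadata["age"], dtype=float)
        groups = {name: (ages >= lo) & (ages < hi)
                  for name, (lo, hi) in zip(AGE_BIN_NAMES, AGE_BINS)}
    elif grouping == "sex":
        male = np.asarray(metadata["is_male"], dtype=bool)
        groups = {"male": male, "female": ~male}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    for name, mask in groups.items():
        if not np.any(mask):
            out[name] = None
            continue
        try:
            out[name] = bootstrap_ci(metric, (scores[mask], labels[mask]),
                                     n_boot=n_boot, seed=seed, name=name)
        except ValueError:
            out[name] = None
    return out
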