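"""Classification losses and confusion-matrix metrics.

Two losses are provided for log-probability outputs:

* plain cross-entropy,  H(p, q) = -sum_x p(x) ln q(x);
* enhanced cross-entropy (ECE), a focal-style reweighting
  H(p, q) = -sum_x (1 - q(x))^2 p(x) ln q(x),
  which down-weights confidently correct ("easy") trials so hard trials
  dominate the gradient.  For one-hot p, ECE <= CE always.

Natural logarithms are used throughout; predicted probabilities are
clipped at 1e-12 before taking logs.  Metrics (accuracy, macro-F1,
Cohen's kappa) are derived exclusively from the confusion matrix:
accuracy = trace/total; per-class precision/recall one-vs-rest; kappa =
(acc - p_e)/(1 - p_e) with chance agreement p_e = sum_k row_k col_k / n^2.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core_data import ConfusionMatrix, ValidationError

__all__ = [
    "ProbPair",
    "MetricsReport",
    "cross_entropy",
    "enhanced_cross_entropy",
    "batch_loss",
    "batch_loss_grad",
    "confusion",
    "metrics_from_confusion",
]

EPS = 1e-12


@dataclasses.dataclass
class ProbPair:
    """A (true, predicted) distribution pair over the same classes."""

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.q = np.asarray(self.q, dtype=np.float64)
        for name, v in (("p", self.p), ("q", self.q)):
            if v.ndim != 1 or v.shape != self.p.shape:
                raise ValidationError(f"{name} must be 1-D and shapes must match")
            if (v < -1e-9).any():
                raise ValidationError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{name} sums to {v.sum()!r}, not 1")


def cross_entropy(pair: ProbPair) -> float:
    """H(p, q) = -sum p ln q; zero iff q puts all mass on the true class."""
    q = np.clip(pair.q, EPS, 1.0)
    return float(-(pair.p * np.log(q)).sum())


def enhanced_cross_entropy(pair: ProbPair) -> float:
    """Focal-style loss -sum (1-q)^2 p ln q (<= plain CE for one-hot p)."""
    q = np.clip(pair.q, EPS, 1.0)
    return float(-((1.0 - q) ** 2 * pair.p * np.log(q)).sum())


def batch_loss(logits: np.ndarray, labels: np.ndarray, kind: str = "ece") -> float:
    """Mean per-trial loss from log-probability rows and integer labels.

    ``logits`` are log-probabilities (rows log-sum-exp to 0); ``p`` is the
    one-hot of each label, for which both losses reduce to a function of
    the predicted probability of the true class only.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n, nc = logits.shape
    bad = np.flatnonzero((labels < 0) | (labels >= nc))
    if bad.size:
        raise ValidationError(f"label out of range at trial {bad[0]}: {labels[bad[0]]}")
    lp_true = logits[np.arange(n), labels]
    q_true = np.clip(np.exp(lp_true), EPS, 1.0)
    log_q = np.log(q_true)
    if kind == "ce":
        per_trial = -log_q
    elif kind == "ece":
        per_trial = -((1.0 - q_true) ** 2) * log_q
    else:
        raise ValidationError(f"unknown loss kind {kind!r}")
    return float(per_trial.mean())


def batch_loss_grad(logits: np.ndarray, labels: np.ndarray, kind: str = "ece") -> np.ndarray:
    """Gradient of :func:`batch_loss` w.r.t. the log-probability rows.

    With u = ln q(true) the per-trial losses are L_ce(u) = -u and
    L_ece(u) = -(1 - e^u)^2 u, whose derivatives are -1 and
    2 u e^u (1 - e^u) - (1 - e^u)^2 respectively; gradients on non-true
    entries are zero (the loss reads only the true-class entry).
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n, _ = logits.shape
    u = logits[np.arange(n), labels]
    q = np.clip(np.exp(u), EPS, 1.0)
    if kind == "ce":
        d = -np.ones(n)
    elif kind == "ece":
        d = 2.0 * u * q * (1.0 - q) - (1.0 - q) ** 2
    else:
        raise ValidationError(f"unknown loss kind {kind!r}")
    grad = np.zeros_like(logits)
    grad[np.arange(n), labels] = d / n
    return grad


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion(labels: np.ndarray, predictions: np.ndarray, n_classes: int) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise ValidationError(
            f"labels ({labels.shape}) and predictions ({predictions.shape}) differ in length"
        )
    for name, v in (("labels", labels), ("predictions", predictions)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValidationError(f"{name} outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts=counts)


@dataclasses.dataclass
class MetricsReport:
    """Accuracy, macro-F1 and Cohen's kappa plus per-class detail."""

    accuracy: float
    f1: float
    kappa: float
    per_class: list[dict[str, float]]
    n: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, macro-averaged F1 and kappa from a confusion matrix.

    Degenerate one-vs-rest cells (no predicted or no true members of a
    class) give precision/recall/F1 of 0 for that class; chance agreement
    p_e = 1 (all mass in one cell) gives kappa = 0 by convention.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    nc = cm.n_classes
    acc = float(np.trace(counts)) / total
    rows = counts.sum(axis=1).astype(np.float64)
    cols = counts.sum(axis=0).astype(np.float64)
    per_class = []
    f1s = []
    for k in range(nc):
        tp = float(counts[k, k])
        fp = cols[k] - tp
        fn = rows[k] - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class.append({"precision": prec, "recall": rec, "f1": f1})
        f1s.append(f1)
    p_e = float((rows * cols).sum()) / total**2
    kappa = 0.0 if abs(1.0 - p_e) < 1e-15 else (acc - p_e) / (1.0 - p_e)
    return MetricsReport(
        accuracy=acc,
        f1=float(np.mean(f1s)),
        kappa=float(kappa),
        per_class=per_class,
        n=total,
    )
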