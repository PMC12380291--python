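"""Output head, classification rule, supervised loss and the five metrics.

The output head maps a pooled length-d representation to a single logit via
``Linear(ReLU(LayerNorm(r)))``; a row is called positive when the sigmoid
probability is **greater than or equal to** 0.5.  Training minimizes binary
cross-entropy evaluated in the fused logit form (``softplus(z) - y z``),
which stays finite for arbitrarily large logits and accepts soft targets in
[0, 1] (needed by Mixup).

Evaluation uses accuracy, precision, recall, F1 and AUC.  Precision,
recall and F1 return 0 on an empty denominator (the convention used when a
model never predicts the positive class).  AUC is the Mann-Whitney
concordance — the probability that a random positive is scored above a
random negative, ties counting one half — computed from midranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .autodiff import Tensor, layer_norm, softplus

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "predict_logit",
    "predict_logit_t",
    "classify",
    "bce_logit_loss",
    "bce_logit_loss_t",
    "confusion",
    "metrics_from_confusion",
    "auc",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. AUC on a single class)."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def predict_logit_t(representation: Tensor, params: Mapping[str, Tensor]) -> Tensor:
    """Batched head: LayerNorm -> ReLU -> Linear(d -> 1); returns (B,)."""
    h = layer_norm(representation, params["head/ln_g"], params["head/ln_b"]).relu()
    out = h @ params["head/w"] + params["head/b"]  # (B, 1)
    return out.reshape(out.shape[0])


def predict_logit(representation: np.ndarray, params: Mapping[str, Tensor]) -> float:
    """Scalar logit for one length-d representation."""
    rep = np.asarray(representation, dtype=np.float64)
    return float(predict_logit_t(Tensor(rep[None, :]), params).data[0])


def classify(logit: float, threshold: float = 0.5) -> int:
    """1 iff sigmoid(logit) >= threshold (the boundary is positive)."""
    prob = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
    return int(prob >= threshold)


def bce_logit_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy in the numerically stable fused form."""
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if logits.shape != y.shape:
        raise ValueError("logits and targets must have the same length")
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def bce_logit_loss_t(logits: Tensor, y: np.ndarray) -> Tensor:
    """Differentiable fused BCE; accepts soft targets in [0, 1]."""
    y_t = Tensor(np.asarray(y, dtype=np.float64))
    return (softplus(logits) - y_t * logits).mean()


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("confusion counts need binary entries")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Acc, Pre, RCL, F1); 0/0 denominators yield 0 by convention."""
    if c.total == 0:
        raise ValueError("no evaluated rows")
    acc = (c.TP + c.TN) / c.total
    pre = _safe_ratio(c.TP, c.TP + c.FP)
    rcl = _safe_ratio(c.TP, c.TP + c.FN)
    f1 = _safe_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    return acc, pre, rcl, f1


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling.

    Equals the mean over all (positive, negative) pairs of
    ``[s_pos > s_neg] + 0.5 [s_pos == s_neg]``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
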