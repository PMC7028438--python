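"""Dynamic batch-wise class-weighted cross-entropy and the joint objective.

For each mini-batch the per-class weight is recomputed from the batch's own
label composition::

    c_k = 1 - (count of class k in the batch) / M + ξ

so a class that fills the whole batch gets weight ξ (0.01 by default, which
keeps the weight away from zero), an absent class gets 1 + ξ, and rarer
classes always weigh more than common ones.  The weighted cross-entropy
sums -c_{y_j} log p_j(y_j) over the batch; L2 regularization over the
weight matrices is added once on the joint objective.  The two task losses
combine as λ·L_task1 + (1-λ)·L_task2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["BatchWeights", "LossConfig", "batch_class_weights",
           "weighted_cross_entropy", "joint_loss"]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossConfig:
    xi: float = 0.01            # additive constant keeping weights positive
    l2_lambda: float = 0.01     # L2 regularization strength
    task_lambda: float = 0.2    # weight of the coarse task in the joint loss
    dynamic_weights: bool = True

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")
        if not 0.0 <= self.task_lambda <= 1.0:
            raise ValueError("task_lambda must lie in [0, 1]")


@dataclass(frozen=True)
class BatchWeights:
    """Per-class dynamic weights for one mini-batch."""

    c: np.ndarray               # [K]
    xi: float
    batch_size: int
    num_classes: int


def batch_class_weights(labels: np.ndarray, num_classes: int,
                        xi: float = 0.01) -> BatchWeights:
    """Recompute the per-class weights from one batch's label counts."""
    labels = np.asarray(labels)
    m = labels.shape[0]
    if m < 1:
        raise ValueError("batch must contain at least one label")
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("labels out of range")
    counts = np.bincount(labels, minlength=num_classes)
    c = 1.0 - counts / m + xi
    return BatchWeights(c=c, xi=xi, batch_size=m, num_classes=num_classes)


def weighted_cross_entropy(pred_probs: Tensor | np.ndarray, labels: np.ndarray,
                           weights: BatchWeights | None = None,
                           l2_lambda: float = 0.0,
                           model_weights: list[Tensor] | None = None) -> Tensor:
    """Class-weighted cross-entropy, summed over the batch.

    ``pred_probs`` rows must be probability distributions; each instance's
    log-probability of its true class is scaled by the dynamic weight of
    that class.  Passing ``weights=None`` gives the unweighted loss.
    """
    probs = pred_probs if isinstance(pred_probs, Tensor) else Tensor(pred_probs)
    labels = np.asarray(labels)
    m, k = probs.shape
    if labels.shape[0] != m:
        raise ValueError("labels do not match batch size")
    row_sums = probs.data.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-4):
        raise ValueError("pred_probs rows must sum to 1")
    if weights is not None and weights.num_classes != k:
        raise ValueError("weight vector does not match class count")
    c = np.ones(k) if weights is None else weights.c
    picked = probs[np.arange(m), labels]                # [M]
    logp = picked.clip_min(_PROB_FLOOR).log()
    loss = -(Tensor(c[labels]) * logp).sum()
    if l2_lambda > 0 and model_weights:
        reg = Tensor(0.0)
        for w in model_weights:
            reg = reg + (w ** 2).sum()
        loss = loss + l2_lambda * reg
    return loss


def joint_loss(loss_task1: Tensor | float, loss_task2: Tensor | float,
               task_lambda: float) -> Tensor:
    """Convex combination λ·L_task1 + (1-λ)·L_task2."""
    if not 0.0 <= task_lambda <= 1.0:
        raise ValueError("task_lambda must lie in [0, 1]")
    l1 = loss_task1 if isinstance(loss_task1, Tensor) else Tensor(loss_task1)
    l2 = loss_task2 if isinstance(loss_task2, Tensor) else Tensor(loss_task2)
    return task_lambda * l1 + (1.0 - task_lambda) * l2
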