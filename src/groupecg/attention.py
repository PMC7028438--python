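"""Attention pooling over Bi-LSTM hidden sequences.

The two directions are merged additively: h_t is the sum of the forward
and backward hidden states at time t, and the *final state* F is the sum
of each direction's own terminal step (the forward pass's last time index
plus the backward pass's first-in-time index).  A bilinear score
h_t' = h_tᵀ U F is normalized with a numerically stable softmax into an
attention distribution a, and the pooled feature is the convex combination
Σ_t a_t h_t.

Every Bi-LSTM in the model — the global one and each per-lead one — owns
its own pooling instance (its own U).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .nn import Module, uniform_init

__all__ = ["AttentionResult", "AttentionPooling", "combine_directions",
           "attention_scores", "attention_distribution", "attention_pool"]


@dataclass
class AttentionResult:
    """Final state, per-step scores, attention distribution, pooled feature."""

    final_state: Tensor          # [M, Dh]
    scores: Tensor               # [M, T']
    weights: Tensor              # [M, T'], rows sum to 1
    pooled: Tensor               # [M, Dh]


def combine_directions(forward_seq: Tensor, backward_seq: Tensor
                       ) -> tuple[Tensor, Tensor]:
    """Merge directions → (h sequence [M, T', Dh], final state F [M, Dh])."""
    if forward_seq.shape != backward_seq.shape:
        raise ValueError("direction sequences must have identical shapes")
    h = forward_seq + backward_seq
    final = forward_seq[:, -1, :] + backward_seq[:, 0, :]
    return h, final


def attention_scores(h: Tensor, u: Tensor | Parameter, final_state: Tensor) -> Tensor:
    """Bilinear per-step scores h_tᵀ U F → [M, T']."""
    if u.shape[0] != u.shape[1]:
        raise ValueError("attention weight matrix U must be square")
    m, dh = final_state.shape
    projected = h @ u                                    # [M, T', Dh]
    return (projected * final_state.reshape(m, 1, dh)).sum(axis=2)


def attention_distribution(scores: Tensor) -> Tensor:
    """Softmax over time steps (shift-invariant via max subtraction)."""
    if scores.shape[-1] == 0:
        raise ValueError("empty score sequence")
    return ad.softmax(scores, axis=-1)


def attention_pool(weights: Tensor, h: Tensor) -> Tensor:
    """Convex combination Σ_t a_t h_t → [M, Dh]."""
    if weights.shape[-1] != h.shape[1]:
        raise ValueError("attention weights and hidden sequence length differ")
    m, t_len = weights.shape
    return (weights.reshape(m, t_len, 1) * h).sum(axis=1)


class AttentionPooling(Module):
    """Attention pooling for one Bi-LSTM, owning its weight matrix U."""

    def __init__(self, hidden_size: int, rng: np.random.Generator):
        self.U = Parameter(uniform_init(rng, (hidden_size, hidden_size), hidden_size))

    def __call__(self, forward_seq: Tensor, backward_seq: Tensor) -> AttentionResult:
        h, final = combine_directions(forward_seq, backward_seq)
        scores = attention_scores(h, self.U, final)
        weights = attention_distribution(scores)
        return AttentionResult(final_state=final, scores=scores,
                               weights=weights, pooled=attention_pool(weights, h))
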