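"""Grouped bidirectional LSTM with a global-context access connection.

One *global* Bi-LSTM consumes the element-wise sum of all per-lead feature
sequences and, at every time step, broadcasts its hidden state into the
gates of *n* per-lead (*intra-group*) Bi-LSTMs.  The global cell carries a
peephole on its forget gate (the gate reads the previous cell memory
C_{t-1} alongside the previous hidden state and the summed input); the
intra cells additionally read the same-direction global hidden state of the
same time step.

Gate equations, global cell (σ sigmoid, φ tanh, ⊙ elementwise product)::

    f_t = σ(W_f [C_{t-1}, h_{t-1}, Σ_i x_{i,t}] + b_f)
    i_t = σ(W_i [h_{t-1}, Σ_i x_{i,t}] + b_i)
    c̃_t = φ(W_c [h_{t-1}, Σ_i x_{i,t}] + b_c)
    C_t = f_t ⊙ C_{t-1} + i_t ⊙ c̃_t
    o_t = σ(W_o [h_{t-1}, Σ_i x_{i,t}] + b_o)
    h_t = o_t ⊙ φ(C_t)

Intra cell: identical, with gate inputs [h_{t-1}, h_g_t, x_{i,t}] (and
C_{t-1} prepended in the forget gate).  The peephole enters through the
dense weight block over the concatenated input, not a diagonal vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .nn import Module, uniform_init

__all__ = ["RecurrentConfig", "LSTMCell", "GroupOutputs", "GroupBiLSTM"]


@dataclass(frozen=True)
class RecurrentConfig:
    hidden_size: int = 64
    share_intra: bool = True
    #: extend the C_{t-1} peephole to the input and output gates as well
    full_peephole: bool = False

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")


class LSTMCell(Module):
    """A single-direction cell; ``context_size > 0`` adds the global-hidden
    input slot used by the intra-group cells."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 *, context_size: int = 0, full_peephole: bool = False):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.context_size = context_size
        self.full_peephole = full_peephole
        dh, dc = hidden_size, context_size
        base = dh + dc + input_size                 # [h_prev, (h_g), x]
        def w(rows):
            return Parameter(uniform_init(rng, (rows, dh), rows))
        self.W_f = w(dh + base)                     # forget gate reads C_{t-1}
        self.W_i = w((dh if full_peephole else 0) + base)
        self.W_c = w(base)
        self.W_o = w((dh if full_peephole else 0) + base)
        self.b_f = Parameter(np.zeros(dh))
        self.b_i = Parameter(np.zeros(dh))
        self.b_c = Parameter(np.zeros(dh))
        self.b_o = Parameter(np.zeros(dh))

    def step(self, x: Tensor, c_prev: Tensor, h_prev: Tensor,
             h_global: Tensor | None = None) -> tuple[Tensor, Tensor]:
        """One recurrence step → (C_t, h_t), each [M, hidden_size]."""
        if (h_global is not None) != (self.context_size > 0):
            raise ValueError("global-context input does not match cell configuration")
        parts = [h_prev] + ([h_global] if h_global is not None else []) + [x]
        base = ad.concat(parts, axis=1)
        with_c = ad.concat([c_prev] + parts, axis=1)
        f = ad.sigmoid(with_c @ self.W_f + self.b_f)
        gate_in = with_c if self.full_peephole else base
        i = ad.sigmoid(gate_in @ self.W_i + self.b_i)
        cand = ad.tanh(base @ self.W_c + self.b_c)
        c = f * c_prev + i * cand
        if self.full_peephole:
            o_in = ad.concat([c] + parts, axis=1)   # output gate reads C_t
        else:
            o_in = base
        o = ad.sigmoid(o_in @ self.W_o + self.b_o)
        h = o * ad.tanh(c)
        return c, h


@dataclass
class GroupOutputs:
    """Hidden sequences of one grouped pass (time-aligned in record order)."""

    global_forward: Tensor       # [M, T', Dh]
    global_backward: Tensor      # [M, T', Dh]
    intra_forward: Tensor        # [M, n, T', Dh]
    intra_backward: Tensor       # [M, n, T', Dh]

    @property
    def n_leads(self) -> int:
        return self.intra_forward.shape[1]


class GroupBiLSTM(Module):
    """One global Bi-LSTM plus n intra-group Bi-LSTMs with global access."""

    def __init__(self, input_size: int, n_leads: int, cfg: RecurrentConfig,
                 rng: np.random.Generator):
        if n_leads < 2:
            raise ValueError("need at least 2 leads")
        self.cfg = cfg
        self.n_leads = n_leads
        dh = cfg.hidden_size
        mk_global = lambda: LSTMCell(input_size, dh, rng,
                                     full_peephole=cfg.full_peephole)
        mk_intra = lambda: LSTMCell(input_size, dh, rng, context_size=dh,
                                    full_peephole=cfg.full_peephole)
        self.global_fw = mk_global()
        self.global_bw = mk_global()
        if cfg.share_intra:
            self.intra_fw = [mk_intra()]
            self.intra_bw = [mk_intra()]
        else:
            self.intra_fw = [mk_intra() for _ in range(n_leads)]
            self.intra_bw = [mk_intra() for _ in range(n_leads)]

    @property
    def n_global(self) -> int:
        """Number of global Bi-LSTMs in the module (always one)."""
        return 1

    def _zeros(self, m: int) -> Tensor:
        return Tensor(np.zeros((m, self.cfg.hidden_size)))

    def _direction(self, features: Tensor, times: range,
                   global_cell: LSTMCell, intra_cells: list[LSTMCell]
                   ) -> tuple[Tensor, Tensor]:
        m, n, t_len, d = features.shape
        dh = self.cfg.hidden_size
        shared = len(intra_cells) == 1
        c_g, h_g = self._zeros(m), self._zeros(m)
        if shared:
            c_i, h_i = self._zeros(m * n), self._zeros(m * n)
        else:
            c_i = [self._zeros(m) for _ in range(n)]
            h_i = [self._zeros(m) for _ in range(n)]
        g_seq: list[Tensor | None] = [None] * t_len
        i_seq: list[Tensor | None] = [None] * t_len
        for t in times:
            x_t = features[:, :, t, :]                       # [M, n, D]
            x_sum = x_t.sum(axis=1)                          # [M, D]
            c_g, h_g = global_cell.step(x_sum, c_g, h_g)
            # the freshly updated global hidden state enters every intra
            # cell of the same direction and time step
            if shared:
                x_flat = x_t.reshape(m * n, d)
                ctx = h_g.reshape(m, 1, dh).broadcast_to((m, n, dh)).reshape(m * n, dh)
                c_i, h_i = intra_cells[0].step(x_flat, c_i, h_i, h_global=ctx)
                i_seq[t] = h_i.reshape(m, n, 1, dh)
            else:
                outs = []
                for j in range(n):
                    c_i[j], h_i[j] = intra_cells[j].step(
                        x_t[:, j, :], c_i[j], h_i[j], h_global=h_g)
                    outs.append(h_i[j].reshape(m, 1, 1, dh))
                i_seq[t] = ad.concat(outs, axis=1)
            g_seq[t] = h_g.reshape(m, 1, dh)
        return ad.concat(g_seq, axis=1), ad.concat(i_seq, axis=2)

    def __call__(self, features: Tensor) -> GroupOutputs:
        """Run both directions over per-lead features [M, n, T', D]."""
        if features.ndim != 4:
            raise ValueError("features must be [M, n_leads, T', D]")
        if features.shape[1] != self.n_leads:
            raise ValueError(
                f"expected {self.n_leads} leads, got {features.shape[1]}")
        t_len = features.shape[2]
        g_fw, i_fw = self._direction(features, range(t_len),
                                     self.global_fw, self.intra_fw)
        g_bw, i_bw = self._direction(features, range(t_len - 1, -1, -1),
                                     self.global_bw, self.intra_bw)
        return GroupOutputs(global_forward=g_fw, global_backward=g_bw,
                            intra_forward=i_fw, intra_backward=i_bw)
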