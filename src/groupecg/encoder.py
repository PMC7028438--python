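"""Per-lead residual grouped convolutional encoder.

Each ECG lead is encoded by its own "group": a small residual network
(contraction path) followed by a multi-branch expansion whose outputs are
concatenated along the channel axis.  The number of groups always equals
the number of input leads, so the same code serves 2-lead through 12-lead
configurations.  By default the groups share parameters, which makes the
encoder equivariant under lead permutation; an independent parameter set
per lead is available via configuration.

The per-layer order is convolution → ReLU → batch normalization (the
unconventional order is deliberate and switchable to the usual
convolution → BN → ReLU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm, Conv1d, Module

__all__ = ["ResGCNNConfig", "ConvActNorm", "ResidualBlock", "ExpansionPaths",
           "LeadEncoder", "GroupedEncoder"]


@dataclass(frozen=True)
class ResGCNNConfig:
    """Encoder hyperparameters.

    ``stride_schedule`` has one entry per residual block; together with the
    stem stride it fixes the output length ``T' = ceil(L / prod(strides))``.
    """

    base_channels: int = 32
    n_res_blocks: int = 3
    bottleneck_kernels: tuple[int, int, int] = (1, 3, 1)
    dilation_rates: tuple[int, int] = (2, 3)
    pool_kernel: int = 3
    stem_kernel: int = 7
    stem_stride: int = 2
    stride_schedule: tuple[int, ...] = (1, 2, 1)
    share_across_leads: bool = True
    relu_before_norm: bool = True

    def __post_init__(self):
        if self.n_res_blocks < 1:
            raise ValueError("need at least one residual block")
        if len(self.stride_schedule) != self.n_res_blocks:
            raise ValueError("stride_schedule must have one entry per block")
        if any(s < 1 for s in self.stride_schedule) or self.stem_stride < 1:
            raise ValueError("strides must be >= 1")
        if any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")

    @property
    def out_channels(self) -> int:
        """Channels after the four-branch expansion concatenation."""
        return 4 * self.base_channels

    def output_length(self, l_win: int) -> int:
        t = -(-l_win // self.stem_stride)
        for s in self.stride_schedule:
            t = -(-t // s)
        return t


class ConvActNorm(Module):
    """Convolution followed by ReLU and batch normalization (in that order)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 *, stride: int = 1, dilation: int = 1, relu_before_norm: bool = True):
        self.conv = Conv1d(in_ch, out_ch, kernel, rng, stride=stride, dilation=dilation)
        self.norm = BatchNorm(out_ch)
        self.relu_before_norm = relu_before_norm

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.relu_before_norm:
            return self.norm(ad.relu(y))
        return ad.relu(self.norm(y))


class ResidualBlock(Module):
    """Bottleneck block: 1x1 → kx1 (optionally strided) → 1x1, plus shortcut."""

    def __init__(self, in_ch: int, out_ch: int, cfg: ResGCNNConfig,
                 rng: np.random.Generator, stride: int = 1):
        k1, k2, k3 = cfg.bottleneck_kernels
        mid = max(out_ch // 2, 1)
        order = cfg.relu_before_norm
        self.layers = [
            ConvActNorm(in_ch, mid, k1, rng, relu_before_norm=order),
            ConvActNorm(mid, mid, k2, rng, stride=stride, relu_before_norm=order),
            ConvActNorm(mid, out_ch, k3, rng, relu_before_norm=order),
        ]
        if in_ch != out_ch or stride != 1:
            self.shortcut = Conv1d(in_ch, out_ch, 1, rng, stride=stride)
        else:
            self.shortcut = None

    def __call__(self, x: Tensor) -> Tensor:
        y = x
        for layer in self.layers:
            y = layer(y)
        sc = x if self.shortcut is None else self.shortcut(x)
        return y + sc


class ExpansionPaths(Module):
    """Four parallel branches — 1x3 conv, two dilated 1x3 convs, average pool
    with a 1x1 projection — concatenated along channels (4c total)."""

    def __init__(self, in_ch: int, branch_ch: int, cfg: ResGCNNConfig,
                 rng: np.random.Generator):
        order = cfg.relu_before_norm
        d2, d3 = cfg.dilation_rates
        self.conv = ConvActNorm(in_ch, branch_ch, 3, rng, relu_before_norm=order)
        self.dilated2 = ConvActNorm(in_ch, branch_ch, 3, rng, dilation=d2,
                                    relu_before_norm=order)
        self.dilated3 = ConvActNorm(in_ch, branch_ch, 3, rng, dilation=d3,
                                    relu_before_norm=order)
        self.pool_kernel = cfg.pool_kernel
        self.pool_proj = ConvActNorm(in_ch, branch_ch, 1, rng, relu_before_norm=order)

    def __call__(self, x: Tensor) -> Tensor:
        branches = [
            self.conv(x),
            self.dilated2(x),
            self.dilated3(x),
            self.pool_proj(ad.avg_pool1d(x, self.pool_kernel)),
        ]
        lengths = {b.shape[2] for b in branches}
        if len(lengths) != 1:
            raise RuntimeError(f"expansion branch length mismatch: {lengths}")
        return ad.concat(branches, axis=1)


class LeadEncoder(Module):
    """The full contraction + expansion stack for a single lead."""

    def __init__(self, cfg: ResGCNNConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.stem = ConvActNorm(1, c, cfg.stem_kernel, rng, stride=cfg.stem_stride,
                                relu_before_norm=cfg.relu_before_norm)
        self.blocks = [
            ResidualBlock(c, c, cfg, rng, stride=s)
            for s in cfg.stride_schedule[:-1]
        ]
        # final block: bottleneck entry then the multi-branch expansion
        self.pre_expand = ResidualBlock(c, c, cfg, rng, stride=cfg.stride_schedule[-1])
        self.expansion = ExpansionPaths(c, c, cfg, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.stem(x)
        for block in self.blocks:
            y = block(y)
        y = self.pre_expand(y)
        return self.expansion(y)


class GroupedEncoder(Module):
    """One encoder group per lead; groups share parameters by default."""

    def __init__(self, cfg: ResGCNNConfig, n_leads: int, rng: np.random.Generator):
        if n_leads < 2:
            raise ValueError("need at least 2 leads")
        self.cfg = cfg
        self.n_leads = n_leads
        if cfg.share_across_leads:
            self.shared = LeadEncoder(cfg, rng)
            self.per_lead = None
        else:
            self.shared = None
            self.per_lead = [LeadEncoder(cfg, rng) for _ in range(n_leads)]

    @property
    def n_groups(self) -> int:
        """Number of per-lead encoder groups (always the lead count)."""
        return self.n_leads

    def __call__(self, x: Tensor) -> Tensor:
        """Encode a windowed batch [M, n, L] → feature maps [M, n, T', D]."""
        m, n, l_win = x.shape
        if n != self.n_leads:
            raise ValueError(f"expected {self.n_leads} leads, got {n}")
        if self.shared is not None:
            flat = x.reshape(m * n, 1, l_win)
            feats = self.shared(flat)                       # [M*n, D, T']
            d, t_out = feats.shape[1], feats.shape[2]
            return feats.reshape(m, n, d, t_out).transpose(0, 1, 3, 2)
        outs = []
        for i, enc in enumerate(self.per_lead):
            lead = x[:, i:i + 1, :]                          # [M, 1, L]
            outs.append(enc(lead))                           # [M, D, T']
        feats = ad.stack(outs, axis=1)                       # [M, n, D, T']
        return feats.transpose(0, 1, 3, 2)
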