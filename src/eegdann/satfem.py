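"""Dual-branch spatial feature extractor: graph attention + modified ResNet.

One branch reads the electrode graph (62 nodes, 5-band DE features) through
stacked graph-attention layers; the other reads the 5-channel topographic
activity map through a ResNet-style convolutional stack whose stem accepts
5 input channels (7x7 conv, stride 2, padding 4, no bias). The two branch
outputs are concatenated into a single fused feature vector.

Graph attention layer (single head). For node i with neighbourhood N(i)
(self-loop included):

    e_ij   = LeakyReLU( a^T [W h_i || W h_j] )          j in N(i)
    alpha_ij = exp(e_ij) / sum_{k in N(i)} exp(e_ik)
    h'_i   = sigma( sum_{j in N(i)} alpha_ij W h_j )

The attention rows therefore always sum to one over the neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .nn import BatchNorm2d, Conv2d, Module

__all__ = [
    "GatBranchConfig",
    "ResNetBranchConfig",
    "GALayer",
    "GatBranch",
    "BasicBlock",
    "ResNetBranch",
    "Satfem",
    "fuse",
]


@dataclass(frozen=True)
class GatBranchConfig:
    """Stacked single-head graph-attention layers over the electrode graph."""

    in_dim: int = 5
    hidden_dims: tuple[int, ...] = (32, 32)
    readout: str = "mean"  # or "flatten"
    leaky_slope: float = 0.2
    sigma: str = "elu"  # output nonlinearity of each layer

    def __post_init__(self):
        if self.readout not in ("mean", "flatten"):
            raise ValueError("readout must be 'mean' or 'flatten'")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky_slope must be in (0, 1)")
        if self.sigma not in ("elu", "relu", "identity"):
            raise ValueError("sigma must be elu, relu or identity")

    def out_dim(self, n_nodes: int) -> int:
        last = self.hidden_dims[-1] if self.hidden_dims else self.in_dim
        return last if self.readout == "mean" else last * n_nodes


@dataclass(frozen=True)
class ResNetBranchConfig:
    """Stem + 4 stages x 2 basic blocks on the 5-channel activity map."""

    in_channels: int = 5
    conv1_out: int = 64
    conv1_kernel: int = 7
    conv1_stride: int = 2
    conv1_padding: int = 4
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    composite_shortcut: bool = False  # Conv3x3->Conv1x1->BN shortcut on every block

    def __post_init__(self):
        if len(self.stage_widths) != 4:
            raise ValueError("exactly 4 stages required")

    @property
    def out_dim(self) -> int:
        return self.stage_widths[-1]


def _apply_sigma(x: Tensor, sigma: str) -> Tensor:
    if sigma == "elu":
        return x.elu()
    if sigma == "relu":
        return x.relu()
    return x


class GALayer(Module):
    """One graph-attention layer; vectorised over a batch of graphs that
    share a single adjacency."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 leaky_slope: float = 0.2, sigma: str = "elu"):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Tensor(rng.uniform(-limit, limit, size=(out_dim, in_dim)),
                        requires_grad=True)
        self.a = Tensor(rng.uniform(-limit, limit, size=2 * out_dim),
                        requires_grad=True)
        self.out_dim = out_dim
        self.leaky_slope = leaky_slope
        self.sigma = sigma

    def attention(self, h: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Return (alpha, Wh). ``h``: (..., V, d_in); ``mask``: (V, V) bool."""
        wh = h @ self.W.transpose()  # (..., V, d_out)
        a_src = self.a[: self.out_dim]
        a_dst = self.a[self.out_dim :]
        f = wh @ a_src.reshape(self.out_dim, 1)  # (..., V, 1): term from W h_i
        g = wh @ a_dst.reshape(self.out_dim, 1)  # (..., V, 1): term from W h_j
        logits = (f + g.transpose(*range(g.ndim - 2), g.ndim - 1, g.ndim - 2)
                  if g.ndim > 2 else f + g.transpose())
        logits = logits.leaky_relu(self.leaky_slope)
        alpha = logits.masked_softmax(mask, axis=-1)
        return alpha, wh

    def forward(self, h: Tensor, mask: np.ndarray) -> Tensor:
        alpha, wh = self.attention(h, mask)
        return _apply_sigma(alpha @ wh, self.sigma)


class GatBranch(Module):
    def __init__(self, cfg: GatBranchConfig, rng: np.random.Generator, n_nodes: int = 62):
        super().__init__()
        self.cfg = cfg
        self.n_nodes = n_nodes
        dims = [cfg.in_dim, *cfg.hidden_dims]
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            setattr(self, f"gal{i}",
                    GALayer(din, dout, rng, cfg.leaky_slope, cfg.sigma))
        self.n_layers = len(dims) - 1

    def forward(self, node_features: Tensor, adjacency: np.ndarray) -> Tensor:
        """``node_features``: (N, V, 5) batch; returns (N, out_dim)."""
        mask = np.asarray(adjacency) > 0
        h = node_features
        for i in range(self.n_layers):
            h = getattr(self, f"gal{i}")(h, mask)
        if self.cfg.readout == "mean":
            return h.mean(axis=-2)
        return h.reshape(h.shape[0], -1)

    @property
    def out_dim(self) -> int:
        return self.cfg.out_dim(self.n_nodes)


class BasicBlock(Module):
    """Two 3x3 conv/BN stages plus a shortcut, summed and ReLU'd.

    Default shortcut: identity when shapes match, otherwise a stride-matched
    1x1 conv + BN projection. ``composite_shortcut`` instead applies the variant
    BN(Conv1x1(Conv3x3(x))) on every block.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator, composite_shortcut: bool = False):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm2d(out_ch)
        self.composite_shortcut = composite_shortcut
        self.needs_projection = stride != 1 or in_ch != out_ch
        if composite_shortcut:
            self.sc_conv3 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
            self.sc_conv1 = Conv2d(out_ch, out_ch, 1, rng, stride=1, padding=0)
            self.sc_bn = BatchNorm2d(out_ch)
        elif self.needs_projection:
            self.sc_conv1 = Conv2d(in_ch, out_ch, 1, rng, stride=stride, padding=0)
            self.sc_bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        main = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        if self.composite_shortcut:
            shortcut = self.sc_bn(self.sc_conv1(self.sc_conv3(x)))
        elif self.needs_projection:
            shortcut = self.sc_bn(self.sc_conv1(x))
        else:
            shortcut = x
        return (main + shortcut).relu()


class ResNetBranch(Module):
    """Stem conv -> 4 stages of basic blocks -> global average pool.

    Stage entries use stride 2, except stages 3 and 4 fall back to stride 1
    when the incoming spatial extent is already <= 3, so the 9x9 scalp grid
    (3x3 after the stem) never collapses below 1x1.
    """

    def __init__(self, cfg: ResNetBranchConfig, rng: np.random.Generator,
                 input_hw: tuple[int, int] = (9, 9)):
        super().__init__()
        self.cfg = cfg
        self.conv1 = Conv2d(cfg.in_channels, cfg.conv1_out, cfg.conv1_kernel,
                            rng, stride=cfg.conv1_stride, padding=cfg.conv1_padding)
        self.bn1 = BatchNorm2d(cfg.conv1_out)

        def conv_out(s, k, st, p):
            return (s + 2 * p - k) // st + 1

        h = conv_out(input_hw[0], cfg.conv1_kernel, cfg.conv1_stride, cfg.conv1_padding)
        h = conv_out(h, 3, 2, 1)  # maxpool k3 s2 p1
        in_ch = cfg.conv1_out
        self.stage_strides: list[int] = []
        blocks = []
        for stage, width in enumerate(cfg.stage_widths):
            stride = 1 if stage == 0 else 2
            if stage >= 2 and h <= 3:
                stride = 1
            self.stage_strides.append(stride)
            for b in range(cfg.blocks_per_stage):
                blocks.append(BasicBlock(in_ch, width, stride if b == 0 else 1,
                                         rng, cfg.composite_shortcut))
                in_ch = width
            h = conv_out(h, 3, stride, 1)
            if h < 1:
                raise ValueError("spatial size collapsed below 1x1; adjust strides")
        for i, blk in enumerate(blocks):
            setattr(self, f"block{i}", blk)
        self.n_blocks = len(blocks)

    def stem(self, x: Tensor) -> Tensor:
        """Stem: Conv7x7 -> BN -> ReLU -> MaxPool(3, stride 2, pad 1)."""
        return self.bn1(self.conv1(x)).relu().maxpool2d(3, 2, 1)

    def forward(self, x: Tensor) -> Tensor:
        """``x``: (N, 5, H, W) channels-first maps; returns (N, out_dim)."""
        h = self.stem(x)
        for i in range(self.n_blocks):
            h = getattr(self, f"block{i}")(h)
        return h.mean(axis=(2, 3))  # global average pool

    @property
    def out_dim(self) -> int:
        return self.cfg.out_dim


def fuse(x1: Tensor, x2: Tensor) -> Tensor:
    """Concatenate branch outputs, activity branch first (axis -1)."""
    return concat([x1, x2], axis=-1)


class Satfem(Module):
    """The fused dual-branch extractor; either branch can be disabled for
    ablations (at least one must stay on)."""

    def __init__(
        self,
        rng: np.random.Generator,
        gat_cfg: GatBranchConfig | None = None,
        resnet_cfg: ResNetBranchConfig | None = None,
        use_activity: bool = True,
        use_topology: bool = True,
        n_nodes: int = 62,
        input_hw: tuple[int, int] = (9, 9),
    ):
        super().__init__()
        if not (use_activity or use_topology):
            raise ValueError("at least one branch must be enabled")
        self.use_activity = use_activity
        self.use_topology = use_topology
        # always consume the rng in a fixed order so configs are comparable
        rng_act = np.random.default_rng(rng.integers(2**31))
        rng_top = np.random.default_rng(rng.integers(2**31))
        if use_activity:
            self.resnet = ResNetBranch(resnet_cfg or ResNetBranchConfig(), rng_act, input_hw)
        if use_topology:
            self.gat = GatBranch(gat_cfg or GatBranchConfig(), rng_top, n_nodes)

    def forward(self, maps: Tensor | None, node_features: Tensor | None,
                adjacency: np.ndarray | None) -> Tensor:
        outs = []
        if self.use_activity:
            outs.append(self.resnet(maps))
        if self.use_topology:
            outs.append(self.gat(node_features, adjacency))
        return outs[0] if len(outs) == 1 else fuse(outs[0], outs[1])

    @property
    def out_dim(self) -> int:
        dim = 0
        if self.use_activity:
            dim += self.resnet.out_dim
        if self.use_topology:
            dim += self.gat.out_dim
        return dim
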