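"""Dual-path attention-gated U-shaped segmentation network.

The architecture has four distinguishing pieces:

* **ResidualConvBlock** — a 1x1 channel projection followed by two additive
  residual units ``u(x) = ReLU(BN(Conv3x3(x))) + x``; the block output is the
  *sum of both residual-unit outputs* (x1 + x2), not the last one alone.
* **Dual-path encoder** — path 1 alternates blocks and 2x2 max pooling;
  path 2 repeatedly max-pools the raw input stack and concatenates it with
  path 1's pooled features to form the next level's block input.
* **Attention-gated skips** — each skip feature map is reweighted by a
  sigmoid-bounded spatial map computed from the skip and the coarser decoder
  feature (additive attention).
* **Dual-path decoder** — path 1 mirrors the encoder (bilinear upsample +
  1x1 projection, gated skip concat, block); path 2 upsamples the previous
  level's fused output and concatenates it with the path-1 result.

Input is a 2.5D stack ``(k, H, W)``; output is ``(num_classes, H, W)``
scores for the middle slice.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import tensor as T
from .slicing import SliceStack, SliceTarget

MAX_WIDTH = 512


@dataclass
class NetworkConfig:
    in_channels: int = 3          # k of the 2.5D stack
    num_classes: int = 2
    depth: int = 5                # number of resolution levels
    base_width: int = 16          # channels at the top level
    block_type: str = "resconv"   # "resconv" or "plain"
    attention: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.block_type not in ("resconv", "plain"):
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.in_channels < 1 or self.in_channels % 2 == 0:
            raise ValueError("in_channels (stack depth k) must be a positive odd integer")

    def width(self, level: int) -> int:
        return min(self.base_width * (2 ** level), MAX_WIDTH)

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class ResidualConvBlock(nn.Module):
    """1x1 projection + two residual units; output = x1 + x2.

    With the 3x3 convolution parameters zeroed and batch-norm in identity
    mode, the residual units pass their input through unchanged, so the block
    reduces exactly to ``2 * Conv1x1(input)``.
    """

    def __init__(self, in_channels: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, width, 1, rng=rng)
        self.conv1 = nn.Conv2d(width, width, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.out_channels = width

    def forward(self, x: T.Tensor) -> T.Tensor:
        x0 = self.proj(x)
        x1 = T.add(T.relu(self.bn1(self.conv1(x0))), x0)
        x2 = T.add(T.relu(self.bn2(self.conv2(x1))), x1)
        return T.add(x1, x2)


class PlainConvBlock(nn.Module):
    """The conventional double (Conv3x3 + BN + ReLU) block (ablation)."""

    def __init__(self, in_channels: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, width, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.out_channels = width

    def forward(self, x: T.Tensor) -> T.Tensor:
        h = T.relu(self.bn1(self.conv1(x)))
        return T.relu(self.bn2(self.conv2(h)))


BLOCK_TYPES = {"resconv": ResidualConvBlock, "plain": PlainConvBlock}


class AttentionGate(nn.Module):
    """Additive attention on a skip connection.

    ``x_l`` is the encoder (skip) feature at full level extent; ``g`` is the
    decoder gating feature at half that extent (or equal, when
    ``gate_factor=1``).  Both are projected to a shared intermediate width at
    the gating extent, summed (A + B = C), passed through ReLU (D), projected
    to one channel (E), squashed by a sigmoid (F), and the resulting map is
    bilinearly resampled back to x_l's extent to give the weights alpha.
    The gate returns ``alpha * x_l`` broadcast over channels.

    With all gate parameters zero, E = 0 everywhere, so alpha = 0.5 and the
    gate is a constant 0.5 multiplier.
    """

    def __init__(self, skip_channels: int, gate_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None,
                 gate_factor: int = 2):
        super().__init__()
        if gate_factor not in (1, 2):
            raise ValueError("gate_factor must be 1 or 2")
        inter = inter_channels or max(skip_channels // 2, 1)
        self.theta_x = nn.Conv2d(skip_channels, inter, 1, rng=rng)
        self.phi_g = nn.Conv2d(gate_channels, inter, 1, rng=rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng=rng)
        self.gate_factor = gate_factor

    def forward(self, x_l: T.Tensor, g: T.Tensor) -> T.Tensor:
        xs, gs = x_l.shape[2:], g.shape[2:]
        if tuple(xs) != tuple(s * self.gate_factor for s in gs):
            raise ValueError(
                f"attention gate expects skip extent = {self.gate_factor} x gate extent, "
                f"got skip {tuple(xs)} vs gate {tuple(gs)}")
        b_in = T.maxpool2x(x_l) if self.gate_factor == 2 else x_l
        a = self.phi_g(g)
        b = self.theta_x(b_in)
        c = T.add(a, b)
        d = T.relu(c)
        e = self.psi(d)
        f = T.sigmoid(e)
        alpha = T.resize_bilinear(f, tuple(xs))
        return T.mul(alpha, x_l)

    def attention_map(self, x_l, g) -> np.ndarray:
        """The alpha weights alone (for inspection/tests)."""
        x_l, g = T.astensor(x_l), T.astensor(g)
        b_in = T.maxpool2x(x_l) if self.gate_factor == 2 else x_l
        f = T.sigmoid(self.psi(T.relu(T.add(self.phi_g(g), self.theta_x(b_in)))))
        return T.resize_bilinear(f, tuple(x_l.shape[2:])).data


class DualPathAttentionUNet(nn.Module):
    """See module docstring.  Operates on NCHW tensors with C = k."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        block_cls = BLOCK_TYPES[config.block_type]
        k = config.in_channels
        d = config.depth

        # encoder path 1 blocks; level i > 0 consumes pooled path-1 features
        # concatenated with the pooled raw-input stream (k extra channels)
        self.enc_blocks = []
        for lvl in range(d):
            cin = k if lvl == 0 else config.width(lvl - 1) + k
            self.enc_blocks.append(block_cls(cin, config.width(lvl), rng))

        # decoder: fused-stream channel bookkeeping (path-2 carries the
        # previous level's fused output)
        fused = config.width(d - 1)
        self.up_projs = []
        self.gates = []
        self.dec_blocks = []
        self._fused_channels = [0] * d
        self._fused_channels[d - 1] = fused
        for lvl in range(d - 2, -1, -1):
            w = config.width(lvl)
            self.up_projs.append(nn.Conv2d(fused, w, 1, rng=rng))
            if config.attention:
                self.gates.append(AttentionGate(w, fused, rng=rng))
            self.dec_blocks.append(block_cls(2 * w, w, rng))
            fused = w + fused  # block output ++ upsampled previous fused stream
            self._fused_channels[lvl] = fused
        self.head = nn.Conv2d(fused, config.num_classes, 1, rng=rng)

    # -- spec surface ---------------------------------------------------------
    def _check_extent(self, h: int, w: int) -> None:
        div = self.config.divisor
        if h % div or w % div:
            raise ValueError(
                f"spatial extent {(h, w)} not divisible by 2^(depth-1) = {div}")

    def encode(self, x: T.Tensor):
        """Return (per-level skip features, bottleneck features)."""
        x = T.astensor(x)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}")
        self._check_extent(*x.shape[2:])
        feats = []
        raw = x
        h = self.enc_blocks[0](x)
        feats.append(h)
        for lvl in range(1, self.config.depth):
            raw = T.maxpool2x(raw)
            h = T.concat([T.maxpool2x(h), raw], axis=1)
            h = self.enc_blocks[lvl](h)
            feats.append(h)
        return feats[:-1], feats[-1]

    def decode(self, skips, bottleneck) -> T.Tensor:
        d = self.config.depth
        if len(skips) != d - 1:
            raise ValueError(f"expected {d - 1} skip levels, got {len(skips)}")
        fused = bottleneck
        for i, lvl in enumerate(range(d - 2, -1, -1)):
            skip = skips[lvl]
            up = self.up_projs[i](T.upsample2x(fused))
            if up.shape[2:] != skip.shape[2:]:
                raise ValueError("skip/decoder extent mismatch: config does not match encoder")
            if self.config.attention:
                skip = self.gates[i](skip, fused)
            block_out = self.dec_blocks[i](T.concat([up, skip], axis=1))
            fused = T.concat([block_out, T.upsample2x(fused)], axis=1)
        return self.head(fused)

    def forward(self, x: T.Tensor) -> T.Tensor:
        skips, bottleneck = self.encode(x)
        return self.decode(skips, bottleneck)

    # -- inference -------------------------------------------------------------
    def predict_batch(self, batch: np.ndarray) -> np.ndarray:
        """Argmax class indices for a (N, k, H, W) batch (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(T.Tensor(batch)).data
        finally:
            self.train(was_training)
        return logits.argmax(axis=1).astype(np.int16)

    def predict_slice(self, stack: SliceStack) -> SliceTarget:
        """Per-pixel argmax mask for one 2.5D stack."""
        mask = self.predict_batch(stack.channels[None])[0]
        return SliceTarget(mask=mask, center_index=stack.center_index)
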