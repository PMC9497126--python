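"""Fully convolutional DenseNet for CBCT -> synthetic-CT slice translation.

The network follows the FC-DenseNet family: an initial convolution, a
down-sampling path of dense blocks each followed by a transition-down
(batch norm, ELU, 1x1 convolution, dropout p=0.2, 2x2 max-pooling), a
bottleneck dense block, and an up-sampling path of transition-ups
(transposed convolution) each followed by a dense block that concatenates
the skip feature maps from the matching down-path resolution. A final 1x1
convolution maps to the output channel count.

Dense-layer internals are BN -> ELU -> 3x3 conv -> dropout; each layer adds
``growth_rate`` feature maps to the running concatenation. Only the newly
created feature maps of a block are upsampled (keeping the parameter count
bounded), except at the last block whose full concatenation feeds the final
convolution.

Inputs whose side length is not divisible by ``2**n_pool`` (e.g. 270 with
five poolings) are reflect-padded to the next multiple and cropped back
after the forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    Dropout,
    ELU,
    MaxPool2x2,
    Module,
    Tensor,
    concat,
)

__all__ = ["NetworkConfig", "FCDenseNet", "build_network"]


@dataclass
class NetworkConfig:
    n_pool: int = 5
    growth_rate: int = 12
    layers_per_block: int | tuple[int, ...] = 4
    first_channels: int = 48
    dropout_p: float = 0.2
    in_channels: int = 1
    out_channels: int = 1
    residual: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_pool < 1:
            raise ValueError("n_pool must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.growth_rate < 1 or self.first_channels < 1:
            raise ValueError("growth_rate and first_channels must be >= 1")
        n_blocks = 2 * self.n_pool + 1
        if isinstance(self.layers_per_block, int):
            self.layers_per_block = (self.layers_per_block,) * n_blocks
        elif len(self.layers_per_block) != n_blocks:
            raise ValueError(f"layers_per_block needs {n_blocks} entries")

    @classmethod
    def tiny(cls, **kw) -> "NetworkConfig":
        """CPU-friendly preset: n_pool 2, growth 8, 3 layers per block."""
        kw.setdefault("n_pool", 2)
        kw.setdefault("growth_rate", 8)
        kw.setdefault("layers_per_block", 3)
        kw.setdefault("first_channels", 16)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "n_pool": self.n_pool,
            "growth_rate": self.growth_rate,
            "layers_per_block": list(self.layers_per_block),
            "first_channels": self.first_channels,
            "dropout_p": self.dropout_p,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "residual": self.residual,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["layers_per_block"] = tuple(d["layers_per_block"])
        return cls(**d)


class DenseLayer(Module):
    """BN -> ELU -> 3x3 conv -> dropout, producing `growth` new feature maps."""

    def __init__(self, cin, growth, p, rng, drop_rng):
        super().__init__()
        self.norm = BatchNorm2d(cin)
        self.act = ELU()
        self.conv = Conv2d(cin, growth, 3, rng)
        self.drop = Dropout(p, drop_rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.conv(self.act(self.norm(x))))


class DenseBlock(Module):
    def __init__(self, cin, growth, n_layers, p, rng, drop_rng):
        super().__init__()
        self.layers = []
        c = cin
        for i in range(n_layers):
            layer = DenseLayer(c, growth, p, rng, drop_rng)
            self._children[f"layer{i}"] = layer
            self.layers.append(layer)
            c += growth
        self.out_channels = c
        self.new_channels = growth * n_layers

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (full concatenation incl. input, new feature maps only)."""
        feats = [x]
        new = []
        for layer in self.layers:
            y = layer(concat(feats, axis=1) if len(feats) > 1 else feats[0])
            feats.append(y)
            new.append(y)
        return concat(feats, axis=1), concat(new, axis=1) if len(new) > 1 else new[0]


class TransitionDown(Module):
    """BN, ELU, 1x1 conv, dropout (p=0.2), 2x2 max-pool — in that order."""

    def __init__(self, c, p, rng, drop_rng):
        super().__init__()
        self.norm = BatchNorm2d(c)
        self.act = ELU()
        self.conv = Conv2d(c, c, 1, rng)
        self.drop = Dropout(p, drop_rng)
        self.pool = MaxPool2x2()

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.drop(self.conv(self.act(self.norm(x)))))


class FCDenseNet(Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        # dropout stochasticity is owned by a separate, reseedable stream
        self.drop_rng = np.random.default_rng([cfg.seed, 0xD0])
        lp = cfg.layers_per_block
        g = cfg.growth_rate

        self.first_conv = Conv2d(cfg.in_channels, cfg.first_channels, 3, rng)
        c = cfg.first_channels
        self.down_blocks, self.downs, self.skip_channels = [], [], []
        for i in range(cfg.n_pool):
            blk = DenseBlock(c, g, lp[i], cfg.dropout_p, rng, self.drop_rng)
            c = blk.out_channels
            td = TransitionDown(c, cfg.dropout_p, rng, self.drop_rng)
            self._children[f"down_block{i}"] = blk
            self._children[f"td{i}"] = td
            self.down_blocks.append(blk)
            self.downs.append(td)
            self.skip_channels.append(c)

        self.bottleneck = DenseBlock(c, g, lp[cfg.n_pool], cfg.dropout_p, rng,
                                     self.drop_rng)
        up_in = self.bottleneck.new_channels

        self.ups, self.up_blocks = [], []
        for i in range(cfg.n_pool):
            skip_c = self.skip_channels[cfg.n_pool - 1 - i]
            tu = ConvTranspose2x2(up_in, up_in, rng)
            blk = DenseBlock(up_in + skip_c, g, lp[cfg.n_pool + 1 + i],
                             cfg.dropout_p, rng, self.drop_rng)
            self._children[f"tu{i}"] = tu
            self._children[f"up_block{i}"] = blk
            self.ups.append(tu)
            self.up_blocks.append(blk)
            up_in = blk.new_channels
        self.final_conv = Conv2d(self.up_blocks[-1].out_channels, cfg.out_channels,
                                 1, rng)
        if cfg.residual:
            # zero-initialised correction head: the residual network starts
            # exactly at the identity mapping
            self.final_conv.w.data[:] = 0.0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x: Tensor, auto_pad: bool = True) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, np.float32))
        if x.ndim != 4:
            raise ValueError("expected (N, C, H, W) input")
        div = 2**self.cfg.n_pool
        h, w = x.shape[2], x.shape[3]
        pad_h = (-h) % div
        pad_w = (-w) % div
        if (pad_h or pad_w) and not auto_pad:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^n_pool = {div}; "
                "enable auto_pad or resize the input"
            )
        x_in = x
        if pad_h or pad_w:
            x = x.pad2d((0, pad_h, 0, pad_w), mode="reflect")

        y = self.first_conv(x)
        skips = []
        for blk, td in zip(self.down_blocks, self.downs):
            full, _ = blk(y)
            skips.append(full)
            y = td(full)
        _, new = self.bottleneck(y)
        for i, (tu, blk) in enumerate(zip(self.ups, self.up_blocks)):
            up = tu(new)
            skip = skips[self.cfg.n_pool - 1 - i]
            if up.shape[2:] != skip.shape[2:]:
                raise AssertionError("skip connection resolution mismatch")
            full, new = blk(concat([skip, up], axis=1))
        out = self.final_conv(full)
        if pad_h or pad_w:
            out = out[:, :, :h, :w]
        if self.cfg.residual:
            out = out + x_in
        return out


def build_network(cfg: NetworkConfig) -> FCDenseNet:
    """Construct the translation network from its configuration."""
    return FCDenseNet(cfg)
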