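"""One-dimensional densely connected convolutional backbone.

Each dense layer computes BN -> ReLU -> 1x1 bottleneck conv -> BN -> ReLU
-> width-``conv_kernel`` conv producing ``k`` (the growth rate) new
feature maps, which are concatenated onto the layer's input.  Inside a
block every convolution has stride 1 and same-padding, so the time axis
is untouched and the channel count entering layer ``l`` of a block whose
input had ``c0`` channels is exactly ``c0 + k * (l - 1)``.

Blocks are joined by transition layers (BN -> ReLU -> 1x1 conv halving the
channels -> non-overlapping 1x2 average pooling), which keep the model
small while the receptive field grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import AvgPool1d, BatchNorm1d, Conv1d, Module, ReLU

__all__ = [
    "DenseNetConfig",
    "expected_channels",
    "DenseLayer",
    "DenseBlock",
    "TransitionLayer",
    "DenseNet1d",
]


@dataclass(frozen=True)
class DenseNetConfig:
    """Backbone hyperparameters.

    ``k`` is the growth rate (new maps per dense layer); ``k0`` the channel
    count out of the stem convolution; ``compression`` the channel fraction
    kept by each transition (0.5 halves it); ``bottleneck_factor`` times
    ``k`` is the 1x1 bottleneck width.
    """

    k0: int = 24
    k: int = 12
    num_blocks: int = 3
    layers_per_block: int = 8
    bottleneck_factor: int = 4
    compression: float = 0.5
    conv_kernel: int = 3
    initial_kernel: int = 7
    initial_stride: int = 2

    def __post_init__(self) -> None:
        for name in ("k0", "k", "num_blocks", "layers_per_block", "bottleneck_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 < self.compression <= 1:
            raise ValueError(f"compression must lie in (0, 1], got {self.compression}")
        for name in ("conv_kernel", "initial_kernel"):
            if getattr(self, name) % 2 != 1:
                raise ValueError(f"{name} must be odd, got {getattr(self, name)}")
        if self.initial_stride < 1:
            raise ValueError(f"initial_stride must be >= 1, got {self.initial_stride}")


def expected_channels(k0: int, k: int, l: int) -> int:
    """Channels entering dense layer ``l`` (1-based) of a block whose input had ``k0``."""
    if l < 1:
        raise ValueError(f"layer index l must be >= 1, got {l}")
    return k0 + k * (l - 1)


class DenseLayer(Module):
    """BN-ReLU-conv1x1(bottleneck)-BN-ReLU-conv(k); output = [input || new maps]."""

    def __init__(self, in_channels: int, config: DenseNetConfig,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        bottleneck = config.bottleneck_factor * config.k
        self.in_channels = in_channels
        self.out_channels = in_channels + config.k
        self.bn1 = BatchNorm1d(in_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv1 = Conv1d(in_channels, bottleneck, kernel=1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm1d(bottleneck, dtype=dtype)
        self.relu2 = ReLU()
        self.conv2 = Conv1d(bottleneck, config.k, kernel=config.conv_kernel, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv1(self.relu1(self.bn1(x)))
        new = self.conv2(self.relu2(self.bn2(h)))
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("non-finite activations in dense layer")
        return np.concatenate([x, new], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx_direct = dy[:, : self.in_channels]
        dnew = dy[:, self.in_channels :]
        dh = self.bn2.backward(self.relu2.backward(self.conv2.backward(dnew)))
        dx = self.bn1.backward(self.relu1.backward(self.conv1.backward(dh)))
        return dx + dx_direct


class DenseBlock(Module):
    def __init__(self, in_channels: int, config: DenseNetConfig,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.layers = []
        c = in_channels
        for _ in range(config.layers_per_block):
            layer = DenseLayer(c, config, rng, dtype=dtype)
            self.layers.append(layer)
            c = layer.out_channels
        self.out_channels = c

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class TransitionLayer(Module):
    """BN-ReLU-1x1 conv (channel compression) then 1x2 average pooling."""

    def __init__(self, in_channels: int, config: DenseNetConfig,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.out_channels = int(np.floor(config.compression * in_channels))
        self.bn = BatchNorm1d(in_channels, dtype=dtype)
        self.relu = ReLU()
        self.conv = Conv1d(in_channels, self.out_channels, kernel=1, rng=rng, dtype=dtype)
        self.pool = AvgPool1d()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] < 2:
            raise ValueError(f"transition needs time_steps >= 2, got {x.shape[2]}")
        return self.pool(self.conv(self.relu(self.bn(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.bn.backward(self.relu.backward(self.conv.backward(self.pool.backward(dy))))


class DenseNet1d(Module):
    """Stem convolution followed by ``num_blocks`` (dense block -> transition) pairs."""

    def __init__(self, config: DenseNetConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        self.config = config or DenseNetConfig()
        rng = rng or np.random.default_rng(0)
        cfg = self.config
        self.stem = Conv1d(1, cfg.k0, kernel=cfg.initial_kernel, stride=cfg.initial_stride,
                           rng=rng, dtype=dtype)
        self.blocks: list[DenseBlock] = []
        self.transitions: list[TransitionLayer] = []
        c = cfg.k0
        for _ in range(cfg.num_blocks):
            block = DenseBlock(c, cfg, rng, dtype=dtype)
            self.blocks.append(block)
            trans = TransitionLayer(block.out_channels, cfg, rng, dtype=dtype)
            self.transitions.append(trans)
            c = trans.out_channels
        self.out_channels = c

    @property
    def min_input_len(self) -> int:
        return (2 ** self.config.num_blocks) * self.config.initial_stride

    def out_time(self, input_len: int) -> int:
        t = self.stem.out_time(input_len)
        for _ in range(self.config.num_blocks):
            t //= 2
        return t

    def forward(self, x: np.ndarray) -> np.ndarray:
        """``x`` is (batch, 1, time) or (batch, time); returns (batch, channels, time')."""
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] < self.min_input_len:
            raise ValueError(
                f"segment length {x.shape[2]} below the minimum {self.min_input_len} "
                f"for {self.config.num_blocks} blocks at stride {self.config.initial_stride}"
            )
        h = self.stem(x)
        for block, trans in zip(self.blocks, self.transitions):
            h = trans(block(h))
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for block, trans in zip(reversed(self.blocks), reversed(self.transitions)):
            dy = block.backward(trans.backward(dy))
        return self.stem.backward(dy)

    def summary(self, input_len: int) -> list[dict]:
        """Per-layer channel/time accounting — the audit surface for the
        c0 + k*(l-1) bookkeeping."""
        cfg = self.config
        rows = []
        t = self.stem.out_time(input_len)
        rows.append({"name": "stem_conv", "in_channels": 1, "out_channels": cfg.k0,
                     "time_steps": t})
        c = cfg.k0
        for b, (block, trans) in enumerate(zip(self.blocks, self.transitions), start=1):
            block_in = c
            for l, layer in enumerate(block.layers, start=1):
                rows.append({
                    "name": f"block{b}_dense{l}",
                    "in_channels": layer.in_channels,
                    "out_channels": layer.out_channels,
                    "time_steps": t,
                    "expected_in_channels": expected_channels(block_in, cfg.k, l),
                })
                c = layer.out_channels
            t //= 2
            rows.append({"name": f"transition{b}", "in_channels": c,
                         "out_channels": trans.out_channels, "time_steps": t})
            c = trans.out_channels
        return rows
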