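"""Minimal 1-D neural-network layers with explicit forward/backward passes.

Arrays are ``(batch, channels, time)``; each layer caches exactly what its
backward pass needs and releases it afterwards.  Gradients accumulate into
``.grads`` (zeroed by the optimizer step).  Correctness of every backward
pass is pinned by finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Module", "Conv1d", "BatchNorm1d", "ReLU", "AvgPool1d", "Linear"]


class Module:
    """Base class: parameter discovery, train/eval mode, recursion."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    # -- traversal -------------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def named_parameters(self) -> Iterator[tuple[str, "Module", str]]:
        seen = 0
        for mod in self.modules():
            for key in mod.params:
                yield f"{type(mod).__name__}{seen}.{key}", mod, key
            seen += 1

    def n_parameters(self) -> int:
        return sum(mod.params[k].size for _, mod, k in self.named_parameters())

    def zero_grad(self) -> None:
        for mod in self.modules():
            for key, val in mod.params.items():
                mod.grads[key] = np.zeros_like(val)

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- interface -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv1d(Module):
    """1-D convolution (cross-correlation) with symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if pad is None:
            pad = (kernel - 1) // 2  # "same" for odd kernels at stride 1
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_channels * kernel))  # He init for ReLU stacks
        self.params = {
            "W": (rng.standard_normal((out_channels, in_channels, kernel)) * scale).astype(dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }
        self._xp: np.ndarray | None = None
        self._in_time = 0
        # reused scratch buffers (forward / backward): avoids realloc churn
        self._zbuf: dict[str, np.ndarray] = {}

    def out_time(self, t: int) -> int:
        return (t + 2 * self.pad - self.kernel) // self.stride + 1

    def _scratch(self, tag: str, shape, dtype) -> np.ndarray:
        buf = self._zbuf.get(tag)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            self._zbuf[tag] = buf
        return buf

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, t = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        self._in_time = t
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        self._xp = xp
        t_out = self.out_time(t)
        w = self.params["W"]
        # one channel-mixing matmul per kernel tap over the full padded length
        # (contiguous operands), then shifted accumulation: no im2col copies
        y = np.zeros((n, self.out_channels, t_out), dtype=w.dtype)
        z = self._scratch("fwd", (n, self.out_channels, xp.shape[2]), w.dtype)
        for k in range(self.kernel):
            np.matmul(w[:, :, k], xp, out=z)
            y += z[:, :, k : k + self.stride * t_out : self.stride]
        y += self.params["b"][None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward before forward"
        n, _, t_out = dy.shape
        w = self.params["W"]
        self.grads["b"] += dy.sum(axis=(0, 2))
        t_pad = self._in_time + 2 * self.pad
        dxp = np.zeros((n, self.in_channels, t_pad), dtype=dy.dtype)
        z = self._scratch("bwd", (n, self.in_channels, t_out), dy.dtype)
        for k in range(self.kernel):
            sl = xp[:, :, k : k + self.stride * t_out : self.stride]
            self.grads["W"][:, :, k] += np.matmul(dy, sl.transpose(0, 2, 1)).sum(axis=0)
            np.matmul(w[:, :, k].T, dy, out=z)
            dxp[:, :, k : k + self.stride * t_out : self.stride] += z
        self._xp = None
        return dxp[:, :, self.pad : self.pad + self._in_time] if self.pad else dxp


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, time); eps guards zero variance."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32) -> None:
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._x: np.ndarray | None = None
        self._mean: np.ndarray | None = None
        self._ivar: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            m = x.shape[0] * x.shape[2]
            mean = x.mean(axis=(0, 2))
            # E[x^2] - E[x]^2 via a single contraction; clipped against
            # cancellation for (near-)constant channels
            m2 = np.einsum("nct,nct->c", x, x) / m
            var = np.maximum(m2 - mean * mean, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        # fused affine y = a*x + c with a = gamma*ivar, c = beta - a*mean
        a = self.params["gamma"] * ivar
        c = self.params["beta"] - a * mean
        y = x * a[None, :, None]
        y += c[None, :, None]
        if self.training:
            self._x, self._mean, self._ivar = x, mean, ivar
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mean, ivar = self._x, self._mean, self._ivar
        assert x is not None, "backward before training forward"
        m = dy.shape[0] * dy.shape[2]
        xhat = x - mean[None, :, None].astype(x.dtype)
        xhat *= ivar[None, :, None]
        dgamma = np.einsum("nct,nct->c", dy, xhat)
        dbeta = dy.sum(axis=(0, 2))
        self.grads["gamma"] += dgamma
        self.grads["beta"] += dbeta
        coeff = (self.params["gamma"] * ivar / m).astype(x.dtype)
        xhat *= dgamma[None, :, None].astype(x.dtype)
        dx = m * dy
        dx -= dbeta[None, :, None].astype(x.dtype)
        dx -= xhat
        dx *= coeff[None, :, None]
        self._x = self._mean = self._ivar = None
        return dx


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        assert mask is not None
        self._mask = None
        return dy * mask


class AvgPool1d(Module):
    """Non-overlapping mean pooling of width 2; odd trailing sample is dropped."""

    def __init__(self) -> None:
        super().__init__()
        self._in_time = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, t = x.shape
        if t < 2:
            raise ValueError(f"pooling needs time_steps >= 2, got {t}")
        self._in_time = t
        t_out = t // 2
        return 0.5 * (x[:, :, : 2 * t_out : 2] + x[:, :, 1 : 2 * t_out : 2])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t_out = dy.shape
        dx = np.zeros((n, c, self._in_time), dtype=dy.dtype)
        half = 0.5 * dy
        dx[:, :, : 2 * t_out : 2] = half
        dx[:, :, 1 : 2 * t_out : 2] = half
        return dx


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.params = {
            "W": (rng.standard_normal((out_features, in_features)) * scale).astype(dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        self.grads["W"] += dy.T @ x
        self.grads["b"] += dy.sum(axis=0)
        self._x = None
        return dy @ self.params["W"]
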