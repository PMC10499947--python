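"""Bidirectional LSTM over the backbone sequence, attention pooling, classifier.

The backbone's (channels x time) output is read time-major by two LSTMs —
one forward, one backward — whose per-step hidden states are concatenated
into a feature vector of length ``feature_len`` (128 by default, 64 per
direction).  A learned global query is scored against every step with one
of three similarity functions:

* multiplicative:  f(Q, K_i) = Q^T W_a K_i
* cascade:         f(Q, K_i) = W_a [Q : K_i]        (W_a a row vector)
* perceptron:      f(Q, K_i) = v_a^T tanh(W_a Q + U_a K_i)

Scores are softmax-normalized into attention weights and the weighted sum
of the step vectors is the pooled context.  The classifier is a single
logistic unit over [context || global average of backbone channels].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Linear, Module

__all__ = [
    "RecurrentConfig",
    "AttentionParams",
    "AttentionOutput",
    "LSTM",
    "BiLSTM",
    "Attention",
    "attention_score",
    "attention_pool",
    "classify",
    "softmax",
]

SCORING_MODES = ("multiplicative", "cascade", "perceptron")


@dataclass(frozen=True)
class RecurrentConfig:
    """feature_len is the total per-step bidirectional dimension (128 default)."""

    feature_len: int = 128
    scoring_mode: str = "perceptron"

    def __post_init__(self) -> None:
        if self.feature_len < 2 or self.feature_len % 2 != 0:
            raise ValueError(f"feature_len must be even and >= 2, got {self.feature_len}")
        if self.scoring_mode not in SCORING_MODES:
            raise ValueError(
                f"scoring_mode must be one of {SCORING_MODES}, got {self.scoring_mode!r}"
            )

    @property
    def per_direction(self) -> int:
        return self.feature_len // 2


@dataclass
class AttentionParams:
    """Learnable scoring parameters W_a, U_a, v_a and the global query Q.

    Shapes per mode (d = feature_len, p = hidden width of the perceptron):
    multiplicative W_a (d, d); cascade W_a (2d,); perceptron W_a (p, d),
    U_a (p, d), v_a (p,).  U_a and v_a are unused outside perceptron mode.
    """

    W_alpha: np.ndarray
    U_alpha: np.ndarray | None = None
    v_alpha: np.ndarray | None = None
    query: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def validate(self, mode: str, d: int) -> None:
        if not all(
            np.all(np.isfinite(a)) for a in
            (self.W_alpha, self.U_alpha, self.v_alpha, self.query) if a is not None
        ):
            raise ValueError("attention parameters must be finite")
        if self.query.shape != (d,):
            raise ValueError(f"query must have shape ({d},), got {self.query.shape}")
        if mode == "multiplicative" and self.W_alpha.shape != (d, d):
            raise ValueError(f"multiplicative W_alpha must be ({d}, {d})")
        if mode == "cascade" and self.W_alpha.shape != (2 * d,):
            raise ValueError(f"cascade W_alpha must be ({2 * d},)")
        if mode == "perceptron":
            p = self.W_alpha.shape[0]
            if self.W_alpha.shape != (p, d) or self.U_alpha is None \
                    or self.U_alpha.shape != (p, d) \
                    or self.v_alpha is None or self.v_alpha.shape != (p,):
                raise ValueError("perceptron mode needs W_alpha (p,d), U_alpha (p,d), v_alpha (p,)")


@dataclass
class AttentionOutput:
    """weights: per-step probabilities; context: pooled feature vector."""

    weights: np.ndarray
    context: np.ndarray
    logit: float | None = None
    probability: float | None = None


def attention_score(Q: np.ndarray, K_i: np.ndarray, params: AttentionParams,
                    mode: str = "perceptron") -> float:
    """Similarity of the query with one key, per the selected scoring function."""
    Q = np.asarray(Q, dtype=float)
    K_i = np.asarray(K_i, dtype=float)
    if Q.shape != K_i.shape:
        raise ValueError(f"query/key shape mismatch: {Q.shape} vs {K_i.shape}")
    if mode == "multiplicative":
        return float(Q @ params.W_alpha @ K_i)
    if mode == "cascade":
        return float(params.W_alpha @ np.concatenate([Q, K_i]))
    if mode == "perceptron":
        return float(params.v_alpha @ np.tanh(params.W_alpha @ Q + params.U_alpha @ K_i))
    raise ValueError(f"unknown scoring mode {mode!r}")


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    s = s - s.max(axis=axis, keepdims=True)  # max-subtracted for stability
    e = np.exp(s)
    return e / e.sum(axis=axis, keepdims=True)


def attention_pool(scores, values) -> AttentionOutput:
    """Softmax the scores and take the weighted sum of the value vectors."""
    scores = np.asarray(scores, dtype=float)
    values = np.asarray(values, dtype=float)
    if scores.ndim != 1 or len(scores) != len(values):
        raise ValueError(
            f"scores ({scores.shape}) and values ({values.shape}) must align on the time axis"
        )
    if len(scores) < 1:
        raise ValueError("need at least one step to pool")
    w = softmax(scores)
    context = w @ values
    return AttentionOutput(weights=w, context=context)


def classify(context: np.ndarray, weights: np.ndarray, bias: float = 0.0) -> float:
    """Logistic probability of AF from a pooled feature vector; strictly in (0, 1)."""
    context = np.asarray(context, dtype=float)
    if not np.all(np.isfinite(context)):
        raise ValueError("context must be finite")
    logit = float(np.dot(weights, context) + bias)
    # clamp keeps the probability strictly inside (0, 1) even for huge |logit|
    logit = float(np.clip(logit, -500.0, 500.0))
    p = 1.0 / (1.0 + np.exp(-logit))
    eps = 1e-12
    return float(np.clip(p, eps, 1.0 - eps))


class LSTM(Module):
    """Single-direction LSTM; input (batch, time, dim), output (batch, time, hidden)."""

    def __init__(self, input_dim: int, hidden: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.input_dim, self.hidden = input_dim, hidden
        sx = np.sqrt(1.0 / input_dim)
        sh = np.sqrt(1.0 / hidden)
        self.params = {
            "Wx": (rng.standard_normal((4 * hidden, input_dim)) * sx).astype(dtype),
            "Wh": (rng.standard_normal((4 * hidden, hidden)) * sh).astype(dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }
        # forget-gate bias of 1: standard recipe for gradient flow early on
        self.params["b"][hidden : 2 * hidden] = 1.0
        self._cache: dict | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # gate layout in the 4h axis: [input, forget, output | candidate],
        # so one expit call covers the three sigmoids per step
        from scipy.special import expit

        n, t, d = x.shape
        if t < 1:
            raise ValueError("sequence must be non-empty")
        h_dim = self.hidden
        dtype = self.params["Wx"].dtype
        x = x.astype(dtype, copy=False)
        xw = x.reshape(n * t, d) @ self.params["Wx"].T + self.params["b"]
        gates = np.ascontiguousarray(xw.reshape(n, t, 4 * h_dim).transpose(1, 0, 2))
        cs = np.empty((t, n, h_dim), dtype=dtype)
        hs = np.empty((t, n, h_dim), dtype=dtype)
        h = np.zeros((n, h_dim), dtype=dtype)
        c = np.zeros((n, h_dim), dtype=dtype)
        wh_t = self.params["Wh"].T
        for step in range(t):
            a = gates[step]
            a += h @ wh_t
            expit(a[:, : 3 * h_dim], out=a[:, : 3 * h_dim])
            np.tanh(a[:, 3 * h_dim :], out=a[:, 3 * h_dim :])
            i = a[:, :h_dim]
            f = a[:, h_dim : 2 * h_dim]
            o = a[:, 2 * h_dim : 3 * h_dim]
            g = a[:, 3 * h_dim :]
            c = f * c
            c += i * g
            h = o * np.tanh(c)
            cs[step] = c
            hs[step] = h
        self._cache = {"x": x, "gates": gates, "cs": cs, "hs": hs}
        return np.ascontiguousarray(hs.transpose(1, 0, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache = self._cache
        assert cache is not None, "backward before forward"
        x, gates, cs, hs = cache["x"], cache["gates"], cache["cs"], cache["hs"]
        n, t, _ = x.shape
        h_dim = self.hidden
        dtype = x.dtype
        dy_t = dy.transpose(1, 0, 2).astype(dtype, copy=False)
        dh_next = np.zeros((n, h_dim), dtype=dtype)
        dc_next = np.zeros((n, h_dim), dtype=dtype)
        wh = self.params["Wh"]
        zeros = np.zeros((n, h_dim), dtype=dtype)
        for step in range(t - 1, -1, -1):
            a = gates[step]
            i = a[:, :h_dim]
            f = a[:, h_dim : 2 * h_dim]
            o = a[:, 2 * h_dim : 3 * h_dim]
            g = a[:, 3 * h_dim :]
            c = cs[step]
            c_prev = cs[step - 1] if step > 0 else zeros
            tc = np.tanh(c)
            dh = dy_t[step] + dh_next
            dc = dh * o
            dc *= 1 - tc * tc
            dc += dc_next
            # overwrite the gate slots with pre-activation gradients
            do_pre = dh * tc
            do_pre *= o * (1 - o)
            di_pre = dc * g
            di_pre *= i * (1 - i)
            dg_pre = dc * i
            dg_pre *= 1 - g * g
            df_pre = dc * c_prev
            df_pre *= f * (1 - f)
            dc_next = dc * f
            a[:, :h_dim] = di_pre
            a[:, h_dim : 2 * h_dim] = df_pre
            a[:, 2 * h_dim : 3 * h_dim] = do_pre
            a[:, 3 * h_dim :] = dg_pre
            dh_next = a @ wh
        da_flat = gates.transpose(1, 0, 2).reshape(n * t, 4 * h_dim)
        x_flat = x.reshape(n * t, -1)
        self.grads["Wx"] += da_flat.T @ x_flat
        self.grads["b"] += da_flat.sum(axis=0)
        h_prev = np.concatenate([np.zeros((1, n, h_dim), dtype=dtype), hs[:-1]], axis=0)
        self.grads["Wh"] += (
            gates.reshape(t * n, 4 * h_dim).T @ h_prev.reshape(t * n, h_dim)
        )
        dx = (da_flat @ self.params["Wx"]).reshape(n, t, -1)
        self._cache = None
        return dx


class BiLSTM(Module):
    """Forward + backward LSTM; per-step output is [h_fwd || h_bwd]."""

    def __init__(self, input_dim: int, config: RecurrentConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        self.config = config or RecurrentConfig()
        rng = rng or np.random.default_rng(0)
        h = self.config.per_direction
        self.fwd = LSTM(input_dim, h, rng=rng, dtype=dtype)
        self.bwd = LSTM(input_dim, h, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        # fused loop: both directions share each elementwise pass (the
        # per-step ufunc overhead dominates at these widths), with separate
        # per-direction recurrence matmuls.  Equivalent to running
        # self.fwd on x and self.bwd on the time-reversed x.
        from scipy.special import expit

        n, t, d = x.shape
        if t < 1:
            raise ValueError("sequence must be non-empty")
        h_dim = self.config.per_direction
        pf, pb = self.fwd.params, self.bwd.params
        dtype = pf["Wx"].dtype
        x = x.astype(dtype, copy=False)
        x_rev = x[:, ::-1]
        xw_f = (x.reshape(n * t, d) @ pf["Wx"].T + pf["b"]).reshape(n, t, 4 * h_dim)
        xw_b = (x_rev.reshape(n * t, d) @ pb["Wx"].T + pb["b"]).reshape(n, t, 4 * h_dim)
        gates = np.ascontiguousarray(
            np.concatenate([xw_f, xw_b], axis=0).transpose(1, 0, 2)
        )  # (t, 2n, 4h)
        cs = np.empty((t, 2 * n, h_dim), dtype=dtype)
        hs = np.empty((t, 2 * n, h_dim), dtype=dtype)
        h = np.zeros((2 * n, h_dim), dtype=dtype)
        c = np.zeros((2 * n, h_dim), dtype=dtype)
        whf_t, whb_t = pf["Wh"].T, pb["Wh"].T
        for step in range(t):
            a = gates[step]
            a[:n] += h[:n] @ whf_t
            a[n:] += h[n:] @ whb_t
            expit(a[:, : 3 * h_dim], out=a[:, : 3 * h_dim])
            np.tanh(a[:, 3 * h_dim :], out=a[:, 3 * h_dim :])
            i = a[:, :h_dim]
            f = a[:, h_dim : 2 * h_dim]
            o = a[:, 2 * h_dim : 3 * h_dim]
            g = a[:, 3 * h_dim :]
            c = f * c
            c += i * g
            h = o * np.tanh(c)
            cs[step] = c
            hs[step] = h
        self._cache = {"x": x, "gates": gates, "cs": cs, "hs": hs}
        hf = hs[:, :n].transpose(1, 0, 2)
        hb = hs[:, n:].transpose(1, 0, 2)[:, ::-1]
        return np.ascontiguousarray(np.concatenate([hf, hb], axis=2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache = self._cache
        assert cache is not None, "backward before forward"
        x, gates, cs, hs = cache["x"], cache["gates"], cache["cs"], cache["hs"]
        n, t, d = x.shape
        h_dim = self.config.per_direction
        pf, pb = self.fwd.params, self.bwd.params
        dtype = x.dtype
        dy = dy.astype(dtype, copy=False)
        # stack per-direction output gradients time-major: forward half as-is,
        # backward half time-reversed (its loop ran over reversed input)
        dh_all = np.concatenate(
            [dy[:, :, :h_dim], dy[:, ::-1, h_dim:]], axis=0
        ).transpose(1, 0, 2)
        dh_next = np.zeros((2 * n, h_dim), dtype=dtype)
        dc_next = np.zeros((2 * n, h_dim), dtype=dtype)
        whf, whb = pf["Wh"], pb["Wh"]
        zeros = np.zeros((2 * n, h_dim), dtype=dtype)
        for step in range(t - 1, -1, -1):
            a = gates[step]
            i = a[:, :h_dim]
            f = a[:, h_dim : 2 * h_dim]
            o = a[:, 2 * h_dim : 3 * h_dim]
            g = a[:, 3 * h_dim :]
            c = cs[step]
            c_prev = cs[step - 1] if step > 0 else zeros
            tc = np.tanh(c)
            dh = dh_all[step] + dh_next
            dc = dh * o
            dc *= 1 - tc * tc
            dc += dc_next
            do_pre = dh * tc
            do_pre *= o * (1 - o)
            di_pre = dc * g
            di_pre *= i * (1 - i)
            dg_pre = dc * i
            dg_pre *= 1 - g * g
            df_pre = dc * c_prev
            df_pre *= f * (1 - f)
            dc_next = dc * f
            a[:, :h_dim] = di_pre
            a[:, h_dim : 2 * h_dim] = df_pre
            a[:, 2 * h_dim : 3 * h_dim] = do_pre
            a[:, 3 * h_dim :] = dg_pre
            dh_next = np.empty_like(dh)
            dh_next[:n] = a[:n] @ whf
            dh_next[n:] = a[n:] @ whb
        da = gates.transpose(1, 0, 2)  # (2n, t, 4h)
        h_prev = np.concatenate(
            [np.zeros((1, 2 * n, h_dim), dtype=dtype), hs[:-1]], axis=0
        ).transpose(1, 0, 2)
        x_rev = x[:, ::-1]
        for params, grads, da_h, hp, xin in (
            (pf, self.fwd.grads, da[:n], h_prev[:n], x),
            (pb, self.bwd.grads, da[n:], h_prev[n:], x_rev),
        ):
            da_flat = da_h.reshape(n * t, 4 * h_dim)
            grads["Wx"] += da_flat.T @ np.ascontiguousarray(xin).reshape(n * t, d)
            grads["Wh"] += da_flat.T @ np.ascontiguousarray(hp).reshape(n * t, h_dim)
            grads["b"] += da_flat.sum(axis=0)
        dx = (da[:n].reshape(n * t, 4 * h_dim) @ pf["Wx"]).reshape(n, t, d)
        dx += (da[n:].reshape(n * t, 4 * h_dim) @ pb["Wx"]).reshape(n, t, d)[:, ::-1]
        self._cache = None
        return dx


class Attention(Module):
    """Batched attention scoring + pooling with a learned global query."""

    def __init__(self, d: int, mode: str = "perceptron", hidden: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        if mode not in SCORING_MODES:
            raise ValueError(f"scoring mode must be one of {SCORING_MODES}, got {mode!r}")
        rng = rng or np.random.default_rng(0)
        self.d, self.mode = d, mode
        p = hidden or d
        s = np.sqrt(1.0 / d)
        if mode == "multiplicative":
            self.params = {
                "W": (rng.standard_normal((d, d)) * s).astype(dtype),
                "Q": (rng.standard_normal(d) * s).astype(dtype),
            }
        elif mode == "cascade":
            self.params = {
                "W": (rng.standard_normal(2 * d) * s).astype(dtype),
                "Q": (rng.standard_normal(d) * s).astype(dtype),
            }
        else:
            self.params = {
                "W": (rng.standard_normal((p, d)) * s).astype(dtype),
                "U": (rng.standard_normal((p, d)) * s).astype(dtype),
                "v": (rng.standard_normal(p) * np.sqrt(1.0 / p)).astype(dtype),
                "Q": (rng.standard_normal(d) * s).astype(dtype),
            }
        self._cache: dict | None = None

    def _scores(self, keys: np.ndarray) -> np.ndarray:
        q = self.params["Q"]
        if self.mode == "multiplicative":
            return keys @ (q @ self.params["W"])
        if self.mode == "cascade":
            d = self.d
            wq, wk = self.params["W"][:d], self.params["W"][d:]
            return keys @ wk + float(wq @ q)
        h = np.tanh(self.params["W"] @ q + keys @ self.params["U"].T)
        self._h = h
        return h @ self.params["v"]

    def forward(self, keys: np.ndarray) -> np.ndarray:
        """keys (batch, time, d) -> context (batch, d); weights stashed on the module."""
        scores = self._scores(keys)
        w = softmax(scores, axis=1)
        context = np.einsum("nt,ntd->nd", w, keys)
        self._cache = {"keys": keys, "w": w}
        self.weights = w
        return context

    def backward(self, dcontext: np.ndarray) -> np.ndarray:
        cache = self._cache
        assert cache is not None
        keys, w = cache["keys"], cache["w"]
        dkeys = w[:, :, None] * dcontext[:, None, :]
        dscores_raw = np.einsum("ntd,nd->nt", keys, dcontext)
        ds = w * (dscores_raw - (dscores_raw * w).sum(axis=1, keepdims=True))
        q = self.params["Q"]
        if self.mode == "multiplicative":
            qw = q @ self.params["W"]
            dkeys += ds[:, :, None] * qw
            dqw = np.einsum("nt,ntd->d", ds, keys)
            self.grads["W"] += np.outer(q, dqw)
            self.grads["Q"] += self.params["W"] @ dqw
        elif self.mode == "cascade":
            d = self.d
            wq, wk = self.params["W"][:d], self.params["W"][d:]
            total = float(ds.sum())
            dw = np.concatenate([total * q, np.einsum("nt,ntd->d", ds, keys)])
            self.grads["W"] += dw
            self.grads["Q"] += total * wq
            dkeys += ds[:, :, None] * wk
        else:
            h = self._h
            dh = ds[:, :, None] * self.params["v"]
            da = dh * (1 - h * h)
            self.grads["v"] += np.einsum("ntp,nt->p", h, ds)
            p = da.shape[-1]
            self.grads["U"] += da.reshape(-1, p).T @ keys.reshape(-1, self.d)
            dkeys += da @ self.params["U"]
            du_q = da.sum(axis=(0, 1))
            self.grads["W"] += np.outer(du_q, q)
            self.grads["Q"] += self.params["W"].T @ du_q
            self._h = None
        self._cache = None
        return dkeys

    def as_params(self) -> AttentionParams:
        if self.mode == "perceptron":
            return AttentionParams(
                W_alpha=self.params["W"], U_alpha=self.params["U"],
                v_alpha=self.params["v"], query=self.params["Q"],
            )
        return AttentionParams(W_alpha=self.params["W"], query=self.params["Q"])


class Classifier(Module):
    """Single logistic unit: probability of AF."""

    def __init__(self, in_features: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.linear = Linear(in_features, 1, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.linear(x)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        return self.linear.backward(dlogit[:, None])
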