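"""The full detector: DenseNet-1D backbone -> BiLSTM -> attention -> logistic unit.

Feature fusion: the attention-pooled recurrent context (global timing
structure, 128-d) is concatenated with the global average of the backbone
channels (local morphology, one value per channel) before the final
logistic classifier.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .densenet import DenseNet1d, DenseNetConfig
from .recurrent import Attention, BiLSTM, Classifier, RecurrentConfig

__all__ = ["AFNet", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class AFNet:
    """End-to-end AF detector operating on fixed-length z-scored segments."""

    def __init__(
        self,
        backbone_config: DenseNetConfig | None = None,
        recurrent_config: RecurrentConfig | None = None,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.backbone_config = backbone_config or DenseNetConfig()
        self.recurrent_config = recurrent_config or RecurrentConfig()
        self.backbone = DenseNet1d(self.backbone_config, rng=rng, dtype=dtype)
        self.bilstm = BiLSTM(self.backbone.out_channels, self.recurrent_config,
                             rng=rng, dtype=dtype)
        self.attention = Attention(self.recurrent_config.feature_len,
                                   mode=self.recurrent_config.scoring_mode,
                                   rng=rng, dtype=dtype)
        self.classifier = Classifier(
            self.recurrent_config.feature_len + self.backbone.out_channels,
            rng=rng, dtype=dtype,
        )
        self._cache: dict | None = None

    # -- module plumbing -------------------------------------------------
    @property
    def submodules(self):
        return (self.backbone, self.bilstm, self.attention, self.classifier)

    def named_parameters(self):
        for i, mod in enumerate(self.submodules):
            for name, leaf, key in mod.named_parameters():
                yield f"m{i}.{name}", leaf, key

    def n_parameters(self) -> int:
        return sum(leaf.params[k].size for _, leaf, k in self.named_parameters())

    def zero_grad(self) -> None:
        for mod in self.submodules:
            mod.zero_grad()

    def train(self, mode: bool = True) -> "AFNet":
        for mod in self.submodules:
            mod.train(mode)
        return self

    def eval(self) -> "AFNet":
        return self.train(False)

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, segment_len) z-scored segments -> (batch,) logits."""
        fmap = self.backbone(x)                      # (n, c, t')
        t_steps = fmap.shape[2]
        gap = fmap.mean(axis=2)                      # (n, c) morphology summary
        seq = np.ascontiguousarray(fmap.transpose(0, 2, 1))
        keys = self.bilstm(seq)                      # (n, t', feature_len)
        context = self.attention(keys)               # (n, feature_len)
        feats = np.concatenate([context, gap], axis=1)
        logits = self.classifier(feats)
        self._cache = {"t_steps": t_steps}
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        eps = 1e-12
        return np.clip(sigmoid(self.forward_logits(x)), eps, 1 - eps)

    def backward(self, dlogits: np.ndarray) -> None:
        cache = self._cache
        assert cache is not None, "backward before forward"
        d = self.recurrent_config.feature_len
        dfeats = self.classifier.backward(dlogits)
        dcontext, dgap = dfeats[:, :d], dfeats[:, d:]
        dkeys = self.attention.backward(dcontext)
        dseq = self.bilstm.backward(dkeys)
        dfmap = np.ascontiguousarray(dseq.transpose(0, 2, 1))
        dfmap += dgap[:, :, None] / cache["t_steps"]
        self.backbone.backward(dfmap)
        self._cache = None

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: leaf.params[key] for name, leaf, key in self.named_parameters()}
        # batch-norm running statistics travel with the parameters
        for i, mod in enumerate(self.submodules):
            if hasattr(mod, "modules"):
                for j, sub in enumerate(mod.modules()):
                    if hasattr(sub, "running_mean"):
                        state[f"m{i}.bn{j}.running_mean"] = sub.running_mean
                        state[f"m{i}.bn{j}.running_var"] = sub.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, leaf, key in self.named_parameters():
            leaf.params[key] = np.array(state[name])
        for i, mod in enumerate(self.submodules):
            if hasattr(mod, "modules"):
                for j, sub in enumerate(mod.modules()):
                    if hasattr(sub, "running_mean"):
                        sub.running_mean = np.array(state[f"m{i}.bn{j}.running_mean"])
                        sub.running_var = np.array(state[f"m{i}.bn{j}.running_var"])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "afnet-checkpoint-v1",
            "backbone_config": self.backbone_config.__dict__,
            "recurrent_config": self.recurrent_config.__dict__,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "AFNet":
        with np.load(Path(path), allow_pickle=False) as payload:
            meta = json.loads(str(payload["__meta__"]))
            if meta.get("format") != "afnet-checkpoint-v1":
                raise ValueError(f"unrecognized checkpoint format in {path}")
            model = cls(
                DenseNetConfig(**meta["backbone_config"]),
                RecurrentConfig(**meta["recurrent_config"]),
            )
            model.load_state_dict({k: payload[k] for k in payload.files if k != "__meta__"})
        return model

    def export_attention_weights(self, path: str | Path) -> Path:
        """Write the last forward pass's attention weights as time_step,weight CSV."""
        w = getattr(self.attention, "weights", None)
        if w is None:
            raise RuntimeError("run a forward pass before exporting attention weights")
        path = Path(path)
        with path.open("w") as fh:
            fh.write("time_step,weight\n")
            for t, val in enumerate(np.asarray(w)[0]):
                fh.write(f"{t},{val:.8f}\n")
        return path
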