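"""Run configuration: one YAML file validated into typed sub-configs.

Layout (every section optional; defaults fill the gaps; unknown keys are
rejected by name so typos never silently fall back to a default):

    synth:      {fs: 500, duration_s: 10, af_fraction: 0.1667, seed: 0, ...}
    preprocess: {kind: bandpass, low_hz: 0.5, high_hz: 40, order: 4, target_len: 5000}
    model:      {k0: 24, k: 12, num_blocks: 3, layers_per_block: 8,
                 feature_len: 128, scoring_mode: perceptron, ...}
    train:      {lr0: 0.1, epochs: 100, batch_size: 64, ...}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .nn.densenet import DenseNetConfig
from .nn.recurrent import RecurrentConfig
from .preprocess import DEFAULT_TARGET_LEN, FilterSpec
from .synth import ECGSynthConfig
from .training import TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    synth: ECGSynthConfig
    filter_spec: FilterSpec
    target_len: int
    backbone: DenseNetConfig
    recurrent: RecurrentConfig
    train: TrainConfig
    log_level: str = "INFO"


_MODEL_FIELDS_BACKBONE = {f.name for f in dataclasses.fields(DenseNetConfig)}
_MODEL_FIELDS_RECURRENT = {f.name for f in dataclasses.fields(RecurrentConfig)}


def _build(cls, section: dict, name: str, extra_allowed: set[str] = frozenset()):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed - extra_allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {', '.join(sorted(unknown))}")
    kwargs = {k: v for k, v in section.items() if k in allowed}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def _normalize(section: dict, tuple_keys: tuple[str, ...]) -> dict:
    out = dict(section)
    for key in tuple_keys:
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse and validate; an empty or missing file yields all defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    for key, value in (overrides or {}).items():
        raw.setdefault(key, {}).update(value)
    known_sections = {"synth", "preprocess", "model", "train", "log_level"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(sorted(unknown))}")

    synth = _build(ECGSynthConfig, _normalize(raw.get("synth", {}), ("noise_amplitudes",)),
                   "synth")
    pre = dict(raw.get("preprocess", {}))
    target_len = pre.pop("target_len", DEFAULT_TARGET_LEN)
    if target_len < 1:
        raise ConfigError(f"preprocess.target_len must be >= 1, got {target_len}")
    filter_spec = _build(FilterSpec, pre, "preprocess")

    model = dict(raw.get("model", {}))
    unknown = set(model) - _MODEL_FIELDS_BACKBONE - _MODEL_FIELDS_RECURRENT
    if unknown:
        raise ConfigError(f"unknown key(s) in 'model': {', '.join(sorted(unknown))}")
    backbone = _build(DenseNetConfig,
                      {k: v for k, v in model.items() if k in _MODEL_FIELDS_BACKBONE},
                      "model")
    recurrent = _build(RecurrentConfig,
                       {k: v for k, v in model.items() if k in _MODEL_FIELDS_RECURRENT},
                       "model")
    train = _build(TrainConfig,
                   _normalize(raw.get("train", {}),
                              ("milestone_fractions", "split_ratio")),
                   "train")
    return RunConfig(synth=synth, filter_spec=filter_spec, target_len=target_len,
                     backbone=backbone, recurrent=recurrent, train=train,
                     log_level=str(raw.get("log_level", "INFO")))


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Echo the effective configuration; the output reloads to an equal RunConfig."""
    synth = dataclasses.asdict(config.synth)
    synth.pop("morphology", None)  # defaulted; not part of the file dialect
    synth["noise_amplitudes"] = list(config.synth.noise_amplitudes)
    pre = dataclasses.asdict(config.filter_spec)
    pre["kind"] = config.filter_spec.kind.value
    pre["target_len"] = config.target_len
    train = dataclasses.asdict(config.train)
    train["milestone_fractions"] = list(config.train.milestone_fractions)
    train["split_ratio"] = list(config.train.split_ratio)
    payload = {
        "synth": synth,
        "preprocess": pre,
        "model": {**dataclasses.asdict(config.backbone),
                  **dataclasses.asdict(config.recurrent)},
        "train": train,
        "log_level": config.log_level,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
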