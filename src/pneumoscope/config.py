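"""Layered run configuration: defaults < YAML file < CLI flag overrides.

The fully-resolved configuration is echoed into every output directory
for provenance. Unknown keys and constraint violations raise
ConfigError naming the offending key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import TrainingConfig
from .models import ModelSpec, SpecError


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "data": {"root", "scenario", "seed", "label_map"},
    "model": {"variant", "n_hidden_layers", "reconstruction_loss",
              "sigma", "z", "gamma", "beta", "latent_dim"},
    "training": {"initial_lr", "momentum", "decay_every", "decay_factor",
                 "batch_size", "epochs", "seed"},
    "eval": {"out_dir"},
    "synth": {"n_normal", "n_anomalous", "blob_count_range",
              "blob_radius_range", "blob_contrast", "noise_sd", "seed"},
}
_TOP_KEYS = set(_SECTIONS) | {"global_seed"}


@dataclass
class RunConfig:
    data: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    global_seed: int = 0

    def model_spec(self) -> ModelSpec:
        try:
            return ModelSpec(**self.model)
        except SpecError as exc:
            raise ConfigError(f"model section: {exc}") from exc

    def training_config(self) -> TrainingConfig:
        try:
            return TrainingConfig(
                **{**self.training,
                   "seed": self.training.get("seed", self.global_seed)})
        except ValueError as exc:
            raise ConfigError(f"training section: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _check_keys(section: str, mapping: dict) -> dict:
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    unknown = set(mapping) - _SECTIONS[section]
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}")
    return dict(mapping)


def resolve_config(file: str | Path | None = None,
                   flag_overrides: dict | None = None) -> RunConfig:
    """Resolve defaults < file < flags into a validated RunConfig.

    ``flag_overrides`` uses dotted keys ("model.beta") or "global_seed".
    """
    cfg = RunConfig()
    layers: list[dict] = []
    if file is not None and Path(file).exists():
        with open(file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {file} must contain a mapping")
        layers.append(loaded)
    if flag_overrides:
        nested: dict = {}
        for key, value in flag_overrides.items():
            if value is None:
                continue
            if "." in key:
                sec, sub = key.split(".", 1)
                nested.setdefault(sec, {})[sub] = value
            else:
                nested[key] = value
        layers.append(nested)
    for layer in layers:
        unknown = set(layer) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        for sec in _SECTIONS:
            if sec in layer:
                merged = {**getattr(cfg, sec), **_check_keys(sec, layer[sec])}
                setattr(cfg, sec, merged)
        if "global_seed" in layer:
            cfg.global_seed = int(layer["global_seed"])
    # validate eagerly so errors name the bad field up front
    cfg.model_spec()
    cfg.training_config()
    scenario = cfg.data.get("scenario", "train_pos")
    if scenario not in ("train_pos", "train_neg"):
        raise ConfigError(f"data.scenario must be train_pos or train_neg, "
                          f"got {scenario!r}")
    return cfg
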