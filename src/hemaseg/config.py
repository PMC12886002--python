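"""YAML configuration loading.

A config file may carry any of the blocks ``phantom:``, ``preprocess:``,
``weem:``, ``gpsa:``, ``model:``, ``train:``; each maps onto the matching
dataclass. Missing blocks fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .network import ModelConfig
from .phantom import PhantomConfig, config_from_dict
from .preprocess import AugmentConfig, PreprocessConfig
from .training import TrainConfig
from .weem import EnhancementConfig


def load_yaml(path) -> dict:
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def _build(cls, block: dict):
    return cls(**block) if block else cls()


def load_configs(path=None) -> dict:
    """Parse a YAML file into the package's configuration dataclasses."""
    raw = load_yaml(path) if path else {}
    pre = dict(raw.get("preprocess", {}))
    if "augment" in pre and isinstance(pre["augment"], dict):
        pre["augment"] = AugmentConfig(**pre["augment"])
    if "hu_window" in pre:
        pre["hu_window"] = tuple(pre["hu_window"])
    if "target_spacing_mm" in pre:
        pre["target_spacing_mm"] = tuple(pre["target_spacing_mm"])
    train = dict(raw.get("train", {}))
    if "augment" in train and isinstance(train["augment"], dict):
        train["augment"] = AugmentConfig(**train["augment"])
    return {
        "phantom": (config_from_dict(raw["phantom"]) if raw.get("phantom")
                    else PhantomConfig()),
        "preprocess": _build(PreprocessConfig, pre) if pre else PreprocessConfig(),
        "weem": _build(EnhancementConfig, dict(raw.get("weem", {}))),
        "model": _build(ModelConfig, dict(raw.get("model", {}))),
        "train": _build(TrainConfig, train) if train else TrainConfig(),
        "gpsa": dict(raw.get("gpsa", {})),
    }
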