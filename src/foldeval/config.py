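"""YAML configuration loading for loss hyperparameters.

Expected layout (all keys optional; missing keys keep library defaults)::

    fape:
      clamp: 10.0
      v: 12.0
      h: 1.5
      normalize_by_weight_sum: false
    confidence:
      delta0_deg: 12.0
      n_bins: 50
    weights:
      c1: 1.0
      c2: 1.0
      c3: 1.0
      c4: 1.0
      c_others: [0.5, 0.3, 2.0, 0.01, 0.01, 1.0]
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import FormatError
from .losses import ConfidenceConfig, FapeConfig, LossWeights

__all__ = ["ToolConfig", "load_config"]


@dataclass
class ToolConfig:
    fape: FapeConfig = field(default_factory=FapeConfig)
    confidence: ConfidenceConfig = field(default_factory=ConfidenceConfig)
    weights: LossWeights = field(default_factory=LossWeights)


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> ToolConfig:
    """Load a YAML config file into a ToolConfig."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping")
    unknown = set(raw) - {"fape", "confidence", "weights"}
    if unknown:
        raise FormatError(f"unknown config sections: {sorted(unknown)}")
    cfg = ToolConfig()
    if "fape" in raw:
        cfg.fape = _build(FapeConfig, raw["fape"] or {}, "fape")
    if "confidence" in raw:
        cfg.confidence = _build(ConfidenceConfig, raw["confidence"] or {},
                                "confidence")
    if "weights" in raw:
        w = dict(raw["weights"] or {})
        if "c_others" in w:
            w["c_others"] = tuple(w["c_others"])
        cfg.weights = _build(LossWeights, w, "weights")
    return cfg
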