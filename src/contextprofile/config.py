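"""Typed run configuration and YAML validation.

A run configuration bundles every tunable of the pipeline; the defaults
reproduce the canonical experimental grid (context 3x3, entropy N=500 r=0.2
m=7, threshold grid, soft buffer -10/+7).  Off-grid threshold values are
accepted with a warning; structurally impossible values (e.g. a subsequence
length of 1, where z-normalisation is undefined) are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cmp import ContextConfig
from .evaluation import EvalConfig
from .scoring import MODEL_TAGS, EntropyConfig
from .synth import SynthConfig
from .thresholds import ThresholdConfig

__all__ = ["RunConfig", "validate_config", "dump_config"]


@dataclass
class RunConfig:
    context: ContextConfig = field(default_factory=ContextConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    model: str = "mdcmp_equal"
    k: int | str = 1
    counts: str = "runs"        # runs | raw firings
    duration: str = "literal"   # literal | span dwell rule
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model not in MODEL_TAGS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_TAGS}")
        if self.k != "auto":
            self.k = int(self.k)
        # one seed drives every source of randomness in the run
        if self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)


_SECTIONS = {
    "context": ContextConfig,
    "entropy": EntropyConfig,
    "threshold": ThresholdConfig,
    "eval": EvalConfig,
    "synth": SynthConfig,
}


def validate_config(source: str | Path | dict | None = None) -> RunConfig:
    """Build a RunConfig from YAML (path, text, dict, or None for defaults)."""
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a YAML mapping")
    kwargs: dict = {}
    for key, cls in _SECTIONS.items():
        sect = raw.pop(key, {})
        if not isinstance(sect, dict):
            raise ValueError(f"section {key!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sect) - valid
        if unknown:
            raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
        if key == "synth" and "uti_duration_days" in sect:
            sect["uti_duration_days"] = tuple(sect["uti_duration_days"])
        if key == "synth" and "hosp_duration_days" in sect:
            sect["hosp_duration_days"] = tuple(sect["hosp_duration_days"])
        kwargs[key] = cls(**sect)
    top_valid = {f.name for f in dataclasses.fields(RunConfig)} - set(_SECTIONS)
    unknown = set(raw) - top_valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(raw)
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Persist the fully resolved configuration next to the run's outputs."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if hasattr(obj, "tolist"):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if hasattr(obj, "isoformat"):
            return obj.isoformat()
        return obj

    Path(path).write_text(yaml.safe_dump(clean(cfg), sort_keys=False))
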