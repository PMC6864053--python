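"""YAML run configuration.

One document drives the whole synthetic pipeline: simulation, TF chain,
decomposition, contrast selection and permutation settings. Unknown keys
are rejected so typos fail loudly; defaults everywhere are the study's
stated parameter values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cpd import DecomposeConfig
from .synthdata import SimConfig
from .tfr import TFRConfig

__all__ = ["RunConfig", "load_config", "stage_hash"]


@dataclass
class RunConfig:
    """Top-level pipeline settings."""

    sim: SimConfig = field(default_factory=SimConfig)
    tfr: TFRConfig = field(default_factory=TFRConfig)
    decompose: DecomposeConfig = field(default_factory=DecomposeConfig)
    model_id: int = 2
    n_perm: int = 1000
    perm_scheme: str = "joint"
    seed: int = 0
    rank_sweep: tuple[int, ...] = ()
    n_trials: int = 0  # >0: simulate raw epochs and run the TF chain

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1..4")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _build(cls, data: dict, context: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML file into a validated RunConfig (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"unknown keys in config: {sorted(unknown)}")
    kwargs = {}
    for key, cls in (("sim", SimConfig), ("tfr", TFRConfig), ("decompose", DecomposeConfig)):
        if key in raw:
            kwargs[key] = _build(cls, raw[key] or {}, key)
    for key in top - {"sim", "tfr", "decompose"}:
        if key in raw:
            v = raw[key]
            kwargs[key] = tuple(v) if isinstance(v, list) else v
    return RunConfig(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def stage_hash(*parts) -> str:
    """Stable digest of the configuration pieces that determine a stage."""
    payload = json.dumps([_jsonable(p) for p in parts], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
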