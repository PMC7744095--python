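"""YAML pipeline configuration with strict schema validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .localization import OpticsConfig
from .trajqc import QCParams
from .types import AcquisitionConfig, KineticModel, SchemaError

__all__ = ["EventParams", "HistogramParams", "PipelineConfig", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class EventParams:
    threshold: float = 0.25
    min_frames: int = 5


@dataclass(frozen=True)
class HistogramParams:
    n_bins: Optional[int] = None
    range: Optional[tuple[float, float]] = None


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    ``conditions`` maps a condition label to kinetic-model overrides
    (e.g. a different ``k_form``); an empty mapping runs the base
    kinetics as a single condition named 'default'.
    """

    seed: int = 0
    kinetics: KineticModel = field(default_factory=KineticModel)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    qc: QCParams = field(default_factory=QCParams)
    events: EventParams = field(default_factory=EventParams)
    histogram: HistogramParams = field(default_factory=HistogramParams)
    denominator: str = "exclude_events"
    conditions: dict[str, dict[str, Any]] = field(default_factory=dict)
    movies: bool = False
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.denominator not in ("exclude_events", "total"):
            raise SchemaError(f"denominator must be exclude_events|total, got {self.denominator!r}")

    def condition_models(self) -> dict[str, KineticModel]:
        if not self.conditions:
            return {"default": self.kinetics}
        out = {}
        for label, overrides in self.conditions.items():
            _check_keys(overrides, {f.name for f in dataclasses.fields(KineticModel)},
                        where=f"conditions.{label}")
            out[label] = dataclasses.replace(self.kinetics, **overrides)
        return out


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build(cls, d: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(d, fields, where)
    if cls is AcquisitionConfig and "cycle" in d:
        d = {**d, "cycle": tuple(d["cycle"])}
    if cls is OpticsConfig and "image_shape" in d:
        d = {**d, "image_shape": tuple(d["image_shape"])}
    if cls is HistogramParams and d.get("range") is not None:
        d = {**d, "range": tuple(d["range"])}
    return cls(**d)


_BLOCKS = {
    "kinetics": KineticModel,
    "acquisition": AcquisitionConfig,
    "optics": OpticsConfig,
    "qc": QCParams,
    "events": EventParams,
    "histogram": HistogramParams,
}
_SCALARS = {"seed", "denominator", "movies", "verbosity", "conditions"}


def load_config(source: Union[str, Path, dict]) -> PipelineConfig:
    """Load and validate a pipeline config from YAML (path or mapping).

    Unknown keys anywhere are rejected so that a typo cannot silently
    fall back to a default.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    _check_keys(raw, set(_BLOCKS) | _SCALARS, where="config")

    kwargs: dict[str, Any] = {}
    for key, cls in _BLOCKS.items():
        block = raw.get(key) or {}
        if not isinstance(block, dict):
            raise SchemaError(f"config block {key!r} must be a mapping")
        kwargs[key] = _build(cls, block, where=key)
    for key in _SCALARS:
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Round-trippable plain-dict form (for manifests and hashing)."""
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return {
        "seed": cfg.seed,
        "kinetics": enc(cfg.kinetics),
        "acquisition": enc(cfg.acquisition),
        "optics": enc(cfg.optics),
        "qc": enc(cfg.qc),
        "events": enc(cfg.events),
        "histogram": enc(cfg.histogram),
        "denominator": cfg.denominator,
        "conditions": enc(cfg.conditions),
        "movies": cfg.movies,
        "verbosity": cfg.verbosity,
    }
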