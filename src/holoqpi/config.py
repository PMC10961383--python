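"""Run configuration: YAML parsing with strict key validation.

Unknown keys are rejected by name rather than silently defaulted —
a typo in a parameter-recovery experiment would otherwise corrupt the
study without a trace.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Union

import yaml

from .optics import NoiseMeta, OpticalConfig
from .reconstruct import ReconstructionOptions
from .scene import SceneParams, TreatmentEffect

__all__ = ["RunConfig", "MorphometryOptions", "StatsOptions", "FlowGroup",
           "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MorphometryOptions:
    min_height_um: float = 0.3
    min_area_um2: float = 5.0
    support_height_um: float = 0.1
    smoothing_sigma_px: float = 2.0


@dataclass(frozen=True)
class StatsOptions:
    n_fields: int = 5
    control_quantile: float = 0.99


@dataclass(frozen=True)
class FlowGroup:
    label: str
    positive_fraction: float
    n_events: int = 10_000


@dataclass
class RunConfig:
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    scene: SceneParams = field(default_factory=SceneParams)
    treatments: List[TreatmentEffect] = field(default_factory=list)
    reconstruction: ReconstructionOptions = field(default_factory=ReconstructionOptions)
    morphometry: MorphometryOptions = field(default_factory=MorphometryOptions)
    noise: NoiseMeta = field(default_factory=lambda: NoiseMeta(photon_scale=1000.0,
                                                               read_noise_sigma=1.0))
    stats: StatsOptions = field(default_factory=StatsOptions)
    flow_groups: List[FlowGroup] = field(default_factory=list)
    seed: int = 0
    output_dir: str = "holoqpi_out"


_TUPLE_FIELDS = {"field_size_px", "cell_radius_um", "cell_height_um",
                 "carrier_cycles_per_px", "autofocus_range_um"}


def _build(cls, data: Mapping[str, Any], section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    if cls is ReconstructionOptions:
        valid.discard("background_mask")  # array-valued, not configurable from YAML
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    kwargs = {k: (tuple(v) if k in _TUPLE_FIELDS and v is not None else v)
              for k, v in data.items()}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in '{section}': {exc}") from exc


_SECTIONS = {
    "optics": OpticalConfig,
    "scene": SceneParams,
    "reconstruction": ReconstructionOptions,
    "morphometry": MorphometryOptions,
    "noise": NoiseMeta,
    "stats": StatsOptions,
}


def load_config(path: Union[str, Path, None] = None,
                data: Optional[Mapping[str, Any]] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file (or ``None``) yields all defaults. Unknown keys and
    out-of-range values raise :class:`ConfigError` naming the offender.
    """
    if data is None:
        raw = yaml.safe_load(Path(path).read_text()) if path is not None else None
        data = raw or {}
    top_valid = set(_SECTIONS) | {"treatments", "flow_groups", "seed", "output_dir"}
    unknown = set(data) - top_valid
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = RunConfig()
    for name, cls in _SECTIONS.items():
        if name in data:
            setattr(cfg, name, _build(cls, data[name] or {}, name))
    if "treatments" in data:
        cfg.treatments = [_build(TreatmentEffect, t, f"treatments[{i}]")
                          for i, t in enumerate(data["treatments"] or [])]
    if "flow_groups" in data:
        cfg.flow_groups = [_build(FlowGroup, g, f"flow_groups[{i}]")
                           for i, g in enumerate(data["flow_groups"] or [])]
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "output_dir" in data:
        cfg.output_dir = str(data["output_dir"])
    return cfg


def config_to_dict(cfg: RunConfig) -> Dict[str, Any]:
    d: Dict[str, Any] = {}
    for name in _SECTIONS:
        sub = dataclasses.asdict(getattr(cfg, name))
        sub.pop("background_mask", None)
        for k, v in sub.items():
            if isinstance(v, tuple):
                sub[k] = list(v)
        d[name] = sub
    d["treatments"] = [dataclasses.asdict(t) for t in cfg.treatments]
    d["flow_groups"] = [dataclasses.asdict(g) for g in cfg.flow_groups]
    d["seed"] = cfg.seed
    d["output_dir"] = cfg.output_dir
    return d


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
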