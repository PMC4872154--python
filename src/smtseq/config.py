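"""Run configuration: one file, four sections, every default a key.

A YAML (or TOML) file with sections ``references``, ``flow``, ``errors``,
``geometry`` and optionally ``optics`` maps directly onto the dataclasses
of :mod:`smtseq.simcore` and :mod:`smtseq.imagesim`; omitted keys keep
their defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .imagesim import OpticsConfig
from .simcore import ErrorModel, FieldGeometry, FlowProtocol


@dataclass
class SimulationConfig:
    n_templates: int = 8
    reference_seed: int = 0
    flow: FlowProtocol = field(default_factory=FlowProtocol)
    errors: ErrorModel = field(default_factory=ErrorModel)
    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    optics: OpticsConfig = field(default_factory=OpticsConfig)


def _build(cls, section: Dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(section)
    if cls is FlowProtocol and "flow_order" in kwargs:
        kwargs["flow_order"] = tuple(kwargs["flow_order"])
    if cls is FieldGeometry and "pixel_count" in kwargs:
        kwargs["pixel_count"] = tuple(kwargs["pixel_count"])
    return cls(**kwargs)


def load_config(path) -> SimulationConfig:
    """Load a YAML or TOML run configuration."""
    p = Path(path)
    if p.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(p.read_text())
    else:
        data = yaml.safe_load(p.read_text()) or {}
    refs = data.get("references", {})
    return SimulationConfig(
        n_templates=int(refs.get("n_templates", 8)),
        reference_seed=int(refs.get("seed", 0)),
        flow=_build(FlowProtocol, data.get("flow", {})),
        errors=_build(ErrorModel, data.get("errors", {})),
        geometry=_build(FieldGeometry, data.get("geometry", {})),
        optics=_build(OpticsConfig, data.get("optics", {})),
    )


def dump_config(config: SimulationConfig, path) -> None:
    data = {
        "references": {"n_templates": config.n_templates, "seed": config.reference_seed},
        "flow": {
            "flow_order": list(config.flow.flow_order),
            "n_cycles": config.flow.n_cycles,
        },
        "errors": dataclasses.asdict(config.errors),
        "geometry": {
            **dataclasses.asdict(config.geometry),
            "pixel_count": list(config.geometry.pixel_count),
        },
        "optics": dataclasses.asdict(config.optics),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
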