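"""YAML run configuration.

One flat document collects every tunable of a growth-characterization run:
geometry of the idealized LV, material parameters, boundary conditions,
solver controls, mask rasterization and the optimization protocol.  All
sections are optional; omitted values fall back to the package defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .bayesopt import BOSettings
from .constitutive import MaterialParams
from .geometry import LVShapeSpec
from .solver import BoundaryConditions, SolverSettings

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class MaskConfig:
    voxel_spacing: float = 0.5  # mm; ~1/8 of the wall thickness, the CMR regime
    grid_margin: float = 8.0  # mm
    sample_spacing_voxels: float = 1.5  # sub-element sampling, in voxels


@dataclass
class PericardiumConfig:
    enabled: bool = True
    thickness: float = 0.25  # mm (assumed; only E is reported for the tissue)
    youngs_modulus: float = 10.0  # MPa


@dataclass
class RunConfig:
    geometry: LVShapeSpec = field(default_factory=LVShapeSpec)
    material: MaterialParams = field(default_factory=MaterialParams)
    boundary: BoundaryConditions = field(default_factory=BoundaryConditions)
    solver: SolverSettings = field(default_factory=SolverSettings)
    mask: MaskConfig = field(default_factory=MaskConfig)
    pericardium: PericardiumConfig = field(default_factory=PericardiumConfig)
    bayesopt: BOSettings = field(default_factory=BOSettings)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            d = asdict(getattr(self, f.name))
            for k, v in list(d.items()):
                if isinstance(v, tuple):
                    d[k] = list(v)
            out[f.name] = d
        return out


_SECTIONS = {
    "geometry": LVShapeSpec,
    "material": MaterialParams,
    "boundary": BoundaryConditions,
    "solver": SolverSettings,
    "mask": MaskConfig,
    "pericardium": PericardiumConfig,
    "bayesopt": BOSettings,
}

_TUPLE_FIELDS = {"checkpoint_fractions", "init_params", "bounds"}


def _build(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if f.name in _TUPLE_FIELDS and isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {name: _build(cls, data.get(name, {}) or {}) for name, cls in _SECTIONS.items()}
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
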