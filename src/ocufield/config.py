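"""Study configuration: YAML round-trip, validation, provenance embedding."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from .meshing import HeadGeometryParams
from .tissues import ConductivityTable, default_conductivities

__all__ = ["StudyConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Resolved configuration of a full interference study.

    ``frequency_hz`` is informational: at low frequency the quasi-static
    solve is frequency-independent.  ``conductivity_overrides`` is the only
    way to depart from the reference tissue table — overrides are always
    explicit, never applied silently.
    """

    geometry: HeadGeometryParams = field(default_factory=HeadGeometryParams)
    conductivity_overrides: Dict[str, float] = field(default_factory=dict)
    families: Tuple[str, ...] = ("separation_sweep", "intended_region",
                                 "one_eye", "center_boost")
    currents_mA: Tuple[float, ...] = (1.0, 2.0)
    frequency_hz: float = 10.0
    solver_rtol: float = 1e-10
    seed: int = 0
    mesh_file: Optional[str] = None     # user-supplied MSH/VTK instead of synthetic
    output_dir: str = "scratch/study"
    run_verification: bool = True

    def conductivities(self) -> ConductivityTable:
        return ConductivityTable(overrides=self.conductivity_overrides)

    def validate(self) -> None:
        self.geometry.validate()
        from .montage import FAMILIES
        for fam in self.families:
            if fam not in FAMILIES:
                raise ConfigError(f"unknown montage family {fam!r}")
        if any(c <= 0 for c in self.currents_mA):
            raise ConfigError("currents must be positive")
        # fail fast on inconsistent conductivity overrides
        table = self.conductivities()
        from .tissues import TISSUES
        unknown = set(self.conductivity_overrides) - set(TISSUES)
        if unknown:
            raise ConfigError(f"conductivity overrides for unknown tissues: "
                              f"{sorted(unknown)}")
        assert all(t in table for t in TISSUES)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "StudyConfig":
        d = dict(d)
        geo = d.pop("geometry", {})
        if isinstance(geo, dict):
            geo = {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                       if isinstance(v, list) else v)
                   for k, v in geo.items()}
            geo = HeadGeometryParams(**geo)
        for key in ("families", "currents_mA"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(geometry=geo, **d)


def save_config(config: StudyConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def load_config(path: str) -> StudyConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    cfg = StudyConfig.from_dict(data or {})
    cfg.validate()
    return cfg
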