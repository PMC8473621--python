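"""Structured run configuration with YAML round-tripping.

A :class:`SimulationConfig` bundles every parameter of a seeding run —
geometry, rheology, flow, injection, adhesion, grid and seed — with the
study defaults: 1 mm/s marrow inflow, 2.5 s fill window, 5 s total,
50,000 cells of 25 um at 1000 kg/m^3 with 0.03 N/m surface tension,
marrow density 1050 kg/m^3 and power-law k = 0.017, n = 0.708 clamped
to [0.001, 0.01] Pa.s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .adhesion import AdhesionConfig
from .flow import FlowConfig
from .geometry import DefectSpec, ScaffoldSpec
from .rheology import MarrowRheology
from .transport import InjectionSchedule

SCENARIOS = ("no_injection", "continued_injection")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one seeding run."""

    scaffold: ScaffoldSpec = field(default_factory=ScaffoldSpec)
    defect: DefectSpec = field(default_factory=DefectSpec)
    rheology: MarrowRheology = field(default_factory=MarrowRheology)
    flow: FlowConfig = field(default_factory=FlowConfig)
    injection: InjectionSchedule = field(default_factory=InjectionSchedule)
    adhesion: AdhesionConfig = field(default_factory=AdhesionConfig)
    nx: int = 64
    nz: int = 96
    n_bands: int = 5
    seed: int = 0
    scenario: str = "continued_injection"
    sample_interval: float = 0.1    # series sampling, s

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        # the scenario switch drives both fluid and cell injection
        self.flow = dataclasses.replace(
            self.flow, post_fill_inflow=self.scenario == "continued_injection")
        self.injection = dataclasses.replace(
            self.injection, post_fill_mode=self.scenario,
            window=(0.0, self.flow.fill_duration),
            speed=self.flow.inlet_speed, seed=self.seed)
        self.adhesion = dataclasses.replace(
            self.adhesion, attach_start=self.flow.fill_duration)

    def sync(self) -> "SimulationConfig":
        """Re-derive the scenario-coupled fields after mutating members."""
        self.__post_init__()
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kinds = {"scaffold": ScaffoldSpec, "defect": DefectSpec,
                 "rheology": MarrowRheology, "flow": FlowConfig,
                 "injection": InjectionSchedule, "adhesion": AdhesionConfig}
        kwargs = {}
        for key, value in data.items():
            if key in kinds and isinstance(value, dict):
                value = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in value.items()}
                kwargs[key] = kinds[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
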