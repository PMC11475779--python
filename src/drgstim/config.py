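"""Run configuration: schema-validated YAML with explicit units.

A RunConfig gathers every tunable of a simulation run — tissue geometry
and conductivities, neuron kinetics, population placement, stimulation
protocol, analysis settings and seeds — so that a run is reconstructible
from its configuration and the package version.  Unknown keys are
rejected.  A single root seed spawns per-stage seeds through a fixed
counter scheme so all randomness flows from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .neuron.channels import ChannelKinetics
from .population.diameters import DiameterDistribution
from .population.placement import PlacementConfig
from .stimulation.waveform import PulseWaveform
from .volume.geometry import ConductivityTable, ElectrodeSpec, TissueGeometry

# stage offsets for seed spawning
_SEED_STAGES = {"population": 1, "subsample": 2, "fixtures": 3, "analysis": 4}


@dataclass
class SolverConfig:
    coarse_resolution: float = 0.1  # mm
    fine_resolution: float = 0.05  # mm
    rtol: float = 1e-8


@dataclass
class AnalysisConfig:
    subsample_size: int = 2500
    subsample_repetitions: int = 100
    first_k: int = 20
    step_ua: float = 1.0
    slope_window: tuple = (0.10, 0.90)
    threshold_tolerance: float = 0.01


@dataclass
class RunConfig:
    geometry: TissueGeometry = field(default_factory=TissueGeometry)
    conductivities: ConductivityTable = field(default_factory=ConductivityTable)
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    solver: SolverConfig = field(default_factory=SolverConfig)
    kinetics: ChannelKinetics = field(default_factory=ChannelKinetics)
    diameters: DiameterDistribution = field(default_factory=DiameterDistribution)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    pulse: PulseWaveform = field(default_factory=PulseWaveform)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        if stage not in _SEED_STAGES:
            raise KeyError(f"unknown seed stage {stage!r}")
        return (self.seed * 1000 + _SEED_STAGES[stage]) % (2**31 - 1)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = {
                    k: (list(x) if isinstance(x, tuple) else x)
                    for k, x in dataclasses.asdict(v).items()
                }
            else:
                out[f.name] = v
        return out

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def manifest(self) -> dict:
        """Config hash + version, written next to every CLI output."""
        from . import __version__

        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "drgstim_version": __version__,
        }


class ConfigError(ValueError):
    pass


def _build_section(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {path}: {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file -> defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    section_types = {f.name: f.default_factory for f in fields(RunConfig)
                     if f.name != "seed"}
    unknown = set(data) - set(section_types) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, factory in section_types.items():
        if name in data:
            kwargs[name] = _build_section(factory, data[name] or {}, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    cfg = RunConfig(**kwargs)
    cfg.geometry.validate()
    cfg.conductivities.validate()
    cfg.electrode.validate()
    cfg.kinetics.validate()
    cfg.placement.validate()
    cfg.diameters.validate()
    return cfg
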