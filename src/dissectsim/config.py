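"""Run configuration: a typed tree of the geometry, mesh, fluid, waveform,
Windkessel, thrombosis, flap and run-control blocks, with lossless
YAML round-tripping and a config hash for provenance.

Every model constant carries its standard default; overrides are echoed to
the run log by the runner.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .flap import E_PRESETS, FlapParams
from .geometry import DissectionGeometry
from .hemodynamics import BodyForceField, InletWaveform, WindkesselParams
from .rheology import FluidProperties, QuemadaParams
from .thrombosis import ThrombosisParams


@dataclass
class MeshConfig:
    target_edge_length: float = 1.0  # mm
    wall_layers: int = 0


@dataclass
class FluidConfig:
    density: float = 1060.0
    constant_viscosity: float | None = None  # Pa.s; overrides Quemada if set
    plasma_viscosity: float = 1.2e-3
    hematocrit: float = 0.45
    k0: float = 4.33
    k_inf: float = 2.07
    gamma_c: float = 1.88

    def build(self) -> FluidProperties:
        return FluidProperties(
            density=self.density,
            rheology=QuemadaParams(self.plasma_viscosity, self.hematocrit,
                                   self.k0, self.k_inf, self.gamma_c),
            constant_viscosity=self.constant_viscosity,
        )


@dataclass
class WaveformConfig:
    frequency: float = 1.02  # Hz
    mean_velocity: float = 0.09  # m/s

    def build(self) -> InletWaveform:
        return InletWaveform(self.frequency, self.mean_velocity)


@dataclass
class WindkesselConfig:
    C: float = 2.0e-7
    R_p: float = 7.2e6
    R_c: float = 4.0e5
    P0: float = 1.28e4

    def build(self) -> WindkesselParams:
        return WindkesselParams(self.C, self.R_p, self.R_c, self.P0)


@dataclass
class ThrombosisConfig:
    enabled: bool = True
    D_RP: float = 1.6e-13
    D_AP: float = 1.6e-11
    D_C_base: float = 1.0e-8
    k_RP: float = -0.15
    k_AP: float = 3.0
    k_C1: float = 16.0
    k_C2: float = -6.0
    k_BP: float = 12.0
    k_c_wall: float = 16.0
    gamma_t: float = 50.0
    AP_t: float = 15.0
    C_t: float = 10.0
    BP_t: float = 20.0
    tawss_threshold: float = 0.15
    wall_value: float = 2.0
    inlet_value: float = 1.0
    literal_shear_switch: bool = False
    k_M: float = 1.0e7  # momentum-sink constant

    def build(self) -> ThrombosisParams:
        f = {k.name: getattr(self, k.name)
             for k in dataclasses.fields(ThrombosisParams)}
        return ThrombosisParams(**f)

    def build_force(self) -> BodyForceField:
        return BodyForceField(k_M=self.k_M, BP_t=self.BP_t)


@dataclass
class FlapConfig:
    preset: str | None = "flexible"  # rigid | stiffer | flexible | None
    E_flap: float | None = None  # Pa, used when preset is None
    under_relaxation: float = 0.5
    cap_fraction: float = 0.4  # of the narrower lumen
    n_stations: int = 257
    fsi: bool = True  # False freezes the flap regardless of stiffness
    foundation: float | None = None  # Pa/m; None -> 384 E I / b^4 with b = fl_width

    def young_modulus(self) -> float:
        if self.preset is not None:
            return E_PRESETS[self.preset]
        if self.E_flap is None:
            raise ValueError("either preset or E_flap must be given")
        return self.E_flap

    def build(self, geometry: DissectionGeometry) -> FlapParams:
        cap = 1e-3 * self.cap_fraction * min(geometry.tl_width, geometry.fl_width)
        E = self.young_modulus()
        thick = geometry.flap_thickness * 1e-3
        if self.foundation is None and np.isfinite(E):
            b = geometry.fl_width * 1e-3
            foundation = 384.0 * E * thick**3 / 12.0 / b**4
        else:
            foundation = self.foundation or 0.0
        return FlapParams(
            E_flap=E,
            thickness=thick,
            span=geometry.dissected_length * 1e-3,
            n_stations=self.n_stations,
            displacement_cap=cap,
            under_relaxation=self.under_relaxation,
            foundation=foundation,
        )


@dataclass
class RunConfig:
    pre_cycles: int = 3  # flow-only cycles before thrombosis switches on
    cycles: int = 12  # coupled cycles (upper bound)
    steps_per_cycle: int = 2000
    output_every: int = 0  # VTK cadence in steps; 0 disables
    checkpoint_every_cycles: int = 0  # 0 disables
    wss_every: int = 5  # TAWSS quadrature cadence in steps
    growth_tolerance: float = 1e-3  # per-cycle growth < this x FL volume stops
    seed: int = 0
    outdir: str = "runs/run"


@dataclass
class SimulationConfig:
    geometry: DissectionGeometry = field(default_factory=DissectionGeometry)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    windkessel: WindkesselConfig = field(default_factory=WindkesselConfig)
    thrombosis: ThrombosisConfig = field(default_factory=ThrombosisConfig)
    flap: FlapConfig = field(default_factory=FlapConfig)
    run: RunConfig = field(default_factory=RunConfig)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kw = {}
        blocks = {f.name: f for f in dataclasses.fields(cls)}
        for name, f in blocks.items():
            sub = d.get(name, {})
            typ = f.default_factory  # type: ignore[union-attr]
            known = {x.name for x in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in config block '{name}': {sorted(unknown)}")
            kw[name] = typ(**sub)
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def overridden_fields(self) -> dict[str, tuple]:
        """Fields that differ from the documented defaults (echoed to log)."""
        ref = SimulationConfig().to_dict()
        cur = self.to_dict()
        out = {}

        def walk(prefix, a, b):
            for k in a:
                if isinstance(a[k], dict):
                    walk(f"{prefix}{k}.", a[k], b[k])
                elif a[k] != b[k]:
                    out[f"{prefix}{k}"] = (b[k], a[k])

        walk("", cur, ref)
        return out

    def apply_overrides(self, pairs: list[str]) -> "SimulationConfig":
        """Apply 'block.key=value' override strings (CLI convenience)."""
        d = self.to_dict()
        for pair in pairs:
            key, _, raw = pair.partition("=")
            if not raw:
                raise ValueError(f"override must look like block.key=value: {pair!r}")
            parts = key.strip().split(".")
            node = d
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = yaml.safe_load(raw)
        return SimulationConfig.from_dict(d)
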