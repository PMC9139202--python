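"""Pipeline configuration: schema, validation, (de)serialization.

The pipeline has ~25 knobs spanning four stages, so runs are driven by a
plain-text YAML file rather than command-line flags.  An empty file is a
valid config: every field has a default, and the defaults reproduce the
reference study conditions — a 4 mm supplying vessel perfused at
0.2 m/s with blood of kinematic viscosity 3.25e-6 m^2/s (Re ~= 246,
conventionally quoted as 250), and a 56 x 1.2 x 0.1 mm chip channel
running water-like medium at 7e-4 Pa s.

Unknown keys are rejected with the list of valid keys; the physics-
derived Reynolds number and any explicit solver override must agree
within 5% or validation fails.
"""

from __future__ import annotations

import hashlib
import json

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .chip import ChipSpec
from .errors import ConfigError
from .geometry import AneurysmParams
from .solver import InletWaveform, SolverConfig, reynolds_number
from .wss import DimensionalScaling

__all__ = ["PipelineConfig", "load_config", "dump_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Section):
    """Synthetic geometry parameters, or the path of an STL surface."""

    kind: str = "sidewall_aneurysm"  # "sidewall_aneurysm" | "straight_vessel" | "stl"
    stl_path: str | None = None
    spacing: float = Field(default=62.5e-6, gt=0)   # m; 16 cells/mm
    refine_factor: int = Field(default=1, ge=1)
    smoothing_radius: int = Field(default=0, ge=0)
    vessel_diameter: float = Field(default=4.0e-3, gt=0)   # m, supply vessel
    vessel_length: float = Field(default=16.0e-3, gt=0)
    sac_radius: float = Field(default=1.6e-3, gt=0)
    neck_width: float = Field(default=1.28e-3, ge=0)
    sac_side: str = "top"
    sac_center_offset: float = Field(default=8.0e-3, gt=0)
    wall_offset: float | None = None
    domain_height: float | None = None

    def params(self) -> AneurysmParams:
        return AneurysmParams(
            vessel_diameter=self.vessel_diameter,
            vessel_length=self.vessel_length,
            sac_radius=self.sac_radius,
            neck_width=self.neck_width,
            sac_side=self.sac_side,
            sac_center_offset=self.sac_center_offset,
        )


class PhysicsConfig(_Section):
    """Dimensional flow conditions of the supplying vessel."""

    inlet_velocity: float = Field(default=0.2, gt=0)        # m/s
    diameter: float = Field(default=4.0e-3, gt=0)           # m
    kinematic_viscosity: float = Field(default=3.25e-6, gt=0)  # m^2/s (blood)
    density: float = Field(default=1060.0, gt=0)            # kg/m^3 (blood)
    waveform_amplitude: float = Field(default=0.0, ge=0, lt=1)
    waveform_period: float = Field(default=1.0, gt=0)       # nondim (D/U units)

    @property
    def reynolds(self) -> float:
        return reynolds_number(self.inlet_velocity, self.diameter, self.kinematic_viscosity)

    def scaling(self) -> DimensionalScaling:
        return DimensionalScaling(
            rho=self.density, nu=self.kinematic_viscosity,
            U=self.inlet_velocity, D=self.diameter,
        )


class SolverSection(_Section):
    reynolds: float | None = None  # override; must agree with physics within 5%
    penalization_eta: float = Field(default=1e-8, gt=0, lt=1)
    cfl: float = Field(default=0.5, gt=0, le=1)
    steady_tol: float = Field(default=1e-6, gt=0)
    poisson_tol: float = Field(default=1e-10, gt=0)
    max_steps: int = Field(default=100_000, ge=1)
    inlet_profile: str = "parabolic"
    n_periods: int = Field(default=3, ge=2)   # pulsatile runs only
    n_phases: int = Field(default=8, ge=1)


class WSSSection(_Section):
    low_percentile: float = Field(default=5.0, gt=0, lt=100)
    high_percentile: float = Field(default=95.0, gt=0, lt=100)
    min_region_faces: int = Field(default=3, ge=1)
    temporal_statistic: str = "time_averaged"  # or "peak" (pulsatile runs)


class ChipSection(_Section):
    length: float = Field(default=56.0e-3, gt=0)
    width: float = Field(default=1.2e-3, gt=0)
    height: float = Field(default=0.1e-3, gt=0)
    viscosity: float = Field(default=7.0e-4, gt=0)
    density: float = Field(default=993.0, gt=0)

    def spec(self) -> ChipSpec:
        return ChipSpec(self.length, self.width, self.height, self.viscosity, self.density)


class OutputSection(_Section):
    directory: str = "aneuchip_out"
    formats: list[str] = Field(default_factory=lambda: ["vtk", "csv", "json"])
    log_level: str = "INFO"


class PipelineConfig(_Section):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    physics: PhysicsConfig = Field(default_factory=PhysicsConfig)
    solver: SolverSection = Field(default_factory=SolverSection)
    wss: WSSSection = Field(default_factory=WSSSection)
    chip: ChipSection = Field(default_factory=ChipSection)
    output: OutputSection = Field(default_factory=OutputSection)
    seed: int = 0  # reserved: the pipeline is fully deterministic

    def effective_reynolds(self) -> float:
        return self.solver.reynolds if self.solver.reynolds is not None else self.physics.reynolds

    def validate_cross(self) -> None:
        if self.solver.reynolds is not None:
            re_phys = self.physics.reynolds
            if abs(self.solver.reynolds - re_phys) > 0.05 * re_phys:
                raise ConfigError(
                    f"solver.reynolds = {self.solver.reynolds:g} disagrees with "
                    f"the physics-derived value {re_phys:.1f} by more than 5%"
                )
        if self.wss.low_percentile >= self.wss.high_percentile:
            raise ConfigError("wss.low_percentile must be below wss.high_percentile")
        if self.geometry.kind == "stl":
            import os

            if not self.geometry.stl_path or not os.path.exists(self.geometry.stl_path):
                raise ConfigError(f"geometry.stl_path does not exist: {self.geometry.stl_path!r}")

    def solver_config(self) -> SolverConfig:
        wf = InletWaveform(
            mean=1.0,
            amplitude=self.physics.waveform_amplitude,
            period=self.physics.waveform_period,
        )
        return SolverConfig(
            reynolds=self.effective_reynolds(),
            penalization_eta=self.solver.penalization_eta,
            cfl=self.solver.cfl,
            steady_tol=self.solver.steady_tol,
            poisson_tol=self.solver.poisson_tol,
            max_steps=self.solver.max_steps,
            waveform=wf,
            inlet_profile=self.solver.inlet_profile,
            length_scale=self.physics.diameter,
        )


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and fully validate a YAML config; ``None`` or an empty file
    yields the all-defaults configuration."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
            data = loaded
    if overrides:
        for key, val in overrides.items():
            data.setdefault(key, {})
            if isinstance(val, dict):
                data[key] = {**data[key], **val}
            else:
                data[key] = val
    try:
        cfg = PipelineConfig(**data)
    except pydantic.ValidationError as err:
        msgs = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            if e["type"] == "extra_forbidden":
                section = e["loc"][:-1]
                model = PipelineConfig
                for part in section:
                    model = model.model_fields[part].annotation
                valid = ", ".join(model.model_fields)
                msgs.append(f"unknown key '{loc}'; valid keys: {valid}")
            else:
                msgs.append(f"{loc}: {e['msg']}")
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(msgs)) from None
    cfg.validate_cross()
    return cfg


# annotations attached to defaults that carry the reference study
# conditions, rendered as comments in config dumps
_ANNOTATIONS = {
    ("physics", "inlet_velocity"): "reference supply-vessel inlet velocity [m/s]",
    ("physics", "diameter"): "reference supply-vessel diameter, the length scale [m]",
    ("physics", "kinematic_viscosity"): "kinematic viscosity of blood [m^2/s]",
    ("chip", "length"): "chip channel length [m]",
    ("chip", "width"): "chip channel width [m]",
    ("chip", "height"): "chip channel height [m]",
    ("chip", "viscosity"): "dynamic viscosity of water at 37 C [Pa s]",
}


def dump_config(cfg: PipelineConfig) -> str:
    """Render a config as YAML; defaults holding reference study values
    carry an explanatory comment."""
    data = cfg.model_dump()
    lines = []
    for section, content in data.items():
        if not isinstance(content, dict):
            lines.append(yaml.safe_dump({section: content}, default_flow_style=False).strip())
            continue
        lines.append(f"{section}:")
        for key, val in content.items():
            rendered = yaml.safe_dump({key: val}, default_flow_style=True).strip().strip("{}").strip()
            note = _ANNOTATIONS.get((section, key))
            lines.append(f"  {rendered}" + (f"  # {note}" if note else ""))
    return "\n".join(lines) + "\n"


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the fully-resolved configuration."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
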