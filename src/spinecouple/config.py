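"""Configuration for the coupled spine pipeline.

All sections are plain dataclasses with physically meaningful defaults and a
single YAML file as the external representation.  Units follow the package
convention: millimetres, newtons, N·mm, MPa; rotational stiffnesses are
N·mm/rad, translational stiffnesses N/mm.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigurationError

VERTEBRA_LABELS = ("T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5")
INTERVERTEBRAL_JOINTS = (
    "T10/T11", "T11/T12", "T12/L1", "L1/L2",
    "L2/L3", "L3/L4", "L4/L5", "L5/S1",
)
SIJ_JOINTS = ("SIJ-left", "SIJ-right")
ALL_JOINTS = INTERVERTEBRAL_JOINTS + SIJ_JOINTS

MUSCLE_GROUPS = (
    "transversus", "spinalis", "semispinalis", "erector_spinae",
    "obliquus_internus", "obliquus_externus", "psoas_major",
    "multifidi", "quadratus_lumborum",
)


def _default_wedges() -> dict:
    # Sagittal wedge per joint, degrees; positive opens anteriorly (lordosis).
    return {
        "T10/T11": -3.0, "T11/T12": -2.0, "T12/L1": 0.0, "L1/L2": 2.0,
        "L2/L3": 4.0, "L3/L4": 6.0, "L4/L5": 8.0, "L5/S1": 10.0,
    }


@dataclass
class AnatomyConfig:
    """Parametric synthetic T10-pelvis anatomy (standing posture)."""

    body_height_mm: float = 28.0
    disc_height_mm: float = 10.0
    wedge_deg: dict = field(default_factory=_default_wedges)
    base_tilt_deg: float = 20.0           # sacral slope, anterior positive
    body_halfdepth_mm: float = 18.0       # anteroposterior half extent
    body_halfwidth_mm: float = 22.0
    spinous_offset_mm: float = 55.0       # posterior spinous attachment
    lamina_offset_mm: float = 45.0
    transverse_offset_mm: float = 38.0
    pedicle_posterior_mm: float = 40.0
    pedicle_lateral_mm: float = 18.0
    sacrum_height_mm: float = 50.0
    sacrum_center_z_mm: float = 70.0
    sij_lateral_mm: float = 40.0
    sij_posterior_mm: float = 20.0
    sagittal_symmetry: bool = True

    def validate(self) -> None:
        for name in ("body_height_mm", "disc_height_mm", "sacrum_height_mm",
                     "body_halfdepth_mm", "body_halfwidth_mm"):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"anatomy.{name} must be > 0")
        for joint in INTERVERTEBRAL_JOINTS:
            if joint not in self.wedge_deg:
                raise ConfigurationError(f"anatomy.wedge_deg missing joint {joint!r}")
            if abs(self.wedge_deg[joint]) >= 30.0:
                raise ConfigurationError(
                    f"anatomy.wedge_deg[{joint!r}] out of the small-angle range")


def _default_pcsa() -> dict:
    # Physiological cross-sectional area per fascicle, cm^2 (per slip, per side).
    return {
        "erector_spinae": 4.0, "multifidi": 2.0, "spinalis": 1.5,
        "semispinalis": 1.5, "transversus": 1.5, "obliquus_internus": 3.0,
        "obliquus_externus": 3.0, "psoas_major": 3.0, "quadratus_lumborum": 1.5,
    }


@dataclass
class MuscleConfig:
    """Fascicle strengths: f_max = PCSA x specific tension."""

    specific_tension_n_per_cm2: float = 90.0
    pcsa_cm2: dict = field(default_factory=_default_pcsa)

    def validate(self) -> None:
        if self.specific_tension_n_per_cm2 <= 0.0:
            raise ConfigurationError("muscles.specific_tension_n_per_cm2 must be > 0")
        for group in MUSCLE_GROUPS:
            if self.pcsa_cm2.get(group, 0.0) <= 0.0:
                raise ConfigurationError(f"muscles.pcsa_cm2[{group!r}] must be > 0")


@dataclass
class JointsConfig:
    """Lumped bushing stiffnesses for discs+facets and the sacroiliac joints.

    Rotational triples are (lateral-bending X, flexion-extension Y, axial Z)
    in N·mm/rad, expressed in the joint frame; translational triples are
    (anteroposterior, lateral, axial) in N/mm.
    """

    intervertebral_k_rot: tuple = (220000.0, 170000.0, 300000.0)
    intervertebral_k_trans: tuple = (500.0, 500.0, 2500.0)
    thoracic_rot_scale: float = 1.3       # T10/T11..T12/L1 stiffer than lumbar
    sij_k_rot: tuple = (1.0e7, 1.0e7, 1.0e7)
    sij_k_trans: tuple = (5000.0, 5000.0, 5000.0)
    k_rot_overrides: dict = field(default_factory=dict)   # joint -> 3 values

    def validate(self) -> None:
        for name in ("intervertebral_k_rot", "intervertebral_k_trans",
                     "sij_k_rot", "sij_k_trans"):
            if any(v <= 0.0 for v in getattr(self, name)):
                raise ConfigurationError(f"joints.{name} entries must be > 0")
        if self.thoracic_rot_scale <= 0.0:
            raise ConfigurationError("joints.thoracic_rot_scale must be > 0")


def _default_ligament_curves() -> dict:
    # Piecewise-linear force-elongation points (mm, N) beyond slack; the last
    # slope extrapolates.  Tension-only is implicit.
    return {
        "interspinous": [[0.0, 0.0], [1.0, 8.0], [3.0, 40.0], [8.0, 140.0]],
        "anterior_longitudinal": [[0.0, 0.0], [1.0, 10.0], [3.0, 50.0], [8.0, 170.0]],
        "intertransverse": [[0.0, 0.0], [1.0, 4.0], [3.0, 20.0], [8.0, 70.0]],
    }


@dataclass
class LigamentsConfig:
    """Tension-only nonlinear springs per intervertebral level."""

    enabled: bool = True
    slack_mm: float = 1.5
    curves: dict = field(default_factory=_default_ligament_curves)

    def validate(self) -> None:
        if self.slack_mm < 0.0:
            raise ConfigurationError("ligaments.slack_mm must be >= 0")
        for name, pts in self.curves.items():
            forces = [p[1] for p in pts]
            if any(b < a for a, b in zip(forces, forces[1:])):
                raise ConfigurationError(
                    f"ligaments.curves[{name!r}] must be monotone non-decreasing")


@dataclass
class FixationConfig:
    """L1-L5 posterior fixation: titanium pedicle screws and rods."""

    levels: tuple = ("L1", "L2", "L3", "L4", "L5")
    rod_diameter_mm: float = 5.5
    screw_diameter_mm: float = 6.0
    screw_length_mm: float = 45.0
    elastic_modulus_mpa: float = 110000.0
    poisson: float = 0.3
    yield_stress_mpa: Optional[float] = None
    medial_angle_deg: float = 15.0        # screw convergence in the axial plane
    head_offset_mm: float = 8.0           # tulip standoff from the entry point
    rod_elements_per_span: int = 2

    def validate(self) -> None:
        if len(self.levels) < 2:
            raise ConfigurationError("fixation.levels needs >= 2 instrumented levels")
        for name in ("rod_diameter_mm", "screw_diameter_mm", "screw_length_mm",
                     "elastic_modulus_mpa", "head_offset_mm"):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"fixation.{name} must be > 0")
        if not 0.0 <= self.poisson < 0.5:
            raise ConfigurationError("fixation.poisson must be in [0, 0.5)")
        if self.rod_elements_per_span < 2:
            raise ConfigurationError("fixation.rod_elements_per_span must be >= 2")


@dataclass
class SolverConfig:
    """Newton solve tolerances and MSK rigid-joint handling."""

    tol_rel: float = 1e-8
    tol_abs_n: float = 1e-6
    max_iterations: int = 50
    rigid_ceiling_nmm_per_deg: float = 1e6
    fused_rom_tol_deg: float = 0.1

    def validate(self) -> None:
        if self.tol_rel <= 0.0 or self.tol_abs_n <= 0.0:
            raise ConfigurationError("solver tolerances must be > 0")
        if self.max_iterations < 1:
            raise ConfigurationError("solver.max_iterations must be >= 1")


@dataclass
class RecruitmentConfig:
    """Static-optimization muscle recruitment and realistic-loading gravity.

    Gravity acts only in the realistic loading mode (the simplified mode is a
    pure moment without compressive load): trunk-slice weights at the
    vertebral bodies and the weight of everything above T10 (head, arms,
    upper thorax) entering at the T10 boundary.
    """

    exponent: float = 3.0                 # polynomial criterion sum (f/fmax)^p
    gravity: bool = True
    segment_mass_kg: float = 1.5          # per vertebral body slice
    upper_body_mass_kg: float = 22.0      # head+arms+thorax above T10
    upper_body_com_offset_mm: tuple = (0.0, 0.0, 120.0)  # from the T10 center
    equilibrium_tol_rel: float = 1e-9

    def validate(self) -> None:
        if self.exponent <= 1.0:
            raise ConfigurationError("recruitment.exponent must be > 1 for uniqueness")
        if self.segment_mass_kg < 0.0 or self.upper_body_mass_kg < 0.0:
            raise ConfigurationError("recruitment masses must be >= 0")


@dataclass
class ReportingConfig:
    """Coupling-consistency bounds and the working pure-moment magnitude."""

    pure_moment_nmm: float = 7500.0
    rom_bound_intact_deg: float = 0.7
    rom_bound_instrumented_deg: float = 0.3
    t10_moment_bound_pct: float = 3.5

    def validate(self) -> None:
        if self.pure_moment_nmm <= 0.0:
            raise ConfigurationError("reporting.pure_moment_nmm must be > 0")


@dataclass
class PipelineConfig:
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    muscles: MuscleConfig = field(default_factory=MuscleConfig)
    joints: JointsConfig = field(default_factory=JointsConfig)
    ligaments: LigamentsConfig = field(default_factory=LigamentsConfig)
    fixation: FixationConfig = field(default_factory=FixationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    recruitment: RecruitmentConfig = field(default_factory=RecruitmentConfig)
    reporting: ReportingConfig = field(default_factory=ReportingConfig)
    seed: int = 0
    output_dir: str = "spinecouple_out"

    def validate(self) -> "PipelineConfig":
        for section in ("anatomy", "muscles", "joints", "ligaments",
                        "fixation", "solver", "recruitment", "reporting"):
            getattr(self, section).validate()
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in (data or {}).items():
            if key not in sections:
                raise ConfigurationError(f"unknown config section {key!r}")
            if key in ("seed", "output_dir"):
                setattr(cfg, key, value)
                continue
            section = getattr(cfg, key)
            valid = {f.name for f in dataclasses.fields(section)}
            for name, v in (value or {}).items():
                if name not in valid:
                    raise ConfigurationError(f"unknown config field {key}.{name}")
                default = getattr(section, name)
                if isinstance(default, tuple) and isinstance(v, list):
                    v = tuple(v)
                setattr(section, name, v)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
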