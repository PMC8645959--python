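"""Three-stage coupling pipeline and consistency reporting.

Stage A solves the FE model under a pure moment (simplified loading) and
extracts per-joint rotations.  Stage B imposes those rotations on the
stiffness-calibrated MSK model and recruits muscle forces by static
optimization.  Stage C re-solves the FE model driven by the recruited muscle
forces, the T10 boundary loads and the MSK-predicted T10 translation
(realistic loading).  The validation logic compares the two loading modes:
per-joint ROM agreement, T10-level reaction-moment agreement, and implant
stress deltas for the instrumented variant.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import build_default_spine, build_muscle_set
from .config import PipelineConfig
from .errors import PipelineStateError, SpineCoupleError
from .fe_solver import (FEResult, apply_muscle_loads, apply_pure_moment,
                        assemble, compute_rom, internal_cut_wrench,
                        make_bushings, make_ligaments, solve_static)
from .fixation import FixationConstruct, build_fixation, fuse_msk
from .motions import COUPLED_MOTIONS, motion_axis
from .msk_inverse import (ImposedMotion, MuscleForceSolution,
                          calibrate_stiffness, equilibrium_certificate,
                          gravity_loads, solve_msk)

logger = logging.getLogger(__name__)

VARIANTS = ("intact", "instrumented")

#: cut used for the FE-vs-MSK reaction-moment consistency check: the joint
#: directly below the T10 boundary body (the model is truncated at T10).
T10_CUT = "T10/T11"


@dataclass
class CouplingReport:
    """Simplified-vs-realistic comparison for one variant and motion."""

    motion: str
    model_variant: str
    rom_simplified: dict                  # joint -> degrees
    rom_realistic: dict
    rom_max_abs_diff: float
    t10_moment_fe: float                  # N·mm, motion-axis component
    t10_moment_msk: float
    t10_moment_rel_diff: float            # fraction
    t10_moment_fe_norm: float = 0.0       # secondary: full vector norms
    t10_moment_msk_norm: float = 0.0
    screw_stresses: dict = field(default_factory=dict)   # comp -> {mode: MPa}
    rod_stresses: dict = field(default_factory=dict)
    stress_delta: dict = field(default_factory=dict)     # comp -> MPa (C - A)
    stress_delta_pct_yield: Optional[dict] = None


@dataclass
class RunOutput:
    variant: str
    motion: str
    fe_simplified: FEResult
    solution: Optional[MuscleForceSolution]
    fe_realistic: Optional[FEResult]
    report: Optional[CouplingReport]


class CoupledPipeline:
    """Caches the synthetic anatomy, muscle set and per-variant calibration
    so repeated stage runs share the expensive FE solves."""

    def __init__(self, config: Optional[PipelineConfig] = None):
        self.config = (config or PipelineConfig()).validate()
        self.geometry = build_default_spine(self.config.anatomy)
        self.fascicles = build_muscle_set(self.geometry, self.config.muscles,
                                          self.config.anatomy)
        self.bushings = make_bushings(self.geometry, self.config.joints)
        self.ligaments = make_ligaments(self.geometry, self.config.ligaments,
                                        self.config.anatomy)
        self._construct: Optional[FixationConstruct] = None
        self._calibration: dict = {}

    # -- shared pieces ------------------------------------------------------
    @property
    def construct(self) -> FixationConstruct:
        if self._construct is None:
            self._construct = build_fixation(self.geometry, self.config.fixation)
        return self._construct

    @property
    def fused_joints(self) -> tuple:
        return tuple(fuse_msk(self.config.fixation.levels))

    def _instrumentation(self, variant: str):
        if variant not in VARIANTS:
            raise SpineCoupleError(f"unknown model variant {variant!r}")
        return self.construct if variant == "instrumented" else None

    def _assemble(self, variant: str):
        return assemble(self.geometry, self.bushings, self.ligaments,
                        self._instrumentation(variant))

    def calibration(self, variant: str, motion: str) -> dict:
        key = (variant, motion)
        if key not in self._calibration:
            cal = calibrate_stiffness(
                self.geometry, self.bushings, self.ligaments,
                self._instrumentation(variant), motions=(motion,),
                magnitude=self.config.reporting.pure_moment_nmm,
                solver=self.config.solver,
                rigid_ceiling_nmm_per_deg=self.config.solver.rigid_ceiling_nmm_per_deg)
            self._calibration[key] = cal[motion]
        return self._calibration[key]

    # -- stages -------------------------------------------------------------
    def stage_a_simplified(self, variant: str, motion: str) -> FEResult:
        """FE solve under the 7.5 N·m pure moment; ROMs extracted."""
        model = self._assemble(variant)
        apply_pure_moment(model, motion, self.config.reporting.pure_moment_nmm)
        return solve_static(model, self.config.solver)

    def stage_b_msk(self, variant: str, motion: str,
                    rom_from_a: dict) -> MuscleForceSolution:
        """Calibrated stiffness -> inverse statics -> recruitment."""
        if motion not in COUPLED_MOTIONS:
            raise SpineCoupleError(
                f"motion {motion!r} is not carried through the coupling "
                "(axial rotation is simplified-loading only)")
        # Fused joints are not zeroed out: their stage-A rotations are already
        # negligible and their instrumented-FE secant stiffness transmits the
        # full cut moment, which hard zero-rotation constraints would leave
        # indeterminate (and the muscle solution would then not reproduce it).
        imposed = ImposedMotion(motion=motion, rotations=dict(rom_from_a))
        solution = solve_msk(self.geometry, self.fascicles, imposed,
                             self.calibration(variant, motion),
                             self.config.recruitment, bushings=self.bushings)
        # refine the T10 translation prediction with the shared-anatomy lumped
        # compliance (force-dependent kinematics): a load-controlled solve of
        # the same model under the recruited loads, free at T10
        probe = self._realistic_model(variant, solution, prescribe=False)
        free = solve_static(probe, self.config.solver)
        solution.t10_translation = free.u["T10"][:3].copy()
        certificate = equilibrium_certificate(
            solution.fascicle_forces, self.fascicles,
            solution.required_moments, self.geometry)
        if certificate > 1e-6:
            raise SpineCoupleError(
                f"recruitment equilibrium certificate {certificate:.3e} "
                "failed")
        return solution

    def _realistic_model(self, variant: str, solution: MuscleForceSolution,
                         prescribe: bool):
        """Assemble the realistic-loading model: muscle forces, T10 boundary
        loads (upper-body weight), trunk-slice weights, optional prescribed
        T10 translation."""
        model = self._assemble(variant)
        apply_muscle_loads(model, solution, self.fascicles,
                           prescribe_translation=prescribe)
        rec = self.config.recruitment
        if rec.gravity:
            # trunk-slice weights at their posture-displaced positions (the
            # upper-body weight already enters through the T10 reaction load)
            imposed = ImposedMotion(motion=solution.motion,
                                    rotations=dict(solution.imposed_rotations))
            for body, point, w in gravity_loads(self.geometry, rec,
                                                motion=imposed):
                if body != "upper":
                    model.add_force(body, w, point)
        return model

    def stage_c_realistic(self, variant: str, motion: str,
                          solution: MuscleForceSolution) -> FEResult:
        """FE solve driven by muscle forces, T10 loads and translation."""
        if solution.motion != motion:
            raise PipelineStateError(
                f"stage-B solution is for {solution.motion!r}, not {motion!r}")
        model = self._realistic_model(variant, solution, prescribe=True)
        return solve_static(model, self.config.solver)

    # -- full run and report ------------------------------------------------
    def run(self, variant: str, motion: str,
            loading: str = "both") -> RunOutput:
        fe_a = self.stage_a_simplified(variant, motion)
        if loading == "simplified" or motion not in COUPLED_MOTIONS:
            return RunOutput(variant, motion, fe_a, None, None, None)
        rom_a = compute_rom(fe_a, motion)
        solution = self.stage_b_msk(variant, motion, rom_a)
        fe_c = self.stage_c_realistic(variant, motion, solution)
        report = self.validate_and_report(variant, motion, fe_a, solution, fe_c)
        return RunOutput(variant, motion, fe_a, solution, fe_c, report)

    def validate_and_report(self, variant: str, motion: str,
                            fe_a: FEResult, solution: MuscleForceSolution,
                            fe_c: FEResult) -> CouplingReport:
        if fe_a is None or solution is None or fe_c is None:
            raise PipelineStateError("stages A-C must complete before reporting")
        axis = motion_axis(motion)
        rom_a = compute_rom(fe_a, motion)
        rom_c = compute_rom(fe_c, motion)
        rom_diff = max(abs(rom_c[j] - rom_a[j]) for j in rom_a)

        m_msk_vec = np.asarray(solution.passive_moments[T10_CUT], dtype=float)
        _f, m_fe_vec = internal_cut_wrench(fe_c, T10_CUT)
        m_msk = float(m_msk_vec @ axis)
        m_fe = float(m_fe_vec @ axis)
        rel = abs(m_fe - m_msk) / max(abs(m_msk), 1e-12)

        report = CouplingReport(
            motion=motion, model_variant=variant,
            rom_simplified=rom_a, rom_realistic=rom_c,
            rom_max_abs_diff=rom_diff,
            t10_moment_fe=m_fe, t10_moment_msk=m_msk,
            t10_moment_rel_diff=rel,
            t10_moment_fe_norm=float(np.linalg.norm(m_fe_vec)),
            t10_moment_msk_norm=float(np.linalg.norm(m_msk_vec)))

        if variant == "instrumented":
            for comp, vm_a in fe_a.von_mises.items():
                vm_c = fe_c.von_mises[comp]
                bucket = (report.screw_stresses if comp.startswith("screw")
                          else report.rod_stresses)
                bucket[comp] = {"simplified": vm_a, "realistic": vm_c}
                report.stress_delta[comp] = vm_c - vm_a
            yield_stress = self.config.fixation.yield_stress_mpa
            if yield_stress:
                report.stress_delta_pct_yield = {
                    comp: 100.0 * delta / yield_stress
                    for comp, delta in report.stress_delta.items()}
        return report

    def validate(self, motions=COUPLED_MOTIONS) -> tuple:
        """Run the full consistency suite for both variants.

        Returns ``(reports, ok)``: per-run reports and whether every
        configured bound held (ROM agreement per variant, T10 reaction-moment
        agreement, and realistic >= simplified peak implant stresses).
        """
        cfg = self.config.reporting
        reports, ok = [], True
        for variant in VARIANTS:
            bound = (cfg.rom_bound_intact_deg if variant == "intact"
                     else cfg.rom_bound_instrumented_deg)
            for motion in motions:
                out = self.run(variant, motion)
                r = out.report
                reports.append(r)
                if r.rom_max_abs_diff > bound:
                    ok = False
                    logger.warning("%s %s: ROM difference %.3f deg exceeds "
                                   "%.2f deg", variant, motion,
                                   r.rom_max_abs_diff, bound)
                if 100.0 * r.t10_moment_rel_diff > cfg.t10_moment_bound_pct:
                    ok = False
                    logger.warning("%s %s: T10 moment difference %.2f%% "
                                   "exceeds %.2f%%", variant, motion,
                                   100.0 * r.t10_moment_rel_diff,
                                   cfg.t10_moment_bound_pct)
                if variant == "instrumented":
                    for bucket in (r.screw_stresses, r.rod_stresses):
                        if bucket:
                            peak_a = max(v["simplified"] for v in bucket.values())
                            peak_c = max(v["realistic"] for v in bucket.values())
                            if peak_c < peak_a:
                                ok = False
                                logger.warning(
                                    "%s %s: realistic peak stress below "
                                    "simplified", variant, motion)
        return reports, ok


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------

def write_reports(outputs, out_dir, config: PipelineConfig) -> dict:
    """Write rom_comparison.csv, stress_comparison.csv, muscle_forces.csv and
    run_metadata.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rom_rows, stress_rows, force_rows = [], [], []
    for o in outputs:
        if o.report is None:
            continue
        r = o.report
        for joint in r.rom_simplified:
            rom_rows.append({
                "variant": r.model_variant, "motion": r.motion, "joint": joint,
                "rom_simplified_deg": r.rom_simplified[joint],
                "rom_realistic_deg": r.rom_realistic[joint],
                "abs_diff_deg": abs(r.rom_realistic[joint]
                                    - r.rom_simplified[joint])})
        for bucket in (r.screw_stresses, r.rod_stresses):
            for comp, vals in bucket.items():
                row = {"variant": r.model_variant, "motion": r.motion,
                       "component": comp,
                       "simplified_MPa": vals["simplified"],
                       "realistic_MPa": vals["realistic"],
                       "delta_MPa": r.stress_delta[comp]}
                if r.stress_delta_pct_yield is not None:
                    row["delta_pct_yield"] = r.stress_delta_pct_yield[comp]
                stress_rows.append(row)
        if o.solution is not None:
            for name, force in sorted(o.solution.fascicle_forces.items()):
                force_rows.append({"variant": o.variant, "motion": o.motion,
                                   "fascicle": name, "force_N": force})
    paths = {}
    for name, rows in (("rom_comparison", rom_rows),
                       ("stress_comparison", stress_rows),
                       ("muscle_forces", force_rows)):
        path = out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
        paths[name] = path
    meta = {"spinecouple_version": __version__,
            "numpy_version": np.__version__,
            "config": config.to_dict()}
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    paths["metadata"] = meta_path
    return paths
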