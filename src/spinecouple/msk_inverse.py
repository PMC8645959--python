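"""Inverse-static musculoskeletal stage.

The MSK model shares the FE anatomy: a rigid-body chain from the fixed pelvis
to T10 with ideal spherical intervertebral joints carrying linear rotational
springs.  Its three operations are (1) calibration of the joint rotational
stiffnesses against the FE model's moment-rotation behaviour, (2) inverse
statics turning imposed intervertebral rotations into required net joint
moments, and (3) muscle recruitment by static optimization with a polynomial
criterion min sum (f_i/f_max,i)^p, p > 1, subject to moment equilibrium about
every non-fused intervertebral cut and non-negative fascicle forces.

The chain is truncated at T10 (no upper body, gravity off by default), so the
boundary reaction wrench at the T10 upper endplate is zero under the default
conditions; muscles alone equilibrate every cut, including T10/T11.
"""
from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.optimize

from .anatomy import SpineGeometry, moment_arm
from .config import (INTERVERTEBRAL_JOINTS, RecruitmentConfig, SIJ_JOINTS,
                     SolverConfig)
from .errors import RecruitmentError, SpineCoupleError
from .motions import motion_axis

logger = logging.getLogger(__name__)

_GRAVITY_M_PER_S2 = 9.81


def crosses(fascicle, joint: str) -> bool:
    """Does a fascicle's line of action cross the cut through ``joint``?

    "SIJ-pair" is the combined sacrum-pelvis cut through both sacroiliac
    joints."""
    if joint == "SIJ-pair":
        return any(j in fascicle.spanned_joints for j in SIJ_JOINTS)
    return joint in fascicle.spanned_joints


@dataclass
class JointStiffness:
    """Linear rotational stiffness of one intervertebral joint, N·mm/rad.

    No translational or coupling terms: the MSK joints are ideal spherical
    joints plus this rotational spring.  Only the motion-axis response enters
    the inverse statics; ``k_rot`` is stored isotropic with the calibrated
    motion-axis secant.
    """

    joint_label: str
    k_rot: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.k_rot, dtype=float)
        if not np.allclose(K, K.T) or np.any(np.linalg.eigvalsh(K) <= 0.0):
            raise SpineCoupleError(
                f"stiffness {self.joint_label}: k_rot must be SPD")
        self.k_rot = K

    @property
    def k_scalar(self) -> float:
        return float(self.k_rot[0, 0])


@dataclass
class ImposedMotion:
    """Per-joint rotations (degrees, about the motion axis) to hold."""

    motion: str
    rotations: dict                       # joint -> degrees
    fused_joints: tuple = ()

    def __post_init__(self) -> None:
        for j in self.fused_joints:
            self.rotations[j] = 0.0


@dataclass
class MuscleForceSolution:
    """Recruited fascicle forces plus the T10 boundary hand-off record."""

    motion: str
    fascicle_forces: dict                 # name -> N
    t10_reaction: tuple                   # (force (3,), moment (3,)) N, N·mm
    t10_translation: np.ndarray           # mm
    objective_value: float
    required_moments: dict = field(default_factory=dict)  # joint -> (3,)
    passive_moments: dict = field(default_factory=dict)   # joint -> (3,)
    imposed_rotations: dict = field(default_factory=dict)  # joint -> degrees

    def __post_init__(self) -> None:
        bad = [n for n, f in self.fascicle_forces.items() if f < -1e-12]
        if bad:
            raise SpineCoupleError(f"negative fascicle forces: {bad}")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_stiffness(geometry: SpineGeometry,
                        bushings,
                        ligaments=(),
                        instrumentation=None,
                        motions: Iterable[str] = ("flexion",),
                        magnitude: float = 7500.0,
                        solver: Optional[SolverConfig] = None,
                        rigid_ceiling_nmm_per_deg: float = 1e6) -> dict:
    """Directional secant calibration against the FE model.

    For each motion, a pure-moment FE solve at the working magnitude gives the
    per-joint rotation; the MSK stiffness is the secant k = M / theta about
    the motion axis (off-axis coupling discarded).  A joint that does not
    rotate (rigid/fused) gets the configured rigid ceiling, with a warning.

    Returns ``{motion: {joint_label: JointStiffness}}``.
    """
    from .fe_solver import apply_pure_moment, assemble, compute_rom, solve_static

    solver = solver or SolverConfig()
    ceiling = rigid_ceiling_nmm_per_deg * 180.0 / math.pi
    out: dict = {}
    for motion in motions:
        model = assemble(geometry, bushings, ligaments, instrumentation)
        apply_pure_moment(model, motion, magnitude)
        rom = compute_rom(solve_static(model, solver), motion)
        per_joint = {}
        rom["SIJ-pair"] = 0.5 * (rom["SIJ-left"] + rom["SIJ-right"])
        for joint in tuple(geometry.joints) + ("SIJ-pair",):
            theta = math.radians(rom[joint])
            if abs(theta) < 1e-12 or magnitude / abs(theta) > ceiling:
                logger.warning("joint %s rigid under %s: stiffness set to the "
                               "configured ceiling", joint, motion)
                k = ceiling
            else:
                k = magnitude / theta     # signed rotation under +magnitude
                if k <= 0.0:
                    raise SpineCoupleError(
                        f"joint {joint}: negative secant stiffness under {motion}")
            per_joint[joint] = JointStiffness(joint_label=joint,
                                             k_rot=k * np.eye(3))
        out[motion] = per_joint
    return out


# ---------------------------------------------------------------------------
# Inverse statics
# ---------------------------------------------------------------------------

def inverse_statics(geometry: SpineGeometry,
                    motion: ImposedMotion,
                    stiffness: dict,
                    recruitment: Optional[RecruitmentConfig] = None) -> dict:
    """Net muscle moment required at every non-fused intervertebral cut.

    The passive moment at a joint is k * theta about the motion axis; holding
    the posture requires the muscles crossing the cut to supply exactly that
    moment (plus the moment balance of segment weights when gravity is on).
    Sacroiliac cuts carry no recruitment constraint: the sacrum-pelvis
    connection is statically indeterminate joint by joint (their moments are
    carried by the joint constraint forces), and adding the pair cut would
    over-determine the cut force; the sacroiliac consistency between loading
    modes is therefore an emergent outcome, not an enforced one.
    """
    recruitment = recruitment or RecruitmentConfig()
    axis = motion_axis(motion.motion)
    required: dict = {}
    for joint in INTERVERTEBRAL_JOINTS:
        if joint in motion.fused_joints:
            continue
        if joint not in stiffness:
            raise SpineCoupleError(f"missing stiffness for joint {joint}")
        theta_deg = motion.rotations.get(joint, 0.0)
        if abs(theta_deg) > 30.0:
            raise SpineCoupleError(
                f"joint {joint}: rotation {theta_deg:.1f} deg outside the "
                "small-angle regime")
        theta = math.radians(theta_deg)
        m = stiffness[joint].k_scalar * theta * axis
        if recruitment.gravity:
            c = geometry.joint_centers[joint]
            for _body, p, w in gravity_loads(geometry, recruitment,
                                             motion=motion, above_joint=joint):
                m -= np.cross(p - c, w)
        required[joint] = m
    return required


def passive_moments(geometry: SpineGeometry, motion: ImposedMotion,
                    stiffness: dict) -> dict:
    """Joint reaction (spring) moments k*theta at the imposed rotations —
    the loads the intervertebral joints themselves transmit, as opposed to
    the net moments the muscles must supply."""
    axis = motion_axis(motion.motion)
    return {joint: stiffness[joint].k_scalar
            * math.radians(motion.rotations.get(joint, 0.0)) * axis
            for joint in INTERVERTEBRAL_JOINTS if joint in stiffness}


def chain_displacement(geometry: SpineGeometry, motion: ImposedMotion,
                       point, body: str) -> np.ndarray:
    """Kinematic displacement of a body-fixed point under the imposed
    rotations (rigid chain from the fixed pelvis, linearized)."""
    axis = motion_axis(motion.motion)
    p = np.asarray(point, dtype=float)
    u = np.zeros(3)
    for joint in geometry.spanned_joints(body, "Pelvis"):
        if joint in SIJ_JOINTS:
            continue
        theta = math.radians(motion.rotations.get(joint, 0.0))
        u += theta * np.cross(axis, p - geometry.joint_centers[joint])
    if body != "Pelvis":
        sij = [math.radians(motion.rotations.get(j, 0.0)) for j in SIJ_JOINTS]
        u += float(np.mean(sij)) * np.cross(
            axis, p - geometry.joint_centers["SIJ-pair"])
    return u


def gravity_loads(geometry: SpineGeometry,
                  recruitment: RecruitmentConfig,
                  motion: Optional[ImposedMotion] = None,
                  above_joint: Optional[str] = None) -> list:
    """(body, point, weight force) triples of the realistic-loading gravity
    set: one trunk slice per vertebral body plus the upper-body weight
    (body "upper", carried at the T10 boundary).  With ``motion``, load
    points are displaced into the imposed posture (so that, e.g., flexing
    carries the upper-body weight anteriorly); with ``above_joint``, only
    loads cranial of that cut."""
    g = _GRAVITY_M_PER_S2
    loads = []
    cranial = (set(geometry.bodies_cranial_of(above_joint))
               if above_joint else None)

    def place(p, body):
        # gravity acts at the imposed-posture positions: static equilibrium
        # is evaluated in the held posture, not the reference one
        p = np.asarray(p, dtype=float)
        if motion is not None:
            p = p + chain_displacement(geometry, motion, p, body)
        return p

    for v in geometry.vertebrae:
        if v.label == "Sacrum":
            continue
        if cranial is None or v.label in cranial:
            loads.append((v.label, place(v.center, v.label),
                          np.array([0.0, 0.0, -recruitment.segment_mass_kg * g])))
    if cranial is None or "T10" in cranial:
        com = geometry.frame("T10").center + np.asarray(
            recruitment.upper_body_com_offset_mm, dtype=float)
        loads.append(("upper", place(com, "T10"),
                      np.array([0.0, 0.0, -recruitment.upper_body_mass_kg * g])))
    return loads


def predict_t10_translation(geometry: SpineGeometry,
                            motion: ImposedMotion,
                            bushings=None,
                            fascicle_forces: Optional[dict] = None,
                            fascicles: Optional[list] = None) -> np.ndarray:
    """T10 body-center translation predicted by the MSK model.

    Forward kinematics of the chain from the fixed pelvis: each joint rotation
    theta about the motion axis displaces everything cranial of it by
    theta x (x - c) (linearized); the sacrum-pelvis step uses the mean of the
    two sacroiliac rotations about their midpoint.

    When the FE bushings and the recruited forces are supplied, the prediction
    additionally includes the translational joint deflections K_trans^-1 F_cut
    produced by the muscle loads (force-dependent kinematics): the rigid-chain
    translation alone is inconsistent with the compliant FE model under
    several hundred newtons of muscle compression.
    """
    axis = motion_axis(motion.motion)
    x_t10 = geometry.frame("T10").center
    u = np.zeros(3)
    for joint in INTERVERTEBRAL_JOINTS:
        theta = math.radians(motion.rotations.get(joint, 0.0))
        u += theta * np.cross(axis, x_t10 - geometry.joint_centers[joint])
    sij = [math.radians(motion.rotations.get(j, 0.0)) for j in SIJ_JOINTS]
    c_sij = 0.5 * (geometry.joint_centers["SIJ-left"]
                   + geometry.joint_centers["SIJ-right"])
    u += float(np.mean(sij)) * np.cross(axis, x_t10 - c_sij)
    if bushings is not None and fascicle_forces is not None:
        u += _translational_deflections(geometry, bushings, fascicle_forces,
                                        fascicles)
    return u


def _cut_force(geometry: SpineGeometry, joint: str,
               fascicle_forces: dict, fascicles: list) -> np.ndarray:
    """Force the cranial part transmits to the caudal part at a joint cut:
    the sum of the muscle forces applied to cranial bodies by fascicles
    crossing the cut (forces of fascicles entirely on one side cancel)."""
    F = np.zeros(3)
    for f in fascicles:
        if crosses(f, joint):
            _p, ucr = f.cranial_attachment(joint, geometry)
            F += fascicle_forces.get(f.name, 0.0) * ucr
    return F


def _translational_deflections(geometry, bushings, fascicle_forces,
                               fascicles) -> np.ndarray:
    by_label = {b.joint_label: b for b in bushings}
    u = np.zeros(3)
    for joint in INTERVERTEBRAL_JOINTS:
        b = by_label[joint]
        F = _cut_force(geometry, joint, fascicle_forces, fascicles)
        K = b.frame @ np.asarray(b.K_trans, float) @ b.frame.T
        u += np.linalg.solve(K, F)
    # sacroiliac pair acts in parallel between sacrum and pelvis
    F = _cut_force(geometry, "SIJ-left", fascicle_forces, fascicles)
    K = sum(np.asarray(by_label[j].K_trans, float) for j in SIJ_JOINTS)
    u += np.linalg.solve(K, F)
    return u


# ---------------------------------------------------------------------------
# Recruitment
# ---------------------------------------------------------------------------

def recruit_muscles(required_moments: dict,
                    fascicles: list,
                    geometry,
                    exponent: float = 3.0,
                    tol_rel: float = 1e-9) -> tuple:
    """Static optimization: min sum (f_i/f_max,i)^p with moment equilibrium.

    ``required_moments`` maps joint labels to 3-vectors (N·mm) that the
    fascicles crossing each cut must produce.  Returns
    ``(forces: dict name -> N, objective_value)``.  Unique for p > 1 (strict
    convexity on the feasible affine set).  Raises RecruitmentError when the
    equality system is infeasible with non-negative forces.
    """
    if exponent <= 1.0:
        raise SpineCoupleError("recruitment exponent must be > 1")
    joints = sorted(required_moments)
    names = [f.name for f in fascicles]
    n = len(fascicles)
    d = np.concatenate([np.asarray(required_moments[j], dtype=float)
                        for j in joints])
    if not joints or not np.any(d):
        return {name: 0.0 for name in names}, 0.0

    C = np.zeros((3 * len(joints), n))
    for k, f in enumerate(fascicles):
        for i, joint in enumerate(joints):
            if crosses(f, joint):
                C[3 * i:3 * i + 3, k] = f.f_max * moment_arm(f, joint, geometry)

    scale = max(np.abs(d).max(), 1.0)
    Cs, ds = C / scale, d / scale

    lp = scipy.optimize.linprog(np.ones(n), A_eq=Cs, b_eq=ds,
                                bounds=[(0.0, None)] * n, method="highs")
    if not lp.success:
        res, _ = scipy.optimize.nnls(Cs, ds)
        viol = Cs @ res - ds
        worst = [joints[i] for i in
                 np.argsort(-np.abs(viol).reshape(-1, 3).sum(axis=1))[:3]]
        raise RecruitmentError(
            f"infeasible equilibrium; largest violations at joints {worst}")

    p = exponent

    def phi(a):
        return float(np.sum(np.abs(a) ** p))

    def grad(a):
        return p * np.abs(a) ** (p - 1.0) * np.sign(a)

    # prefer the min-norm feasible start over the linprog vertex: it spreads
    # load over redundant fascicles, away from degenerate active sets
    a_mn = np.linalg.lstsq(Cs, ds, rcond=None)[0]
    if (a_mn.min() >= -1e-12
            and np.linalg.norm(Cs @ a_mn - ds)
            <= 1e-9 * max(np.linalg.norm(ds), 1.0)):
        x0 = np.clip(a_mn, 0.0, None)
    else:
        x0 = lp.x

    res = scipy.optimize.minimize(
        phi, x0, jac=grad, method="SLSQP",
        bounds=[(0.0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda a: Cs @ a - ds,
                      "jac": lambda a: Cs}],
        options={"ftol": 1e-14, "maxiter": 500})
    a = np.clip(res.x, 0.0, None)
    a = _polish_kkt(a, Cs, ds, p)

    resid = np.linalg.norm(Cs @ a - ds) / max(np.linalg.norm(ds), 1e-30)
    if resid > max(tol_rel, 1e-7):
        raise RecruitmentError(
            f"recruitment equilibrium residual {resid:.3e} above tolerance")
    forces = {name: float(a_i * f.f_max)
              for name, a_i, f in zip(names, a, fascicles)}
    return forces, phi(a)


def _polish_kkt(a, C, d, p, max_outer: int = 8) -> np.ndarray:
    """Newton refinement of the equality-constrained optimum on the inactive
    set (strictly convex there), with an active-set release step driven by
    the KKT multipliers; falls back to the input on failure."""
    a = np.clip(a.copy(), 0.0, None)
    best = a.copy()
    thresh = 1e-8 * max(a.max(), 1.0)
    active = a <= thresh
    for _ in range(max_outer):
        inactive = ~active
        if not inactive.any():
            break
        ai = a[inactive]
        ai = np.maximum(ai, thresh)
        Ci = C[:, inactive]
        lam = np.zeros(C.shape[0])
        ok = True
        for _ in range(40):
            H = np.diag(p * (p - 1.0) * np.maximum(ai, 1e-12) ** (p - 2.0))
            g = p * ai ** (p - 1.0)
            m = Ci.shape[0]
            KKT = np.block([[H, Ci.T], [Ci, np.zeros((m, m))]])
            rhs = np.r_[-g, d - Ci @ ai]
            try:
                sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
            except np.linalg.LinAlgError:
                ok = False
                break
            step, lam = sol[:ai.size], sol[ai.size:]
            ai = ai + step
            if np.linalg.norm(step) <= 1e-14 * max(np.linalg.norm(ai), 1.0):
                break
        if not ok or np.any(~np.isfinite(ai)):
            return best
        if ai.min() < -1e-12:
            # a variable wants to leave the feasible set: pin it and retry
            pin = np.where(inactive)[0][ai < 0.0]
            active[pin] = True
            a[pin] = 0.0
            continue
        a = np.zeros_like(a)
        a[inactive] = np.clip(ai, 0.0, None)
        if (np.linalg.norm(C @ a - d)
                <= max(np.linalg.norm(C @ best - d), 1e-12)):
            best = a.copy()
        # KKT: an active variable with negative reduced gradient should be
        # released (its multiplier pushes it off the bound)
        reduced = (C.T @ lam)[active]
        if active.any() and reduced.size and reduced.min() < -1e-10:
            release = np.where(active)[0][np.argmin(reduced)]
            active[release] = False
            a[release] = thresh
            continue
        break
    return best


def equilibrium_certificate(forces: dict,
                            fascicles: list,
                            required_moments: dict,
                            geometry) -> float:
    """Brute-force re-summation of fascicle moments at every cut.

    Independent of the optimizer's constraint values: loops over fascicles
    and joints, recomputes each moment arm, and returns the maximum relative
    equilibrium residual over the cuts.
    """
    worst = 0.0
    for joint, req in required_moments.items():
        total = np.zeros(3)
        for f in fascicles:
            if crosses(f, joint):
                total += forces[f.name] * moment_arm(f, joint, geometry)
        ref = max(np.linalg.norm(np.asarray(req)), 1.0)
        worst = max(worst, float(np.linalg.norm(total - np.asarray(req)) / ref))
    return worst


# ---------------------------------------------------------------------------
# Stage-B driver
# ---------------------------------------------------------------------------

def solve_msk(geometry: SpineGeometry,
              fascicles: list,
              motion: ImposedMotion,
              stiffness: dict,
              recruitment: Optional[RecruitmentConfig] = None,
              bushings=None) -> MuscleForceSolution:
    """Full inverse-static stage: required moments -> recruitment -> hand-off.

    ``bushings`` (the FE joint set) enables the force-dependent translational
    correction of the T10 translation prediction.
    """
    recruitment = recruitment or RecruitmentConfig()
    required = inverse_statics(geometry, motion, stiffness, recruitment)
    forces, objective = recruit_muscles(
        required, fascicles, geometry, exponent=recruitment.exponent,
        tol_rel=recruitment.equilibrium_tol_rel)
    F_r, M_r = np.zeros(3), np.zeros(3)
    if recruitment.gravity and recruitment.upper_body_mass_kg > 0.0:
        # upper-body weight enters the FE model as the T10 reaction load,
        # acting at the posture-displaced centre of mass
        ep = geometry.frame("T10").upper_endplate_center
        com = geometry.frame("T10").center + np.asarray(
            recruitment.upper_body_com_offset_mm, dtype=float)
        com = com + chain_displacement(geometry, motion, com, "T10")
        F_r = np.array([0.0, 0.0,
                        -recruitment.upper_body_mass_kg * _GRAVITY_M_PER_S2])
        M_r = np.cross(com - ep, F_r)
    return MuscleForceSolution(
        motion=motion.motion, fascicle_forces=forces,
        t10_reaction=(F_r, M_r),
        t10_translation=predict_t10_translation(
            geometry, motion, bushings=bushings, fascicle_forces=forces,
            fascicles=fascicles),
        objective_value=objective, required_moments=required,
        passive_moments=passive_moments(geometry, motion, stiffness),
        imposed_rotations=dict(motion.rotations))


# ---------------------------------------------------------------------------
# Hand-off CSV (stage B -> stage C artifact)
# ---------------------------------------------------------------------------

def write_solution_csv(solution: MuscleForceSolution, path) -> None:
    """Write forces plus a one-row T10 reaction/translation record; values at
    9 significant digits so the file round-trips bit-exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fascicle", "force_N"])
        for name in sorted(solution.fascicle_forces):
            writer.writerow([name, f"{solution.fascicle_forces[name]:.9g}"])
        F, M = solution.t10_reaction
        record = np.r_[F, M, solution.t10_translation]
        writer.writerow(["__t10__:" + solution.motion,
                         ";".join(f"{v:.9g}" for v in record)])


def read_solution_csv(path) -> MuscleForceSolution:
    forces: dict = {}
    motion, record = None, None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["fascicle", "force_N"]:
            raise SpineCoupleError(f"unexpected solution CSV header in {path}")
        for name, value in reader:
            if name.startswith("__t10__:"):
                motion = name.split(":", 1)[1]
                record = np.array([float(v) for v in value.split(";")])
            else:
                forces[name] = float(value)
    if record is None:
        raise SpineCoupleError(f"missing T10 record in {path}")
    return MuscleForceSolution(
        motion=motion, fascicle_forces=forces,
        t10_reaction=(record[:3], record[3:6]),
        t10_translation=record[6:9], objective_value=math.nan)
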