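"""Static finite-element solver for the lumped spine model.

Rigid vertebral bodies are 6-DOF nodes; intervertebral discs (with facets and
capsules) are generalized bushing joints; ligaments are tension-only
piecewise-linear springs; instrumentation is a set of Euler-Bernoulli beam
elements with rigid ties.  Kinematics are linearized (small rotations); the
only nonlinearity is the ligament tension state, resolved by Newton iteration.

Units: mm, N, N·mm, MPa; rotations in radians internally, ROMs in degrees.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.linalg

from .anatomy import SpineGeometry
from .config import (INTERVERTEBRAL_JOINTS, JointsConfig, LigamentsConfig,
                     AnatomyConfig, SIJ_JOINTS, SolverConfig)
from .errors import (AssemblyError, MappingError, SolverError,
                     SpineCoupleError)
from .motions import motion_axis


def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


# ---------------------------------------------------------------------------
# Element types
# ---------------------------------------------------------------------------

@dataclass
class BushingJoint:
    """6-DOF spring between two rigid bodies, expressed in the joint frame."""

    joint_label: str
    node_upper: str
    node_lower: str
    center: np.ndarray
    frame: np.ndarray                     # 3x3, columns = joint axes in global
    K_rot: np.ndarray                     # 3x3, N·mm/rad
    K_trans: np.ndarray                   # 3x3, N/mm

    def __post_init__(self) -> None:
        for K, name in ((self.K_rot, "K_rot"), (self.K_trans, "K_trans")):
            K = np.asarray(K, dtype=float)
            if not np.allclose(K, K.T) or np.any(np.linalg.eigvalsh(K) <= 0.0):
                raise SpineCoupleError(
                    f"bushing {self.joint_label}: {name} must be symmetric "
                    "positive definite")


@dataclass
class LigamentSpring:
    """Tension-only spring: zero force at or below slack, then a monotone
    piecewise-linear force-elongation curve (last slope extrapolates)."""

    name: str
    node_a: str
    point_a: np.ndarray
    node_b: str
    point_b: np.ndarray
    curve: np.ndarray                     # (k, 2): elongation mm, force N
    slack_mm: float = 0.0

    def force_tangent(self, elongation: float) -> tuple:
        e = elongation - self.slack_mm
        if e <= 0.0:
            return 0.0, 0.0
        x, f = self.curve[:, 0], self.curve[:, 1]
        if e >= x[-1]:
            k = (f[-1] - f[-2]) / (x[-1] - x[-2])
            return f[-1] + k * (e - x[-1]), k
        i = int(np.searchsorted(x, e, side="right")) - 1
        k = (f[i + 1] - f[i]) / (x[i + 1] - x[i])
        return f[i] + k * (e - x[i]), k


@dataclass
class BeamSegment:
    """2-node 3D Euler-Bernoulli beam with a circular section."""

    node_i: str
    node_j: str
    diameter: float
    elastic_modulus: float
    poisson: float
    component_id: str = "beam"

    def __post_init__(self) -> None:
        if self.diameter <= 0.0:
            raise SpineCoupleError(f"beam {self.component_id}: diameter must be > 0")
        if self.elastic_modulus <= 0.0:
            raise SpineCoupleError(
                f"beam {self.component_id}: elastic modulus must be > 0")
        if not 0.0 <= self.poisson < 0.5:
            raise SpineCoupleError(f"beam {self.component_id}: poisson out of range")

    @property
    def section(self) -> tuple:
        d = self.diameter
        A = math.pi * d * d / 4.0
        I = math.pi * d ** 4 / 64.0
        J = 2.0 * I
        return A, I, J


@dataclass
class LoadCase:
    """Loads of one solve; invariants per loading mode are enforced."""

    mode: str                             # "simplified" | "realistic"
    motion: str
    pure_moment: float = 0.0              # N·mm, at T10 (simplified)
    muscle_loads: list = field(default_factory=list)   # (node, force, point)
    t10_reaction: Optional[tuple] = None  # (force 3-vec, moment 3-vec)
    t10_translation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode == "simplified":
            if self.muscle_loads or self.t10_translation is not None:
                raise SpineCoupleError(
                    "simplified loading admits no muscle loads or prescribed "
                    "translation")
        elif self.mode == "realistic":
            if self.pure_moment != 0.0:
                raise SpineCoupleError("realistic loading has pure_moment = 0")
        else:
            raise SpineCoupleError(f"unknown loading mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class FEModel:
    """Assembled static model: nodes, elements, constraints and loads."""

    def __init__(self, geometry: Optional[SpineGeometry] = None):
        self.geometry = geometry
        self.nodes: dict = {}             # name -> position (3,)
        self.node_body: dict = {}         # name -> owning body label (cuts)
        self.bushings: list = []
        self.ligaments: list = []
        self.beams: list = []
        self.ties: dict = {}              # slave -> (master, offset r)
        self.fixed: set = set()           # node names with all 6 DOF = 0
        self.prescribed: dict = {}        # (node, dof 0..5) -> value
        self.point_loads: list = []       # (node, force(3,), point(3,))
        self.node_moments: list = []      # (node, moment(3,))
        self.loadcase: Optional[LoadCase] = None

    # -- construction -------------------------------------------------------
    def add_node(self, name: str, x, body: Optional[str] = None) -> None:
        self.nodes[name] = np.asarray(x, dtype=float)
        self.node_body[name] = body or name

    def add_tie(self, slave: str, master: str) -> None:
        """Rigidly couple a slave node to a master node."""
        r = self.nodes[slave] - self.nodes[master]
        self.ties[slave] = (master, r)

    def fix(self, node: str) -> None:
        self.fixed.add(node)

    def prescribe_translation(self, node: str, values) -> None:
        for i, v in enumerate(np.asarray(values, dtype=float)):
            self.prescribed[(node, i)] = v

    def clear_loads(self) -> None:
        self.point_loads.clear()
        self.node_moments.clear()
        self.prescribed = {k: v for k, v in self.prescribed.items()
                           if k[0] in self.fixed}
        self.loadcase = None

    def add_force(self, node: str, force, point=None) -> None:
        if node not in self.nodes:
            raise MappingError(f"load references unknown body/node {node!r}")
        point = self.nodes[node] if point is None else np.asarray(point, float)
        self.point_loads.append((node, np.asarray(force, dtype=float), point))

    def add_moment(self, node: str, moment) -> None:
        if node not in self.nodes:
            raise MappingError(f"moment references unknown body/node {node!r}")
        self.node_moments.append((node, np.asarray(moment, dtype=float)))

    # -- DOF bookkeeping ----------------------------------------------------
    @property
    def master_nodes(self) -> list:
        return [n for n in self.nodes if n not in self.ties]

    def ndof(self) -> int:
        """Unconstrained DOF count: 6 per master node."""
        return 6 * len(self.master_nodes)

    def _maps(self):
        full_index = {n: 6 * i for i, n in enumerate(self.nodes)}
        master_index = {n: 6 * i for i, n in enumerate(self.master_nodes)}
        return full_index, master_index

    def _transformation(self):
        """T: master-space displacements -> full nodal displacements."""
        full_index, master_index = self._maps()
        T = np.zeros((6 * len(self.nodes), 6 * len(self.master_nodes)))
        for n, fi in full_index.items():
            if n in self.ties:
                master, r = self.ties[n]
                mi = master_index[master]
                T[fi:fi + 3, mi:mi + 3] = np.eye(3)
                T[fi:fi + 3, mi + 3:mi + 6] = -skew(r)
                T[fi + 3:fi + 6, mi + 3:mi + 6] = np.eye(3)
            else:
                mi = master_index[n]
                T[fi:fi + 6, mi:mi + 6] = np.eye(6)
        return T, full_index, master_index


# -- element matrices -------------------------------------------------------

def _bushing_B(bushing: BushingJoint, x_upper, x_lower) -> np.ndarray:
    """6x12 map from (upper, lower) nodal DOFs to local joint deflections."""
    Rt = bushing.frame.T
    B = np.zeros((6, 12))
    for col, x, sgn in ((0, x_upper, 1.0), (6, x_lower, -1.0)):
        S = skew(bushing.center - x)
        B[0:3, col:col + 3] = sgn * Rt
        B[0:3, col + 3:col + 6] = -sgn * Rt @ S
        B[3:6, col + 3:col + 6] = sgn * Rt
    return B


def beam_stiffness_global(beam: BeamSegment, xi, xj) -> tuple:
    """(K_global 12x12, Lambda 12x12, K_local, L) for a 2-node beam."""
    d = xj - xi
    L = float(np.linalg.norm(d))
    if L <= 0.0:
        raise AssemblyError(f"beam {beam.component_id}: zero length")
    ex = d / L
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ex @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])          # global -> local

    E, nu = beam.elastic_modulus, beam.poisson
    G = E / (2.0 * (1.0 + nu))
    A, I, J = beam.section
    k = np.zeros((12, 12))
    ea, gj = E * A / L, G * J / L
    a, b = 12.0 * E * I / L ** 3, 6.0 * E * I / L ** 2
    c, dd = 4.0 * E * I / L, 2.0 * E * I / L
    k[0, 0] = k[6, 6] = ea
    k[0, 6] = k[6, 0] = -ea
    k[3, 3] = k[9, 9] = gj
    k[3, 9] = k[9, 3] = -gj
    # bending in local x-y plane (displacement y, rotation z)
    for (iy, iz), s in (((1, 5), 1.0), ((2, 4), -1.0)):
        jy, jz = iy + 6, iz + 6
        k[iy, iy] = k[jy, jy] = a
        k[iy, jy] = k[jy, iy] = -a
        k[iz, iz] = k[jz, jz] = c
        k[iz, jz] = k[jz, iz] = dd
        k[iy, iz] = k[iz, iy] = s * b
        k[iy, jz] = k[jz, iy] = s * b
        k[jy, iz] = k[iz, jy] = -s * b
        k[jy, jz] = k[jz, jy] = -s * b
    Lam = scipy.linalg.block_diag(R, R, R, R)
    return Lam.T @ k @ Lam, Lam, k, L


def _ligament_gradient(lig: LigamentSpring, nodes, full_index) -> tuple:
    """(g, unit vector a->b): elongation e = g @ u_full (linearized)."""
    u_ab = lig.point_b - lig.point_a
    L = np.linalg.norm(u_ab)
    u = u_ab / L
    g = np.zeros(6 * len(nodes))
    for node, p, sgn in ((lig.node_a, lig.point_a, -1.0),
                         (lig.node_b, lig.point_b, 1.0)):
        fi = full_index[node]
        r = p - nodes[node]
        g[fi:fi + 3] += sgn * u
        g[fi + 3:fi + 6] += sgn * np.cross(r, u)
    return g, u


# ---------------------------------------------------------------------------
# Result
# ---------------------------------------------------------------------------

@dataclass
class FEResult:
    model: FEModel
    u: dict                               # node -> (6,) master-space solution
    joint_rotations: dict                 # joint -> (3,) relative rotation, rad
    joint_wrenches: dict                  # joint -> (F(3,), M(3,)) bushing, global
    reactions: dict                       # node -> (6,) at prescribed DOFs
    beam_forces: list                     # per element records
    von_mises: dict                       # component_id -> max stress, MPa
    ligament_state: dict                  # name -> (elongation, force)
    residual_norm: float
    external_load_norm: float

    def displacement(self, node: str) -> np.ndarray:
        return self.u[node]


def compute_rom(result: FEResult, motion: str) -> dict:
    """Per-joint relative rotation about the motion axis, in degrees.

    The projection axis is the motion's moment axis carried into the caudal
    body's joint frame; positive ROM follows the motion's sign convention
    (flexion positive under a flexion moment).
    """
    axis = motion_axis(motion)
    return {joint: math.degrees(rot @ axis)
            for joint, rot in result.joint_rotations.items()}


def beam_von_mises(section_forces, diameter: float) -> float:
    """Maximum von Mises stress (MPa) on a circular beam section.

    ``section_forces`` = (N, Vy, Vz, T, My, Mz) in N and N·mm.  Normal stress
    combines axial and worst-fiber bending, shear stress is torsional
    (transverse shear neglected, standard for slender implant beams):
    sigma = |N|/A + ||M_bend|| (d/2)/I,  tau = |T| (d/2)/J,
    vm = sqrt(sigma^2 + 3 tau^2).
    """
    if diameter <= 0.0:
        raise SpineCoupleError("beam_von_mises: diameter must be > 0")
    N, Vy, Vz, T, My, Mz = section_forces
    A = math.pi * diameter ** 2 / 4.0
    S = math.pi * diameter ** 3 / 32.0    # I / c
    sigma = abs(N) / A + math.hypot(My, Mz) / S
    tau = abs(T) / (2.0 * S)              # J/c = 2 I/c
    return math.sqrt(sigma * sigma + 3.0 * tau * tau)


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def solve_static(model: FEModel,
                 solver: Optional[SolverConfig] = None) -> FEResult:
    """Newton iteration over the ligament tension state.

    Converges when the free-DOF residual norm drops below
    ``tol_abs + tol_rel * ||external load||``; raises :class:`SolverError`
    on non-convergence, with early abort after three consecutive residual
    increases.
    """
    solver = solver or SolverConfig()
    T, full_index, master_index = model._transformation()
    nfull, nmast = T.shape

    K_full = np.zeros((nfull, nfull))
    for b in model.bushings:
        xu, xl = model.nodes[b.node_upper], model.nodes[b.node_lower]
        B = _bushing_B(b, xu, xl)
        K = B.T @ scipy.linalg.block_diag(np.asarray(b.K_trans, float),
                                          np.asarray(b.K_rot, float)) @ B
        idx = np.r_[np.arange(6) + full_index[b.node_upper],
                    np.arange(6) + full_index[b.node_lower]]
        K_full[np.ix_(idx, idx)] += K
    beam_cache = []
    for beam in model.beams:
        xi, xj = model.nodes[beam.node_i], model.nodes[beam.node_j]
        Kg, Lam, Kl, L = beam_stiffness_global(beam, xi, xj)
        idx = np.r_[np.arange(6) + full_index[beam.node_i],
                    np.arange(6) + full_index[beam.node_j]]
        K_full[np.ix_(idx, idx)] += Kg
        beam_cache.append((beam, idx, Lam, Kl))

    lig_cache = []
    for lig in model.ligaments:
        g, u = _ligament_gradient(lig, model.nodes, full_index)
        lig_cache.append((lig, T.T @ g))

    K = T.T @ K_full @ T

    # external load vector in master space
    F_full = np.zeros(nfull)
    for node, force, point in model.point_loads:
        fi = full_index[node]
        F_full[fi:fi + 3] += force
        F_full[fi + 3:fi + 6] += np.cross(point - model.nodes[node], force)
    for node, moment in model.node_moments:
        F_full[full_index[node] + 3:full_index[node] + 6] += moment
    F = T.T @ F_full

    # constraint partition
    presc = dict(model.prescribed)
    for node in model.fixed:
        for i in range(6):
            presc.setdefault((node, i), 0.0)
    p_idx, p_val = [], []
    for (node, i), v in presc.items():
        if node in model.ties:
            raise AssemblyError(f"cannot constrain slave node {node!r}")
        p_idx.append(master_index[node] + i)
        p_val.append(v)
    p_idx = np.asarray(p_idx, dtype=int)
    free = np.setdiff1d(np.arange(nmast), p_idx)
    if free.size == 0:
        raise AssemblyError("model has no free DOFs")

    u = np.zeros(nmast)
    u[p_idx] = p_val
    load_norm = float(np.linalg.norm(F))
    tol = solver.tol_abs_n + solver.tol_rel * max(load_norm, 1.0)

    def residual_and_tangent(u):
        r = K @ u - F
        Jt = K.copy()
        state = {}
        for lig, g in lig_cache:
            e = float(g @ u)
            f_t, k_t = lig.force_tangent(e)
            r += f_t * g
            if k_t:
                Jt += k_t * np.outer(g, g)
            state[lig.name] = (e, f_t)
        return r, Jt, state

    prev_norm, growth = math.inf, 0
    for iteration in range(solver.max_iterations):
        r, Jt, lig_state = residual_and_tangent(u)
        norm = float(np.linalg.norm(r[free]))
        if iteration == 0:
            # factor once even when already converged: detects free mechanisms
            try:
                scipy.linalg.cho_factor(Jt[np.ix_(free, free)])
            except np.linalg.LinAlgError as exc:
                raise AssemblyError(
                    f"singular constrained stiffness (free mechanism): {exc}"
                ) from exc
        if norm <= tol:
            break
        if norm > prev_norm * (1.0 + 1e-12):
            growth += 1
            if growth >= 3:
                raise SolverError(
                    f"divergence: residual grew 3 consecutive iterations "
                    f"(last {norm:.3e} N)")
        else:
            growth = 0
        prev_norm = norm
        Jff = Jt[np.ix_(free, free)]
        try:
            cf = scipy.linalg.cho_factor(Jff)
        except np.linalg.LinAlgError as exc:
            raise AssemblyError(
                f"singular constrained stiffness (free mechanism): {exc}"
            ) from exc
        u[free] -= scipy.linalg.cho_solve(cf, r[free])
    else:
        raise SolverError(
            f"no convergence in {solver.max_iterations} iterations "
            f"(last residual {prev_norm:.3e} N)")

    r, _, lig_state = residual_and_tangent(u)
    reactions: dict = {}
    for (node, i), _v in presc.items():
        reactions.setdefault(node, np.zeros(6))[i] = r[master_index[node] + i]

    u_full = T @ u
    u_by_node = {n: u[mi:mi + 6] for n, mi in master_index.items()}
    for slave, (master, _r) in model.ties.items():
        fi = full_index[slave]
        u_by_node[slave] = u_full[fi:fi + 6]

    joint_rotations, joint_wrenches = {}, {}
    for b in model.bushings:
        qu, ql = u_by_node[b.node_upper], u_by_node[b.node_lower]
        B = _bushing_B(b, model.nodes[b.node_upper], model.nodes[b.node_lower])
        d = B @ np.r_[qu, ql]
        F_loc = np.asarray(b.K_trans, float) @ d[:3]
        M_loc = np.asarray(b.K_rot, float) @ d[3:]
        joint_rotations[b.joint_label] = qu[3:] - ql[3:]
        joint_wrenches[b.joint_label] = (b.frame @ F_loc, b.frame @ M_loc)

    beam_forces = []
    for beam, idx, Lam, Kl in beam_cache:
        f_loc = Kl @ (Lam @ u_full[idx])
        ends = (-f_loc[:6], f_loc[6:])    # internal section forces at ends
        vm = max(beam_von_mises(e, beam.diameter) for e in ends)
        beam_forces.append({"component": beam.component_id,
                            "node_i": beam.node_i, "node_j": beam.node_j,
                            "end_forces": ends, "diameter": beam.diameter,
                            "von_mises": vm})
    von_mises: dict = {}
    for rec in beam_forces:
        cid = rec["component"]
        von_mises[cid] = max(von_mises.get(cid, 0.0), rec["von_mises"])

    return FEResult(
        model=model, u=u_by_node, joint_rotations=joint_rotations,
        joint_wrenches=joint_wrenches, reactions=reactions,
        beam_forces=beam_forces, von_mises=von_mises,
        ligament_state=lig_state,
        residual_norm=float(np.linalg.norm(r[free])),
        external_load_norm=load_norm)


def write_result_csv(result: FEResult, motion: str, path) -> None:
    """FEResult export: one row per joint (label, ROM_deg), then one row per
    implant component (component_id, max_von_mises_MPa, governing section
    forces N, Vy, Vz, T, My, Mz).  Fixed column order."""
    import csv

    rom = compute_rom(result, motion)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_type", "id", "rom_deg", "max_von_mises_MPa",
                         "N", "Vy", "Vz", "T", "My", "Mz"])
        for joint, value in rom.items():
            writer.writerow(["joint", joint, f"{value:.9g}", "", "", "", "",
                             "", "", ""])
        by_comp: dict = {}
        for rec in result.beam_forces:
            best = by_comp.get(rec["component"])
            if best is None or rec["von_mises"] > best["von_mises"]:
                by_comp[rec["component"]] = rec
        for comp, rec in by_comp.items():
            forces = max(rec["end_forces"],
                         key=lambda e: beam_von_mises(e, rec["diameter"]))
            writer.writerow(["component", comp, "",
                             f"{rec['von_mises']:.9g}",
                             *(f"{v:.9g}" for v in forces)])


# ---------------------------------------------------------------------------
# Internal cut wrench
# ---------------------------------------------------------------------------

def internal_cut_wrench(result: FEResult, joint: str, about=None) -> tuple:
    """(force, moment) transmitted across an intervertebral joint, from
    element internal forces (bushing + ligaments + crossing beams): the action
    of the cranial part on the caudal part, moment about the joint center
    unless ``about`` is given.

    Independent of the external load bookkeeping, so equal (to solver
    tolerance) to the moment balance of all loads cranial of the cut.
    """
    model = result.model
    if model.geometry is None:
        raise SpineCoupleError("cut wrench needs a spine geometry")
    cranial = set(model.geometry.bodies_cranial_of(joint))
    c = model.geometry.joint_centers[joint] if about is None else np.asarray(about)

    def is_cranial(node):
        return model.node_body[node] in cranial

    F_tot, M_tot = np.zeros(3), np.zeros(3)
    for b in model.bushings:
        if is_cranial(b.node_upper) != is_cranial(b.node_lower):
            Fb, Mb = result.joint_wrenches[b.joint_label]
            sgn = 1.0 if is_cranial(b.node_upper) else -1.0
            F_tot += sgn * Fb
            M_tot += sgn * (Mb + np.cross(b.center - c, Fb))
    for lig in model.ligaments:
        ca, cb = is_cranial(lig.node_a), is_cranial(lig.node_b)
        if ca == cb:
            continue
        _e, f = result.ligament_state[lig.name]
        if f == 0.0:
            continue
        p_cr, p_cd = (lig.point_a, lig.point_b) if ca else (lig.point_b, lig.point_a)
        u = (p_cr - p_cd) / np.linalg.norm(p_cr - p_cd)
        Fl = f * u
        F_tot += Fl
        M_tot += np.cross(p_cd - c, Fl)
    for rec in result.beam_forces:
        ci, cj = is_cranial(rec["node_i"]), is_cranial(rec["node_j"])
        if ci == cj:
            continue
        # wrench the element applies to its caudal node
        caudal_node = rec["node_j"] if ci else rec["node_i"]
        # recompute global nodal forces from the solved state
        beam = next(b for b in model.beams
                    if b.node_i == rec["node_i"] and b.node_j == rec["node_j"]
                    and b.component_id == rec["component"])
        xi, xj = model.nodes[beam.node_i], model.nodes[beam.node_j]
        Kg, _Lam, _Kl, _L = beam_stiffness_global(beam, xi, xj)
        u_e = np.r_[result.u[beam.node_i], result.u[beam.node_j]]
        p = Kg @ u_e
        sl = slice(6, 12) if caudal_node == beam.node_j else slice(0, 6)
        w = -p[sl]
        F_tot += w[:3]
        M_tot += w[3:] + np.cross(model.nodes[caudal_node] - c, w[:3])
    return F_tot, M_tot


# ---------------------------------------------------------------------------
# Spine model assembly and load application
# ---------------------------------------------------------------------------

def make_bushings(geometry: SpineGeometry, config: JointsConfig) -> list:
    """Bushing set from the joints section of the pipeline config."""
    config.validate()
    thoracic = {"T10/T11", "T11/T12", "T12/L1"}
    bushings = []
    for joint in geometry.joints:
        if joint in SIJ_JOINTS:
            k_rot, k_trans = config.sij_k_rot, config.sij_k_trans
        else:
            scale = config.thoracic_rot_scale if joint in thoracic else 1.0
            k_rot = tuple(scale * k for k in config.intervertebral_k_rot)
            k_trans = config.intervertebral_k_trans
        if joint in config.k_rot_overrides:
            k_rot = tuple(config.k_rot_overrides[joint])
        upper, lower = geometry.joint_bodies(joint)
        bushings.append(BushingJoint(
            joint_label=joint, node_upper=upper, node_lower=lower,
            center=geometry.joint_centers[joint],
            frame=geometry.joint_frames[joint],
            K_rot=np.diag(k_rot), K_trans=np.diag(k_trans)))
    return bushings


def make_ligaments(geometry: SpineGeometry, config: LigamentsConfig,
                   anatomy: Optional[AnatomyConfig] = None) -> list:
    """Interspinous, anterior longitudinal and intertransverse springs at
    every intervertebral level."""
    if not config.enabled:
        return []
    config.validate()
    anatomy = anatomy or AnatomyConfig()
    sp, tp, bd = (anatomy.spinous_offset_mm, anatomy.transverse_offset_mm,
                  anatomy.body_halfdepth_mm)
    ligaments = []
    for joint in INTERVERTEBRAL_JOINTS:
        upper_lbl, lower_lbl = geometry.joint_bodies(joint)
        upper, lower = geometry.frame(upper_lbl), geometry.frame(lower_lbl)
        tag = joint.replace("/", "_")
        pairs = [
            ("interspinous", (-sp, 0.0, -upper.height / 2.0),
             (-sp, 0.0, lower.height / 2.0)),
            ("anterior_longitudinal", (bd, 0.0, -upper.height / 2.0),
             (bd, 0.0, lower.height / 2.0)),
        ]
        for side, s in (("left", 1.0), ("right", -1.0)):
            pairs.append((f"intertransverse:{side}",
                          (-tp + 15.0, s * tp, -upper.height / 2.0),
                          (-tp + 15.0, s * tp, lower.height / 2.0)))
        for name, up_loc, lo_loc in pairs:
            kind = name.split(":")[0]
            ligaments.append(LigamentSpring(
                name=f"{kind}_{tag}" + (f"_{name.split(':')[1]}" if ":" in name else ""),
                node_a=upper_lbl, point_a=upper.point(up_loc),
                node_b=lower_lbl, point_b=lower.point(lo_loc),
                curve=np.asarray(config.curves[kind], dtype=float),
                slack_mm=config.slack_mm))
    return ligaments


def assemble(geometry: SpineGeometry,
             joints: Iterable[BushingJoint],
             ligaments: Iterable[LigamentSpring] = (),
             instrumentation=None,
             loadcase: Optional[LoadCase] = None) -> FEModel:
    """Compose the FE model: one 6-DOF node per body, bushings and ligaments,
    an optional fixation construct, pelvis (acetabula) fully fixed."""
    model = FEModel(geometry)
    for v in geometry.vertebrae:
        model.add_node(v.label, v.center)
    model.add_node("Pelvis", geometry.pelvis.center)
    model.fix("Pelvis")
    model.bushings = list(joints)
    model.ligaments = list(ligaments)
    for b in model.bushings:
        for n in (b.node_upper, b.node_lower):
            if n not in model.nodes:
                raise MappingError(f"bushing {b.joint_label}: unknown body {n!r}")
    if instrumentation is not None:
        from .fixation import add_construct_to_model
        add_construct_to_model(model, instrumentation)
    if loadcase is not None:
        _apply_loadcase(model, loadcase, geometry)
    return model


def apply_pure_moment(model: FEModel, motion: str, magnitude: float) -> LoadCase:
    """Simplified loading: a pure moment at the T10 upper endplate, carried to
    the T10 body node by the rigid endplate interface (exactly equivalent for
    a couple)."""
    if magnitude <= 0.0:
        raise SpineCoupleError("pure moment magnitude must be > 0")
    axis = motion_axis(motion)
    model.clear_loads()
    model.add_moment("T10", magnitude * axis)
    lc = LoadCase(mode="simplified", motion=motion, pure_moment=magnitude)
    model.loadcase = lc
    return lc


def apply_muscle_loads(model: FEModel, solution, fascicles,
                       prescribe_translation: bool = True) -> LoadCase:
    """Realistic loading: per-fascicle equal-and-opposite concentrated forces
    at the attachments, MSK reaction loads at the T10 upper endplate, and the
    MSK-predicted T10 translation as a hard constraint.  Removes any pure
    moment."""
    model.clear_loads()
    by_name = {f.name: f for f in fascicles}
    muscle_loads = []
    for name, force in solution.fascicle_forces.items():
        f = by_name[name]
        if force < 0.0:
            raise SpineCoupleError(f"fascicle {name}: negative force")
        if force == 0.0:
            continue
        for node, point, load in f.point_loads(force):
            model.add_force(node, load, point)
            muscle_loads.append((node, load, point))
    t10_ep = model.geometry.frame("T10").upper_endplate_center
    F_r, M_r = solution.t10_reaction
    if np.any(F_r) or np.any(M_r):
        model.add_force("T10", F_r, t10_ep)
        model.add_moment("T10", M_r)
    if prescribe_translation:
        model.prescribe_translation("T10", solution.t10_translation)
    lc = LoadCase(mode="realistic", motion=solution.motion,
                  muscle_loads=muscle_loads,
                  t10_reaction=(np.asarray(F_r, float), np.asarray(M_r, float)),
                  t10_translation=(np.asarray(solution.t10_translation, float)
                                   if prescribe_translation else None))
    model.loadcase = lc
    return lc


def _apply_loadcase(model: FEModel, loadcase: LoadCase,
                    geometry: SpineGeometry) -> None:
    if loadcase.mode == "simplified":
        apply_pure_moment(model, loadcase.motion, loadcase.pure_moment)
    else:
        model.clear_loads()
        for node, force, point in loadcase.muscle_loads:
            model.add_force(node, force, point)
        if loadcase.t10_reaction is not None:
            F_r, M_r = loadcase.t10_reaction
            model.add_force("T10", F_r, geometry.frame("T10").upper_endplate_center)
            model.add_moment("T10", M_r)
        if loadcase.t10_translation is not None:
            model.prescribe_translation("T10", loadcase.t10_translation)
        model.loadcase = loadcase
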