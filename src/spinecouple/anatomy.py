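"""Parametric synthetic thoracolumbar anatomy (T10-pelvis) and muscle set.

The generator emulates the role of a body-model-derived spine geometry and a
thoracolumbar muscle architecture with nine bilateral groups: transversus,
spinalis, semispinalis, erector spinae, obliquus internus, obliquus externus,
psoas major, multifidi, and quadratus lumborum.  Vertebrae are rigid frames;
fascicles are straight-line force actuators between attachment points.

Global frame: X anterior, Y left, Z cranial; positions in mm, forces in N.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import (ALL_JOINTS, AnatomyConfig, INTERVERTEBRAL_JOINTS,
                     MuscleConfig, SIJ_JOINTS, VERTEBRA_LABELS)
from .errors import ConfigurationError, CoverageError
from .motions import motion_axis

BODY_CHAIN = VERTEBRA_LABELS + ("Sacrum", "Pelvis")

#: caudal partner label used in joint names ("L5/S1" joins L5 to the sacrum)
_JOINT_LOWER_ALIAS = {"S1": "Sacrum"}


def rot_y(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the global Y (lateral) axis."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class VertebraFrame:
    """Rigid vertebral body frame with the landmarks the pipeline needs."""

    label: str
    center: np.ndarray
    orientation: np.ndarray              # 3x3, columns = body axes in global
    height: float
    upper_endplate_center: np.ndarray = field(init=False)
    lower_endplate_center: np.ndarray = field(init=False)
    pedicle_entry_left: np.ndarray = field(init=False)
    pedicle_entry_right: np.ndarray = field(init=False)
    _pedicle_local: tuple = (30.0, 18.0)

    def __post_init__(self) -> None:
        half = np.array([0.0, 0.0, self.height / 2.0])
        self.upper_endplate_center = self.point(half)
        self.lower_endplate_center = self.point(-half)
        post, lat = self._pedicle_local
        self.pedicle_entry_left = self.point([-post, lat, 0.0])
        self.pedicle_entry_right = self.point([-post, -lat, 0.0])

    def point(self, local) -> np.ndarray:
        """Global position of a body-fixed point given in local coordinates."""
        return self.center + self.orientation @ np.asarray(local, dtype=float)


@dataclass
class PelvisFrame:
    label: str
    center: np.ndarray
    orientation: np.ndarray
    landmarks: dict

    def point(self, local) -> np.ndarray:
        return self.center + self.orientation @ np.asarray(local, dtype=float)


@dataclass
class SpineGeometry:
    """Ordered rigid-body frames, joint centers and joint frames."""

    vertebrae: list                       # T10..L5, Sacrum
    pelvis: PelvisFrame
    joints: tuple                         # labels, intervertebral then SIJ
    joint_centers: dict                   # label -> 3-vector
    joint_frames: dict                    # label -> 3x3 (caudal body frame)
    sagittal_symmetry: bool = True

    def __post_init__(self) -> None:
        self._by_label = {v.label: v for v in self.vertebrae}
        self._by_label["Pelvis"] = self.pelvis

    # -- topology helpers ---------------------------------------------------
    def frame(self, label: str):
        return self._by_label[label]

    @property
    def body_labels(self) -> tuple:
        return BODY_CHAIN

    @staticmethod
    def joint_bodies(joint: str) -> tuple:
        """(cranial, caudal) body labels adjacent to a joint."""
        if joint in SIJ_JOINTS:
            return ("Sacrum", "Pelvis")
        upper, lower = joint.split("/")
        return upper, _JOINT_LOWER_ALIAS.get(lower, lower)

    def bodies_cranial_of(self, joint: str) -> tuple:
        """Body labels on the cranial side of a cut through ``joint``."""
        upper, _ = self.joint_bodies(joint)
        idx = BODY_CHAIN.index(upper)
        return BODY_CHAIN[:idx + 1]

    def spanned_joints(self, body_a: str, body_b: str) -> tuple:
        """Contiguous joints crossed by a line from body_a to body_b."""
        ia, ib = BODY_CHAIN.index(body_a), BODY_CHAIN.index(body_b)
        lo, hi = min(ia, ib), max(ia, ib)
        spanned = []
        for k in range(lo, hi):
            upper = BODY_CHAIN[k]
            if upper == "Sacrum":
                spanned.extend(SIJ_JOINTS)
            else:
                lower = BODY_CHAIN[k + 1]
                suffix = "S1" if lower == "Sacrum" else lower
                spanned.append(f"{upper}/{suffix}")
        return tuple(spanned)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        for v in self.vertebrae:
            R = v.orientation
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
                raise ConfigurationError(f"{v.label}: orientation not orthonormal")
            if not math.isclose(np.linalg.det(R), 1.0, abs_tol=1e-10):
                raise ConfigurationError(f"{v.label}: orientation determinant != +1")
        zs = [v.center[2] for v in self.vertebrae]
        if not all(a > b for a, b in zip(zs, zs[1:])):
            raise ConfigurationError(
                "vertebral centers not strictly decreasing from T10 to sacrum")
        for joint in self.joints:
            upper, lower = self.joint_bodies(joint)
            zu = self.frame(upper).center[2]
            zl = self.frame(lower).center[2]
            zj = self.joint_centers[joint][2]
            if not zl < zj < zu:
                raise ConfigurationError(
                    f"joint {joint} center not between its adjacent bodies")
        if self.sagittal_symmetry:
            for v in self.vertebrae:
                mirrored = v.pedicle_entry_right * np.array([1.0, -1.0, 1.0])
                if not np.allclose(v.pedicle_entry_left, mirrored, atol=1e-9):
                    raise ConfigurationError(
                        f"{v.label}: pedicle entries not sagittally symmetric")


def build_default_spine(config: AnatomyConfig) -> SpineGeometry:
    """Stack the synthetic spine from the sacrum upward.

    Per-joint sagittal wedge angles impose the standing lordosis/kyphosis; the
    sacral base tilt orients the sacrum.  Deterministic for a given config.
    """
    config.validate()
    pelvis = PelvisFrame(
        label="Pelvis", center=np.zeros(3), orientation=np.eye(3),
        landmarks=_pelvis_landmarks())

    tilt = config.base_tilt_deg
    R = rot_y(tilt)
    sacrum = VertebraFrame(
        label="Sacrum",
        center=np.array([0.0, 0.0, config.sacrum_center_z_mm]),
        orientation=R, height=config.sacrum_height_mm,
        _pedicle_local=(config.pedicle_posterior_mm, config.pedicle_lateral_mm))

    vertebrae = [sacrum]
    prev = sacrum
    prev_tilt = tilt
    for label in reversed(VERTEBRA_LABELS):          # L5 ... T10
        joint = _joint_label(label, prev.label)
        tilt = prev_tilt - config.wedge_deg[joint]   # lordotic wedge extends
        R_mid = rot_y(0.5 * (prev_tilt + tilt))
        R = rot_y(tilt)
        half_disc = np.array([0.0, 0.0, config.disc_height_mm / 2.0])
        half_body = np.array([0.0, 0.0, config.body_height_mm / 2.0])
        joint_center = prev.upper_endplate_center + R_mid @ half_disc
        center = joint_center + R @ (half_disc + half_body)
        vert = VertebraFrame(
            label=label, center=center, orientation=R,
            height=config.body_height_mm,
            _pedicle_local=(config.pedicle_posterior_mm, config.pedicle_lateral_mm))
        vertebrae.append(vert)
        prev, prev_tilt = vert, tilt

    vertebrae.reverse()                              # T10 first, Sacrum last

    joint_centers, joint_frames = {}, {}
    for joint in INTERVERTEBRAL_JOINTS:
        upper_lbl, lower_lbl = SpineGeometry.joint_bodies(joint)
        upper = next(v for v in vertebrae if v.label == upper_lbl)
        lower = next(v for v in vertebrae if v.label == lower_lbl)
        joint_centers[joint] = 0.5 * (upper.lower_endplate_center
                                      + lower.upper_endplate_center)
        joint_frames[joint] = lower.orientation      # caudal body frame
    for joint, sign in (("SIJ-left", 1.0), ("SIJ-right", -1.0)):
        joint_centers[joint] = sacrum.point(
            [-config.sij_posterior_mm, sign * config.sij_lateral_mm, -10.0])
        joint_frames[joint] = np.eye(3)              # caudal body = pelvis
    # pseudo-cut through both sacroiliac joints (sacrum+spine vs pelvis),
    # used by the inverse-static stage; not a joint of the FE model
    joint_centers["SIJ-pair"] = 0.5 * (joint_centers["SIJ-left"]
                                       + joint_centers["SIJ-right"])

    geometry = SpineGeometry(
        vertebrae=vertebrae, pelvis=pelvis, joints=ALL_JOINTS,
        joint_centers=joint_centers, joint_frames=joint_frames,
        sagittal_symmetry=config.sagittal_symmetry)
    geometry.validate()
    return geometry


def _joint_label(upper: str, lower: str) -> str:
    suffix = "S1" if lower == "Sacrum" else lower
    return f"{upper}/{suffix}"


def _pelvis_landmarks() -> dict:
    lm = {}
    for side, s in (("left", 1.0), ("right", -1.0)):
        lm[f"iliac_crest_posterior_{side}"] = np.array([-60.0, s * 45.0, 30.0])
        lm[f"ilium_anterior_{side}"] = np.array([40.0, s * 60.0, 20.0])
        lm[f"iliac_crest_lateral_{side}"] = np.array([-30.0, s * 55.0, 30.0])
        lm[f"lesser_trochanter_{side}"] = np.array([20.0, s * 45.0, -60.0])
        lm[f"pubis_{side}"] = np.array([45.0, s * 15.0, -40.0])
        lm[f"acetabulum_{side}"] = np.array([10.0, s * 80.0, -30.0])
    return lm


# ---------------------------------------------------------------------------
# Muscle fascicles
# ---------------------------------------------------------------------------

@dataclass
class MuscleFascicle:
    """Straight-line force actuator between two body-fixed attachments."""

    name: str
    side: str                             # "left" | "right"
    group: str
    origin: np.ndarray                    # caudal attachment (pelvis/vertebra)
    insertion: np.ndarray                 # cranial attachment
    origin_body: str
    insertion_body: str
    f_max: float
    spanned_joints: tuple
    via_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        if self.f_max <= 0.0:
            raise ConfigurationError(f"fascicle {self.name}: f_max must be > 0")
        if np.allclose(self.origin, self.insertion):
            raise ConfigurationError(f"fascicle {self.name}: origin == insertion")

    def path(self) -> list:
        """Attachment path from the cranial end: insertion, via points (which
        ride on the caudal attachment's body, a frictionless redirection),
        then origin.  The caudal attachment is the origin by convention."""
        io = BODY_CHAIN.index(self.origin_body)
        ii = BODY_CHAIN.index(self.insertion_body)
        if io < ii:                        # origin is the cranial attachment
            return [self.origin, *reversed(self.via_points), self.insertion]
        return [self.insertion, *self.via_points, self.origin]

    def cranial_attachment(self, joint: str, geometry: SpineGeometry):
        """(point, unit pull direction) of the path segment crossing a cut:
        the cranial attachment and the direction toward the next path point
        (via points sit on the caudal-most body, so the first segment is the
        one crossing every spanned joint)."""
        pts = self.path()
        p, q = pts[0], pts[1]
        u = np.asarray(q, float) - np.asarray(p, float)
        return np.asarray(p, float), u / np.linalg.norm(u)

    def point_loads(self, force: float) -> list:
        """(body, point, force vector) triples of a tensioned fascicle:
        equal-and-opposite segment tensions at the attachments, redirection
        forces at via points; the set sums to zero force and moment."""
        pts = [np.asarray(p, float) for p in self.path()]
        io = BODY_CHAIN.index(self.origin_body)
        ii = BODY_CHAIN.index(self.insertion_body)
        cranial = self.origin_body if io < ii else self.insertion_body
        caudal = self.insertion_body if io < ii else self.origin_body
        bodies = [cranial] + [caudal] * (len(pts) - 1)

        def unit(a, b):
            d = b - a
            return d / np.linalg.norm(d)

        loads = []
        for i, (body, p) in enumerate(zip(bodies, pts)):
            f = np.zeros(3)
            if i > 0:
                f += force * unit(p, pts[i - 1])
            if i < len(pts) - 1:
                f += force * unit(p, pts[i + 1])
            loads.append((body, p, f))
        return loads


def moment_arm(fascicle: MuscleFascicle, joint: str,
               geometry: SpineGeometry) -> np.ndarray:
    """Moment (vector, mm) about the joint center of a unit fascicle tension.

    Convention: the moment the fascicle exerts on the cranial side of a cut
    through ``joint``; tension pulls the cranial attachment toward the caudal
    one.
    """
    p, u = fascicle.cranial_attachment(joint, geometry)
    c = geometry.joint_centers[joint]
    return np.cross(p - c, u)


_ARCHITECTURE_DOC = """Per-side fascicle architecture (group, caudal body/point,
cranial body/point, slips).  Local vertebral offsets are (anterior, lateral,
axial) mm; pelvis attachments are named landmarks."""


def _architecture(config: AnatomyConfig):
    """Yield (group, origin_body, origin_local_or_landmark, insertion_body,
    insertion_local[, via_points]) tuples for one (left) side; the right side
    mirrors.  Via points (pelvis-fixed, raw coordinates) route the abdominal
    muscles over the belly wall so their flexion lever arms are
    physiological rather than chords through the vertebral bodies."""
    sp, la, tp = (config.spinous_offset_mm, config.lamina_offset_mm,
                  config.transverse_offset_mm)
    arch = []
    for upper in ("T10", "T11", "T12", "L1", "L2"):
        arch.append(("erector_spinae", "Pelvis", "iliac_crest_posterior_left",
                     upper, (-la, 15.0, 0.0)))
    multifidus_pairs = [("T10", "T12"), ("T11", "L1"), ("T12", "L2"),
                        ("L1", "L3"), ("L2", "L4"), ("L3", "L5"),
                        ("L4", "Sacrum"), ("L5", "Sacrum")]
    for upper, lower in multifidus_pairs:
        arch.append(("multifidi", lower, (-la, 12.0, 0.0),
                     upper, (-sp + 5.0, 8.0, 0.0)))
    arch.append(("spinalis", "L3", (-sp + 3.0, 5.0, 0.0), "T10", (-sp + 3.0, 5.0, 0.0)))
    arch.append(("spinalis", "L2", (-sp + 3.0, 5.0, 0.0), "T11", (-sp + 3.0, 5.0, 0.0)))
    arch.append(("semispinalis", "L1", (-tp + 10.0, tp, 0.0), "T10", (-sp, 6.0, 0.0)))
    arch.append(("semispinalis", "L2", (-tp + 10.0, tp, 0.0), "T11", (-sp, 6.0, 0.0)))
    arch.append(("transversus", "Pelvis", "iliac_crest_lateral_left",
                 "T11", (10.0, 50.0, 0.0), [(70.0, 60.0, 90.0)]))
    arch.append(("transversus", "Pelvis", "iliac_crest_lateral_left",
                 "T12", (10.0, 50.0, 0.0), [(70.0, 60.0, 90.0)]))
    arch.append(("obliquus_internus", "Pelvis", "ilium_anterior_left",
                 "T11", (20.0, 35.0, 0.0), [(85.0, 45.0, 100.0)]))
    arch.append(("obliquus_internus", "Pelvis", "ilium_anterior_left",
                 "T12", (20.0, 35.0, 0.0), [(85.0, 45.0, 100.0)]))
    arch.append(("obliquus_externus", "Pelvis", "pubis_left",
                 "T10", (15.0, 45.0, 0.0), [(80.0, 45.0, 60.0)]))
    arch.append(("obliquus_externus", "Pelvis", "ilium_anterior_left",
                 "T10", (15.0, 45.0, 0.0), [(80.0, 50.0, 80.0)]))
    for lumbar in ("L1", "L2", "L3", "L4", "L5"):
        arch.append(("psoas_major", "Pelvis", "lesser_trochanter_left",
                     lumbar, (15.0, 22.0, 0.0)))
    for upper in ("T12", "L1", "L2", "L3", "L4"):
        arch.append(("quadratus_lumborum", "Pelvis", "iliac_crest_lateral_left",
                     upper, (-tp + 15.0, tp, 0.0)))
    return arch


def build_muscle_set(geometry: SpineGeometry,
                     config: MuscleConfig,
                     anatomy: Optional[AnatomyConfig] = None) -> list:
    """Build the bilateral nine-group fascicle set on a geometry.

    Every intervertebral joint ends up spanned by fascicles with opposing
    moment arms about the flexion-extension and lateral-bending axes;
    otherwise a :class:`CoverageError` is raised naming joint and axis.
    """
    config.validate()
    anatomy = anatomy or AnatomyConfig()
    fascicles = []
    counters: dict = {}
    for side, s in (("left", 1.0), ("right", -1.0)):
        for entry in _architecture(anatomy):
            group, o_body, o_loc, i_body, i_loc = entry[:5]
            vias = [np.asarray(v, float) * np.array([1.0, s, 1.0])
                    for v in (entry[5] if len(entry) > 5 else [])]
            origin = _attachment(geometry, o_body, o_loc, s, side)
            insertion = _attachment(geometry, i_body, i_loc, s, side)
            idx = counters.setdefault((group, side), 0) + 1
            counters[(group, side)] = idx
            f_max = config.pcsa_cm2[group] * config.specific_tension_n_per_cm2
            fascicles.append(MuscleFascicle(
                name=f"{group}_{side}_{idx}", side=side, group=group,
                origin=origin, insertion=insertion,
                origin_body=o_body, insertion_body=i_body, f_max=f_max,
                spanned_joints=geometry.spanned_joints(o_body, i_body),
                via_points=vias))
    _check_coverage(fascicles, geometry)
    return fascicles


def _attachment(geometry, body, local_or_landmark, sign, side):
    if body == "Pelvis":
        name = local_or_landmark.replace("_left", f"_{side}")
        return geometry.pelvis.center + geometry.pelvis.landmarks[name]
    local = np.asarray(local_or_landmark, dtype=float)
    local = local * np.array([1.0, sign, 1.0])
    return geometry.frame(body).point(local)


def _check_coverage(fascicles, geometry, min_arm_mm: float = 1.0) -> None:
    axes = {"flexion-extension": motion_axis("flexion"),
            "lateral-bending": motion_axis("lateral_right")}
    for joint in INTERVERTEBRAL_JOINTS:
        for axis_name, axis in axes.items():
            arms = [moment_arm(f, joint, geometry) @ axis
                    for f in fascicles if joint in f.spanned_joints]
            if not (any(a > min_arm_mm for a in arms)
                    and any(a < -min_arm_mm for a in arms)):
                raise CoverageError(
                    f"joint {joint} lacks an opposing fascicle pair about the "
                    f"{axis_name} axis")


# ---------------------------------------------------------------------------
# Fascicle table CSV
# ---------------------------------------------------------------------------

_CSV_HEADER = ["name", "side", "group", "origin_x", "origin_y", "origin_z",
               "insertion_x", "insertion_y", "insertion_z", "via_points",
               "f_max_N", "spanned_joints"]


def write_muscle_csv(fascicles: Iterable[MuscleFascicle], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for f in fascicles:
            via = ";".join(",".join(f"{c:.9g}" for c in p) for p in f.via_points)
            writer.writerow(
                [f.name, f.side, f.group,
                 *(f"{c:.9g}" for c in f.origin),
                 *(f"{c:.9g}" for c in f.insertion),
                 via, f"{f.f_max:.9g}", ";".join(f.spanned_joints)])


def read_muscle_csv(path, geometry: SpineGeometry) -> list:
    """Load a fascicle table; attachment bodies are recovered from the
    spanned-joint list (cranial body above the first spanned joint, caudal
    below the last) and invariants re-validated."""
    fascicles = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_HEADER:
            raise ConfigurationError(f"unexpected muscle CSV header in {path}")
        for row in reader:
            spanned = tuple(row["spanned_joints"].split(";"))
            cranial, _ = SpineGeometry.joint_bodies(spanned[0])
            if spanned[-1] in SIJ_JOINTS:
                caudal = "Pelvis"
            else:
                _, caudal = SpineGeometry.joint_bodies(spanned[-1])
            origin = np.array([float(row[f"origin_{c}"]) for c in "xyz"])
            insertion = np.array([float(row[f"insertion_{c}"]) for c in "xyz"])
            o_body, i_body = ((caudal, cranial) if origin[2] < insertion[2]
                              else (cranial, caudal))
            via = [np.array([float(c) for c in trip.split(",")])
                   for trip in row["via_points"].split(";") if trip]
            f = MuscleFascicle(
                name=row["name"], side=row["side"], group=row["group"],
                origin=origin, insertion=insertion, origin_body=o_body,
                insertion_body=i_body, f_max=float(row["f_max_N"]),
                spanned_joints=spanned, via_points=via)
            if geometry.spanned_joints(o_body, i_body) != spanned:
                raise ConfigurationError(
                    f"fascicle {f.name}: spanned joints not contiguous")
            fascicles.append(f)
    return fascicles


def mirror_point(p: np.ndarray) -> np.ndarray:
    """Reflect a point across the sagittal (XZ) plane."""
    return np.asarray(p) * np.array([1.0, -1.0, 1.0])
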