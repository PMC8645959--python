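"""Posterior pedicle-screw/rod fixation construct and MSK fusion constraints.

The FE side is a pair of rod beam chains connected to the vertebrae through
screw beams: each screw head shares a node with the rod (rigid head-rod
connection), and the shank is anchored to its vertebra by a rigid tie at the
pedicle entry point, reflecting bone purchase along the shank.  The MSK side
replaces the same levels by rigid kinematic/kinetic constraints (zero relative
rotation, full force and moment transmission).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .anatomy import SpineGeometry
from .config import FixationConfig, VERTEBRA_LABELS
from .errors import ConstructError


@dataclass
class Screw:
    level: str
    side: str
    head: np.ndarray                      # rod connection point
    entry: np.ndarray                     # pedicle entry (bone anchor)
    tip: np.ndarray
    diameter: float
    length: float


@dataclass
class Rod:
    side: str
    points: list                          # screw heads cranio-caudal order
    diameter: float


@dataclass
class FixationConstruct:
    config: FixationConfig
    screws: list = field(default_factory=list)
    rods: list = field(default_factory=list)

    @property
    def levels(self) -> tuple:
        return tuple(self.config.levels)


def build_fixation(geometry: SpineGeometry,
                   config: FixationConfig) -> FixationConstruct:
    """Build 2 screws per instrumented vertebra and 2 ipsilateral rods.

    Screws run from the pedicle entry toward the anterior vertebral body with
    the configured medial angulation; heads sit posterior of the entry along
    the screw axis.
    """
    config.validate()
    for level in config.levels:
        if level not in [v.label for v in geometry.vertebrae]:
            raise ConstructError(f"instrumented level {level!r} not in geometry")

    m = np.radians(config.medial_angle_deg)
    construct = FixationConstruct(config=config)
    for side, s in (("left", 1.0), ("right", -1.0)):
        heads = []
        for level in config.levels:
            v = geometry.frame(level)
            entry = v.pedicle_entry_left if side == "left" else v.pedicle_entry_right
            direction = v.orientation @ np.array(
                [np.cos(m), -s * np.sin(m), 0.0])
            tip = entry + config.screw_length_mm * direction
            head = entry - config.head_offset_mm * direction
            construct.screws.append(Screw(
                level=level, side=side, head=head, entry=entry, tip=tip,
                diameter=config.screw_diameter_mm,
                length=config.screw_length_mm))
            heads.append(head)
        construct.rods.append(Rod(side=side, points=heads,
                                  diameter=config.rod_diameter_mm))
    return construct


def add_construct_to_model(model, construct: FixationConstruct) -> None:
    """Insert construct nodes, beams and rigid ties into an FE model."""
    from .fe_solver import BeamSegment   # local import avoids a cycle

    cfg = construct.config
    for screw in construct.screws:
        head = f"screwhead_{screw.level}_{screw.side}"
        entry = f"screwentry_{screw.level}_{screw.side}"
        model.add_node(head, screw.head, body=screw.level)
        model.add_node(entry, screw.entry, body=screw.level)
        model.add_tie(entry, screw.level)
        model.beams.append(BeamSegment(
            node_i=head, node_j=entry, diameter=screw.diameter,
            elastic_modulus=cfg.elastic_modulus_mpa, poisson=cfg.poisson,
            component_id=f"screw_{screw.level}_{screw.side}"))
    n_el = cfg.rod_elements_per_span
    for rod in construct.rods:
        chain = []
        for a, b, lvl_a, lvl_b in zip(rod.points, rod.points[1:],
                                      cfg.levels, cfg.levels[1:]):
            chain.append(f"screwhead_{lvl_a}_{rod.side}")
            for k in range(1, n_el):
                t = k / n_el
                name = f"rodmid_{rod.side}_{lvl_a}_{lvl_b}_{k}"
                model.add_node(name, (1.0 - t) * a + t * b, body=lvl_a)
                chain.append(name)
        chain.append(f"screwhead_{cfg.levels[-1]}_{rod.side}")
        for ni, nj in zip(chain, chain[1:]):
            model.beams.append(BeamSegment(
                node_i=ni, node_j=nj, diameter=rod.diameter,
                elastic_modulus=cfg.elastic_modulus_mpa, poisson=cfg.poisson,
                component_id=f"rod_{rod.side}"))


def fuse_msk(levels) -> list:
    """Rigid-fusion joint constraints for the MSK model.

    Returns the joints interior to the fused block (L1-L5 -> L1/L2 … L4/L5);
    these carry zero imposed rotation and transmit the full wrench in inverse
    statics.
    """
    levels = tuple(levels)
    if len(levels) < 2:
        raise ConstructError("fusion needs >= 2 levels")
    idx = [VERTEBRA_LABELS.index(lv) for lv in levels]
    if sorted(idx) != list(range(min(idx), max(idx) + 1)):
        raise ConstructError(f"fused levels {levels} are not contiguous")
    ordered = [VERTEBRA_LABELS[i] for i in sorted(idx)]
    return [f"{a}/{b}" for a, b in zip(ordered, ordered[1:])]


def write_construct_csv(construct: FixationConstruct, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["component_id", "type", "level", "side",
                        "length_mm", "diameter_mm"])
        for s in construct.screws:
            writer.writerow([f"screw_{s.level}_{s.side}", "screw", s.level,
                             s.side, f"{s.length:.9g}", f"{s.diameter:.9g}"])
        for r in construct.rods:
            length = sum(float(np.linalg.norm(b - a))
                         for a, b in zip(r.points, r.points[1:]))
            writer.writerow([f"rod_{r.side}", "rod",
                             f"{construct.levels[0]}-{construct.levels[-1]}",
                             r.side, f"{length:.9g}", f"{r.diameter:.9g}"])
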