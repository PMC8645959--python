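"""Motion naming and sign conventions.

Global frame: right-handed, X anterior, Y left, Z cranial.  A motion is
identified with the axis of the driving moment (right-hand rule):

* flexion        +Y (cranial vertebrae tip anteriorly)
* extension      -Y
* lateral_left   -X (cranial vertebrae tip to the left)
* lateral_right  +X
* axial_rotation +Z (simplified loading only)
"""
from __future__ import annotations

import numpy as np

from .errors import SpineCoupleError

MOTION_AXES = {
    "flexion": np.array([0.0, 1.0, 0.0]),
    "extension": np.array([0.0, -1.0, 0.0]),
    "lateral_left": np.array([-1.0, 0.0, 0.0]),
    "lateral_right": np.array([1.0, 0.0, 0.0]),
    "axial_rotation": np.array([0.0, 0.0, 1.0]),
}

# Motions carried through the full coupling (stage B excludes axial rotation).
COUPLED_MOTIONS = ("flexion", "extension", "lateral_left", "lateral_right")


def motion_axis(motion: str) -> np.ndarray:
    """Unit moment axis for a named motion."""
    try:
        return MOTION_AXES[motion].copy()
    except KeyError:
        raise SpineCoupleError(f"unknown motion label {motion!r}") from None


def mirror_motion(motion: str) -> str:
    """Name of the motion obtained by reflection across the sagittal plane."""
    return {"lateral_left": "lateral_right", "lateral_right": "lateral_left"}.get(
        motion, motion)
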