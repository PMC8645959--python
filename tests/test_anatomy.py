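import numpy as np
import pytest

from spinecouple.anatomy import (build_default_spine, build_muscle_set,
                                 mirror_point, moment_arm, read_muscle_csv,
                                 write_muscle_csv)
from spinecouple.config import (AnatomyConfig, INTERVERTEBRAL_JOINTS,
                                MUSCLE_GROUPS, MuscleConfig, SIJ_JOINTS)
from spinecouple.errors import ConfigurationError
from spinecouple.motions import motion_axis


def test_default_geometry_counts_and_invariants(geometry):
    """T10..L5 + sacrum bodies, a pelvis, one joint per consecutive pair of
    bodies plus the two sacroiliac joints."""
    assert len(geometry.vertebrae) == 9          # T10..L5 + sacrum
    assert geometry.pelvis.label == "Pelvis"
    assert tuple(geometry.joints) == INTERVERTEBRAL_JOINTS + SIJ_JOINTS
    geometry.validate()                          # all invariants hold


def test_geometry_is_deterministic():
    a = build_default_spine(AnatomyConfig())
    b = build_default_spine(AnatomyConfig())
    for va, vb in zip(a.vertebrae, b.vertebrae):
        assert np.array_equal(va.center, vb.center)
        assert np.array_equal(va.orientation, vb.orientation)
    for joint in a.joints:
        assert np.array_equal(a.joint_centers[joint], b.joint_centers[joint])


def test_sagittal_symmetry_of_pedicles(geometry):
    for v in geometry.vertebrae:
        assert np.allclose(v.pedicle_entry_left,
                           mirror_point(v.pedicle_entry_right), atol=1e-9)


def test_centers_decrease_craniocaudally(geometry):
    zs = [v.center[2] for v in geometry.vertebrae]
    assert all(a > b for a, b in zip(zs, zs[1:]))


@pytest.mark.parametrize("field,value", [
    ("body_height_mm", -1.0),
    ("disc_height_mm", 0.0),
])
def test_invalid_anatomy_config_names_field(field, value):
    cfg = AnatomyConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=field):
        build_default_spine(cfg)


def test_all_nine_groups_present_bilaterally(fascicles):
    for group in MUSCLE_GROUPS:
        for side in ("left", "right"):
            assert any(f.group == group and f.side == side for f in fascicles)


def test_muscle_set_mirror_symmetry(geometry, fascicles):
    """Left and right fascicle sets are exact mirror images."""
    left = {f.name: f for f in fascicles if f.side == "left"}
    right = {f.name: f for f in fascicles if f.side == "right"}
    assert len(left) == len(right)
    for name, f in left.items():
        twin = right[name.replace("_left_", "_right_")]
        assert np.allclose(f.origin, mirror_point(twin.origin), atol=1e-9)
        assert np.allclose(f.insertion, mirror_point(twin.insertion), atol=1e-9)
        assert f.f_max == twin.f_max


def test_fmax_is_pcsa_times_specific_tension(geometry):
    cfg = MuscleConfig(specific_tension_n_per_cm2=90.0,
                       pcsa_cm2={g: 5.0 for g in MUSCLE_GROUPS})
    fs = build_muscle_set(geometry, cfg)
    assert all(f.f_max == pytest.approx(450.0) for f in fs)


def test_joint_coverage_opposing_moment_arms(geometry, fascicles):
    """Every intervertebral joint is spanned by fascicles with opposing
    moment arms about the flexion-extension and lateral-bending axes."""
    for joint in INTERVERTEBRAL_JOINTS:
        for axis in (motion_axis("flexion"), motion_axis("lateral_right")):
            arms = [moment_arm(f, joint, geometry) @ axis
                    for f in fascicles if joint in f.spanned_joints]
            assert max(arms) > 1.0 and min(arms) < -1.0, joint


def test_spanned_joints_are_contiguous(geometry, fascicles):
    for f in fascicles:
        assert f.spanned_joints == geometry.spanned_joints(
            f.origin_body, f.insertion_body)


def test_muscle_csv_round_trip(tmp_path, geometry, fascicles):
    path = tmp_path / "muscles.csv"
    write_muscle_csv(fascicles, path)
    loaded = read_muscle_csv(path, geometry)
    path2 = tmp_path / "muscles2.csv"
    write_muscle_csv(loaded, path2)
    assert path.read_text() == path2.read_text()
    assert [f.name for f in loaded] == [f.name for f in fascicles]


def test_fascicle_point_loads_are_self_equilibrated(fascicles):
    """Tensioned fascicle loads (including via-point redirections) sum to
    zero net force and zero net moment."""
    for f in fascicles:
        loads = f.point_loads(123.0)
        force = sum(load for _b, _p, load in loads)
        moment = sum(np.cross(p, load) for _b, p, load in loads)
        assert np.allclose(force, 0.0, atol=1e-9)
        assert np.allclose(moment, 0.0, atol=1e-6)
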