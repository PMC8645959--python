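import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinecouple.config import SolverConfig
from spinecouple.errors import AssemblyError, MappingError, SpineCoupleError
from spinecouple.fe_solver import (BeamSegment, BushingJoint, FEModel,
                                   LigamentSpring, LoadCase, apply_pure_moment,
                                   beam_von_mises, compute_rom,
                                   internal_cut_wrench, solve_static)
from spinecouple.motions import motion_axis


def two_body_model(k_rot=100000.0, k_trans=2000.0):
    """Lower body fixed, upper body connected by one bushing at the upper
    body's node, so the closed form decouples DOF by DOF."""
    m = FEModel()
    m.add_node("lower", [0.0, 0.0, 0.0])
    m.add_node("upper", [0.0, 0.0, 50.0])
    m.fix("lower")
    m.bushings.append(BushingJoint(
        joint_label="J", node_upper="upper", node_lower="lower",
        center=np.array([0.0, 0.0, 50.0]), frame=np.eye(3),
        K_rot=k_rot * np.eye(3), K_trans=k_trans * np.eye(3)))
    return m


class TestBeamVonMises:
    def test_pure_bending_matches_section_modulus_oracle(self):
        d, M = 5.5, 7500.0
        expected = 32.0 * M / (math.pi * d ** 3)   # 459.09... MPa
        got = beam_von_mises((0.0, 0.0, 0.0, 0.0, M, 0.0), d)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(459.17, abs=0.01)

    def test_pure_axial_matches_area_oracle(self):
        d, N = 5.5, 1000.0
        expected = 4.0 * N / (math.pi * d ** 2)    # 42.09... MPa
        got = beam_von_mises((N, 0.0, 0.0, 0.0, 0.0, 0.0), d)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(42.09, abs=0.01)

    def test_zero_forces_zero_stress(self):
        assert beam_von_mises((0.0,) * 6, 5.5) == 0.0

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(SpineCoupleError):
            beam_von_mises((1.0, 0, 0, 0, 0, 0), 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 100.0), st.floats(-5e4, 5e4), st.floats(-5e4, 5e4),
           st.floats(-5e4, 5e4))
    def test_positive_homogeneity(self, lam, n, t, my):
        """Stress is absolutely homogeneous of degree 1 in the section
        forces."""
        base = beam_von_mises((n, 0, 0, t, my, 0), 6.0)
        scaled = beam_von_mises((lam * n, 0, 0, lam * t, lam * my, 0), 6.0)
        assert scaled == pytest.approx(lam * base, rel=1e-9, abs=1e-9)


class TestStaticSolve:
    def test_zero_load_zero_state(self):
        r = solve_static(two_body_model())
        assert np.allclose(r.u["upper"], 0.0)
        assert r.residual_norm <= 1e-9
        assert all(v == 0.0 for v in r.von_mises.values())

    @pytest.mark.parametrize("dof", range(6))
    def test_single_joint_closed_form_all_dofs(self, dof):
        """One linear bushing: response equals the scalar spring law in every
        generalized direction."""
        k_rot, k_trans = 100000.0, 2000.0
        m = two_body_model(k_rot, k_trans)
        load = np.zeros(6)
        load[dof] = 500.0
        m.add_force("upper", load[:3])
        m.add_moment("upper", load[3:])
        r = solve_static(m)
        expected = np.zeros(6)
        expected[dof] = 500.0 / (k_trans if dof < 3 else k_rot)
        assert np.allclose(r.u["upper"], expected, rtol=1e-10, atol=1e-12)

    def test_rotation_spring_law_in_degrees(self):
        """k = 1 N·m/deg under 7.5 N·m -> 7.5 deg."""
        k = 1000.0 * 180.0 / math.pi          # 1 N·m/deg in N·mm/rad
        m = two_body_model(k_rot=k)
        m.add_moment("upper", [0.0, 7500.0, 0.0])
        r = solve_static(m)
        rom = compute_rom(r, "flexion")
        assert rom["J"] == pytest.approx(7.5, rel=1e-10)

    def test_linearity_without_ligaments(self):
        m1 = two_body_model()
        m1.add_moment("upper", [0.0, 7500.0, 0.0])
        m2 = two_body_model()
        m2.add_moment("upper", [0.0, 15000.0, 0.0])
        r1, r2 = solve_static(m1), solve_static(m2)
        assert np.allclose(2.0 * r1.u["upper"], r2.u["upper"], rtol=1e-10)

    def test_free_mechanism_raises_assembly_error(self):
        m = FEModel()
        m.add_node("a", [0.0, 0.0, 0.0])
        m.add_node("b", [0.0, 0.0, 50.0])
        m.fix("a")                             # b completely unconstrained
        with pytest.raises(AssemblyError):
            solve_static(m)

    def test_duplicate_support_is_idempotent(self):
        m = two_body_model()
        m.fix("lower")
        m.fix("lower")
        m.add_moment("upper", [0.0, 1000.0, 0.0])
        solve_static(m)

    def test_unknown_load_target_raises_mapping_error(self):
        m = two_body_model()
        with pytest.raises(MappingError):
            m.add_force("nonexistent", [1.0, 0.0, 0.0])

    def test_tension_only_ligament_is_one_sided(self):
        """A posterior ligament stiffens flexion but not extension."""
        def with_lig():
            m = two_body_model()
            m.ligaments.append(LigamentSpring(
                name="post", node_a="upper", point_a=np.array([-40.0, 0.0, 60.0]),
                node_b="lower", point_b=np.array([-40.0, 0.0, 40.0]),
                curve=np.array([[0.0, 0.0], [1.0, 50.0], [5.0, 250.0]]),
                slack_mm=0.0))
            return m
        m_flex = with_lig()
        m_flex.add_moment("upper", [0.0, 7500.0, 0.0])
        m_ext = with_lig()
        m_ext.add_moment("upper", [0.0, -7500.0, 0.0])
        bare = two_body_model()
        bare.add_moment("upper", [0.0, -7500.0, 0.0])
        rom_flex = compute_rom(solve_static(m_flex), "flexion")["J"]
        rom_ext = compute_rom(solve_static(m_ext), "flexion")["J"]
        rom_bare = compute_rom(solve_static(bare), "flexion")["J"]
        assert rom_ext == pytest.approx(rom_bare, rel=1e-9)   # slack side
        assert abs(rom_flex) < abs(rom_ext)                    # engaged side


class TestBeamElement:
    def test_cantilever_closed_forms(self):
        L, d, E, P = 100.0, 10.0, 200000.0, 1000.0
        I = math.pi * d ** 4 / 64.0
        A = math.pi * d * d / 4.0
        m = FEModel()
        m.add_node("a", [0.0, 0.0, 0.0])
        m.add_node("b", [0.0, 0.0, L])
        m.fix("a")
        m.beams.append(BeamSegment("a", "b", d, E, 0.3, "c"))
        m.add_force("b", [P, 0.0, P])
        r = solve_static(m)
        assert r.u["b"][0] == pytest.approx(P * L ** 3 / (3 * E * I), rel=1e-10)
        assert r.u["b"][2] == pytest.approx(P * L / (E * A), rel=1e-10)
        assert r.u["b"][4] == pytest.approx(P * L ** 2 / (2 * E * I), rel=1e-10)


class TestSpineLoadCases:
    def test_pure_moment_transmission_all_joints(self, pipeline):
        """Under a pure moment, the internal wrench across every
        intervertebral joint is exactly the applied couple: zero force and
        the full 7.5 N·m about the motion axis."""
        fe = pipeline.stage_a_simplified("intact", "flexion")
        axis = motion_axis("flexion")
        for joint in pipeline.geometry.joints:
            if joint.startswith("SIJ"):
                continue
            F, M = internal_cut_wrench(fe, joint)
            assert np.linalg.norm(F) <= 1e-8 * 7500.0
            assert M @ axis == pytest.approx(7500.0, rel=1e-8)

    def test_global_equilibrium_realistic(self, run_matrix):
        """Applied loads plus support/constraint reactions balance to solver
        tolerance (force and moment about the origin)."""
        out = run_matrix[("instrumented", "flexion")]
        model, result = out.fe_realistic.model, out.fe_realistic
        F = np.zeros(3)
        M = np.zeros(3)
        for node, force, point in model.point_loads:
            F += force
            M += np.cross(point, force)
        for node, moment in model.node_moments:
            M += moment
        for node, r in result.reactions.items():
            F += r[:3]
            M += r[3:] + np.cross(model.nodes[node], r[:3])
        scale = max(result.external_load_norm, 1.0)
        assert np.linalg.norm(F) <= 1e-6 * scale
        assert np.linalg.norm(M) <= 1e-3 * scale   # N·mm vs N scale

    def test_lateral_mirror_symmetry(self, run_matrix):
        """lateral_left and lateral_right produce mirror-identical ROMs and
        identical peak implant stresses with left/right labels swapped."""
        for variant in ("intact", "instrumented"):
            left = run_matrix[(variant, "lateral_left")]
            right = run_matrix[(variant, "lateral_right")]
            rom_l = left.report.rom_simplified
            rom_r = right.report.rom_simplified
            swap = {"SIJ-left": "SIJ-right", "SIJ-right": "SIJ-left"}
            for joint, v in rom_l.items():
                assert v == pytest.approx(rom_r[swap.get(joint, joint)],
                                          rel=1e-6, abs=1e-9)
            if variant == "instrumented":
                vm_l = left.fe_realistic.von_mises
                vm_r = right.fe_realistic.von_mises
                for comp, v in vm_l.items():
                    twin = comp.replace("left", "X").replace("right", "left")
                    twin = twin.replace("X", "right")
                    assert v == pytest.approx(vm_r[twin], rel=1e-5)

    def test_zero_force_solution_is_zero_load_case(self, pipeline):
        from spinecouple.fe_solver import apply_muscle_loads, assemble
        from spinecouple.msk_inverse import MuscleForceSolution
        sol = MuscleForceSolution(
            motion="flexion",
            fascicle_forces={f.name: 0.0 for f in pipeline.fascicles},
            t10_reaction=(np.zeros(3), np.zeros(3)),
            t10_translation=np.zeros(3), objective_value=0.0)
        model = assemble(pipeline.geometry, pipeline.bushings,
                         pipeline.ligaments)
        apply_muscle_loads(model, sol, pipeline.fascicles)
        r = solve_static(model)
        assert all(np.allclose(u, 0.0, atol=1e-12) for u in r.u.values())

    def test_loadcase_invariants(self):
        with pytest.raises(SpineCoupleError):
            LoadCase(mode="simplified", motion="flexion",
                     muscle_loads=[("T10", np.zeros(3), np.zeros(3))])
        with pytest.raises(SpineCoupleError):
            LoadCase(mode="realistic", motion="flexion", pure_moment=7500.0)

    def test_unknown_motion_rejected(self):
        m = two_body_model()
        m.geometry = None
        with pytest.raises(SpineCoupleError):
            apply_pure_moment(m, "sideways", 7500.0)

    def test_result_csv_schema(self, tmp_path, run_matrix):
        from spinecouple.fe_solver import write_result_csv
        fe = run_matrix[("instrumented", "flexion")].fe_simplified
        path = tmp_path / "result.csv"
        write_result_csv(fe, "flexion", path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("row_type,id,rom_deg,max_von_mises_MPa")
        joints = [l for l in lines if l.startswith("joint,")]
        comps = [l for l in lines if l.startswith("component,")]
        assert len(joints) == 10 and len(comps) == 12
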