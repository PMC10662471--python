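import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sescom.body_models import JointSpec, KinematicModel, build_preset
from sescom.kinematics import (
    Posture,
    Transform,
    com_weighted_sum,
    forward_transforms,
    is_rotation,
    joint_rotation,
    rotation_about_axis,
)
from sescom.synthetic import SubjectParams, sample_postures, sample_subject

angles = st.floats(-10.0, 10.0, allow_nan=False)


class TestElementaryRotations:
    def test_zero_angle_is_identity(self):
        for ax in "xyz":
            assert np.allclose(rotation_about_axis(ax, 0.0), np.eye(3))

    def test_y_quarter_turn_sends_x_to_minus_z(self):
        R = rotation_about_axis("y", np.pi / 2)
        assert np.allclose(R @ [1, 0, 0], [0, 0, -1], atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(beta=angles, gamma=angles)
    def test_composition_matches_direct_product(self, beta, gamma):
        direct = rotation_about_axis("x", beta) @ rotation_about_axis("z", gamma)
        cb, sb, cg, sg = np.cos(beta), np.sin(beta), np.cos(gamma), np.sin(gamma)
        oracle = np.array(
            [[cg, -sg, 0], [cb * sg, cb * cg, -sb], [sb * sg, sb * cg, cb]]
        )
        assert np.allclose(direct, oracle, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(ax=st.sampled_from("xyz"), angle=angles)
    def test_always_orthonormal_det_plus_one(self, ax, angle):
        assert is_rotation(rotation_about_axis(ax, angle))

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            rotation_about_axis("y", np.nan)


class TestJointRotation:
    def test_all_zero_is_identity(self):
        assert np.allclose(joint_rotation(("y", "x", "z"), (0, 0, 0)), np.eye(3))

    def test_degenerate_two_dof_equals_hinge(self):
        R = joint_rotation(("y", "x"), (np.pi / 2, 0.0))
        assert np.allclose(R, rotation_about_axis("y", np.pi / 2))

    def test_three_dof_equals_elementary_product(self, rng):
        a, b, g = rng.uniform(-np.pi, np.pi, 3)
        expected = (
            rotation_about_axis("y", a)
            @ rotation_about_axis("x", b)
            @ rotation_about_axis("z", g)
        )
        assert np.allclose(joint_rotation(("y", "x", "z"), (a, b, g)), expected)

    def test_angle_count_mismatch(self):
        with pytest.raises(ValueError, match="angle count"):
            joint_rotation(("y", "x"), (0.1,))


def _two_joint_chain(offset=(0.0, 0.0, -0.5)):
    joints = [
        JointSpec("j1", None, np.zeros(3), ("y",)),
        JointSpec("j2", "j1", np.asarray(offset), ("y",)),
    ]
    return KinematicModel("custom", joints, {"j1": "s1", "j2": "s2"})


class TestForwardTransforms:
    def test_zero_angles_accumulate_offsets(self):
        model = build_preset("d")
        p = Posture({j.name: (0.0,) * len(j.dof) for j in model.joints})
        tfs = forward_transforms(model, p)
        for j in model.joints:
            expected = sum(
                (model.joint(n).offset for n in model.path_from_root(j.name)),
                np.zeros(3),
            )
            assert np.allclose(tfs[j.name].translation, expected, atol=1e-12)
            assert np.allclose(tfs[j.name].rotation, np.eye(3))

    def test_half_turn_root_flips_child_offset(self):
        model = _two_joint_chain(offset=(0.3, 0.0, -0.5))
        d1 = np.array([0.1, 0.2, 0.3])
        p = Posture({"j1": (np.pi,), "j2": (0.0,)}, root_position=d1)
        tfs = forward_transforms(model, p)
        expected = d1 + rotation_about_axis("y", np.pi) @ np.array([0.3, 0.0, -0.5])
        assert np.allclose(tfs["j2"].translation, expected, atol=1e-12)

    def test_associativity_via_intermediate_frames(self, subject, model_d, rng):
        p = sample_postures(model_d, 1, rng)[0]
        tfs = forward_transforms(model_d, p)
        # recompute knee_r global by composing hip_r's global with the local step
        hip = tfs["hip_r"]
        knee_spec = model_d.joint("knee_r")
        local = Transform(
            joint_rotation(knee_spec.dof, p.joint_angles["knee_r"]), knee_spec.offset
        )
        via = hip.compose(local)
        assert np.allclose(via.rotation, tfs["knee_r"].rotation, atol=1e-12)
        assert np.allclose(via.translation, tfs["knee_r"].translation, atol=1e-12)

    def test_missing_joint_angles_rejected(self, model_d):
        with pytest.raises(ValueError, match="missing angles"):
            forward_transforms(model_d, Posture({"l5s1": (0.0, 0.0, 0.0)}))


class TestWeightedSumCom:
    def test_single_segment_zero_angles(self):
        model = KinematicModel(
            "custom", [JointSpec("j1", None, np.zeros(3), ("y",))], {"j1": "s1"}
        )
        params = SubjectParams({"s1": 2.0}, {"s1": np.array([0.1, 0.0, -0.2])})
        d1 = np.array([0.5, 0.0, 1.0])
        com = com_weighted_sum(model, params, Posture({"j1": (0.0,)}, d1))
        assert np.allclose(com, d1 + [0.1, 0.0, -0.2])

    def test_two_equal_segments_stacked(self):
        model = _two_joint_chain(offset=(0.0, 0.0, -0.5))
        params = SubjectParams(
            {"s1": 1.0, "s2": 1.0},
            {"s1": np.array([0, 0, -0.25]), "s2": np.array([0, 0, -0.25])},
        )
        p = Posture({"j1": (0.0,), "j2": (0.0,)})
        assert np.allclose(com_weighted_sum(model, params, p), [0, 0, -0.5])

    def test_mass_rescaling_invariance(self, subject, model_d, rng):
        params = subject.params_for(model_d)
        scaled = SubjectParams(
            {k: 3.7 * v for k, v in params.masses.items()}, params.com_offsets
        )
        p = sample_postures(model_d, 1, rng)[0]
        assert np.allclose(
            com_weighted_sum(model_d, params, p),
            com_weighted_sum(model_d, scaled, p),
            atol=1e-12,
        )

    def test_root_rotation_equivariance(self, subject, rng):
        """Adding a Y rotation at the 3-DoF root rotates CoM - d1 identically."""
        model = subject.model("d")
        params = subject.params_for(model)
        p = sample_postures(model, 1, rng)[0]
        delta = 0.7
        a, b, g = p.joint_angles["l5s1"]
        # root sequence starts with Y, so adding delta pre-composes globally
        com0 = com_weighted_sum(model, params, p) - p.root_position
        Rg = rotation_about_axis("y", delta)
        p_rot = Posture(dict(p.joint_angles))
        p_rot.joint_angles["l5s1"] = (a + delta, b, g)
        com1 = com_weighted_sum(model, params, p_rot) - p.root_position
        assert np.allclose(com1, Rg @ com0, atol=1e-12)

    def test_translation_equivariance_of_root(self, subject, model_d, rng):
        params = subject.params_for(model_d)
        p = sample_postures(model_d, 1, rng)[0]
        shift = np.array([0.2, -0.1, 0.05])
        shifted = Posture(dict(p.joint_angles), p.root_position + shift)
        assert np.allclose(
            com_weighted_sum(model_d, params, shifted),
            com_weighted_sum(model_d, params, p) + shift,
            atol=1e-12,
        )

    def test_nonpositive_total_mass_rejected(self, model_d):
        params = SubjectParams(
            {s: 0.0 for s in model_d.segment_of.values()},
            {s: np.zeros(3) for s in model_d.segment_of.values()},
        )
        p = Posture({j.name: (0.0,) * len(j.dof) for j in model_d.joints})
        with pytest.raises(ValueError, match="total mass"):
            com_weighted_sum(model_d, params, p)

    def test_negative_mass_rejected(self, subject, model_d):
        params = subject.params_for(model_d)
        params.masses["trunk"] = -1.0
        params.masses["arm_r"] += 50.0  # keep M > 0
        p = Posture({j.name: (0.0,) * len(j.dof) for j in model_d.joints})
        with pytest.raises(ValueError, match="negative mass"):
            com_weighted_sum(model_d, params, p)
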