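import numpy as np
import pytest

from sescom.body_models import JointSpec, KinematicModel, build_preset
from sescom.kinematics import Posture, com_weighted_sum, rotation_about_axis
from sescom.sesc import (
    Observation,
    ObservationSet,
    PostureShortageError,
    RankDeficiencyError,
    build_B,
    estimate_com,
    identify_full,
    identify_partial,
    min_postures,
    stack_full,
    true_sesc_vector,
)
from sescom.synthetic import (
    NoiseSpec,
    SubjectParams,
    generate_observations,
    sample_postures,
    sample_subject,
)


def two_joint_chain():
    joints = [
        JointSpec("j1", None, np.zeros(3), ("y",)),
        JointSpec("j2", "j1", np.array([0.0, 0.0, -0.5]), ("y",)),
    ]
    return KinematicModel("custom", joints, {"j1": "s1", "j2": "s2"})


def spherical_chain(n=3):
    """All-spherical serial chain: full column rank identifiable."""
    joints = [JointSpec("j1", None, np.zeros(3), ("y", "x", "z"))]
    for i in range(2, n + 1):
        joints.append(
            JointSpec(f"j{i}", f"j{i-1}", np.array([0.1, 0.05, -0.4]), ("y", "x", "z"))
        )
    return KinematicModel("custom", joints, {f"j{i}": f"s{i}" for i in range(1, n + 1)})


class TestBuildB:
    def test_zero_angles_gives_identity_blocks(self):
        model = build_preset("d")
        p = Posture({j.name: (0.0,) * len(j.dof) for j in model.joints})
        B = build_B(model, p)
        assert B.shape == (3, 27)
        assert np.allclose(B, np.hstack([np.eye(3)] * 9))

    def test_two_joint_chain_blocks(self):
        model = two_joint_chain()
        a1, a2 = 0.4, -0.9
        B = build_B(model, Posture({"j1": (a1,), "j2": (a2,)}))
        Ry = rotation_about_axis
        assert np.allclose(B[:, :3], Ry("y", a1))
        assert np.allclose(B[:, 3:], Ry("y", a1) @ Ry("y", a2))

    def test_hinge_only_model_has_constant_ml_row(self, rng):
        """All rotations about Y fix the Y row, the root of the ML
        degeneracy of the simplest body."""
        model = build_preset("a")
        expected = np.tile([0.0, 1.0, 0.0], model.n_joints)
        for p in sample_postures(model, 10, rng):
            assert np.allclose(build_B(model, p)[1], expected, atol=1e-12)


class TestTrueSescVector:
    def test_two_segment_toy_hand_values(self):
        model = two_joint_chain()
        params = SubjectParams(
            {"s1": 1.0, "s2": 1.0},
            {"s1": np.array([0, 0, -0.25]), "s2": np.array([0, 0, -0.25])},
        )
        V = true_sesc_vector(model, params)
        assert np.allclose(V[:3], [0, 0, -0.375])
        assert np.allclose(V[3:], [0, 0, -0.125])
        # cross-check: CoM at zero angles
        p = Posture({"j1": (0.0,), "j2": (0.0,)})
        assert np.allclose(estimate_com(model, V, p), [0, 0, -0.5])

    def test_zero_mass_distal_segment_gives_zero_block(self):
        model = two_joint_chain()
        params = SubjectParams(
            {"s1": 2.0, "s2": 0.0},
            {"s1": np.array([0, 0, -0.25]), "s2": np.array([0.1, 0.2, -0.25])},
        )
        V = true_sesc_vector(model, params)
        assert np.allclose(V[3:], 0.0)

    @pytest.mark.parametrize("mid", ["a", "b", "c", "d"])
    def test_serial_chain_matches_weighted_sum(self, mid, rng):
        """The central oracle: d1 + B V_true equals the weighted-segment
        sum for every posture, to 1e-10 m."""
        subject = sample_subject(rng)
        model = subject.model(mid)
        params = subject.params_for(model)
        V = true_sesc_vector(model, params)
        for p in sample_postures(model, 100, rng):
            p.root_position = rng.normal(0, 0.05, 3)
            direct = com_weighted_sum(model, params, p)
            serial = estimate_com(model, V, p)
            assert np.abs(direct - serial).max() < 1e-10


class TestIdentifyFull:
    def test_noiseless_recovery_on_spherical_chain(self, rng):
        model = spherical_chain(3)
        V_true = rng.normal(0, 0.1, 3 * model.n_joints)
        postures = sample_postures(
            model, 20, rng,
            {j.name: {ax: (-60, 60) for ax in j.dof} for j in model.joints},
        )
        B = stack_full(model, postures)
        targets = B @ V_true
        res = identify_full(B, targets)
        assert res.rank == 3 * model.n_joints
        assert np.abs(res.vector - V_true).max() < 1e-9

    def test_duplicate_postures_rank_deficient(self, rng):
        model = spherical_chain(3)
        p = sample_postures(model, 1, rng)[0]
        B = stack_full(model, [p] * 10)
        with pytest.raises(RankDeficiencyError, match="deficiency margin"):
            identify_full(B, np.zeros(30))

    def test_preset_hinge_children_are_structurally_deficient(self, rng):
        """A hinge-about-Y child duplicates its parent's y-column of B,
        so even the richest preset cannot be fully identified."""
        model = build_preset("d")
        postures = sample_postures(model, 30, rng)
        B = stack_full(model, postures)
        with pytest.raises(RankDeficiencyError):
            identify_full(B, np.zeros(B.shape[0]))

    def test_too_few_rows_rejected(self, rng):
        model = spherical_chain(3)
        B = stack_full(model, sample_postures(model, 2, rng))
        with pytest.raises(PostureShortageError):
            identify_full(B, np.zeros(6))

    def test_residual_rms_matches_noise_level(self, rng):
        """Least-squares residual RMS approaches the noise SD for a
        heavily overdetermined system."""
        model = spherical_chain(2)
        postures = sample_postures(
            model, 3400, rng,
            {j.name: {ax: (-60, 60) for ax in j.dof} for j in model.joints},
        )
        B = stack_full(model, postures)  # 10200 rows, 18 columns
        V_true = rng.normal(0, 0.1, 6)
        sigma = 0.004
        targets = B @ V_true + rng.normal(0, sigma, B.shape[0])
        res = identify_full(B, targets)
        assert abs(res.residual_rms - sigma) / sigma < 0.05


class TestIdentifyPartial:
    def test_min_postures_values(self):
        assert min_postures(build_preset("b")) == 14
        assert min_postures(build_preset("d")) == 14
        assert min_postures(build_preset("a")) == 11
        assert min_postures(build_preset("c")) == 11
        one = KinematicModel(
            "custom", [JointSpec("j1", None, np.zeros(3), ("y",))], {"j1": "s1"}
        )
        assert min_postures(one) == 2

    def test_shortage_raises(self, subject, model_d, rng):
        postures = sample_postures(model_d, 2, rng)
        obs = generate_observations(subject, model_d, postures, NoiseSpec(0, 0), rng)
        with pytest.raises(PostureShortageError, match="minimum 14"):
            identify_partial(obs, model_d)

    def test_shortage_overridable(self, subject, model_d, rng):
        postures = sample_postures(model_d, 5, rng)
        obs = generate_observations(subject, model_d, postures, NoiseSpec(0, 0), rng)
        with pytest.warns(RuntimeWarning):
            res = identify_partial(obs, model_d, allow_shortage=True)
        assert res.k_postures == 5

    def test_noiseless_cop_recovers_holdout_3d(self, subject, model_d, rng):
        """2D CoP observations suffice to predict full 3D CoM."""
        train = sample_postures(model_d, 40, rng)
        obs = generate_observations(subject, model_d, train, NoiseSpec(0, 0), rng)
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            res = identify_partial(obs, model_d)
        holdout = generate_observations(
            subject, model_d, sample_postures(model_d, 25, rng), NoiseSpec(0, 0), rng
        )
        for o in holdout:
            err = np.abs(estimate_com(model_d, res.vector, o.posture) - o.true_com)
            assert err.max() < 1e-8

    def test_hinge_model_ml_prediction_constant(self, subject, rng):
        model_a = build_preset("a")
        subject_params = subject.params_for(model_a)
        postures = sample_postures(model_a, 30, rng)
        obs = ObservationSet(
            [
                Observation(p, com_weighted_sum(model_a, subject_params, p)[:2])
                for p in postures
            ]
        )
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            res = identify_partial(obs, model_a)
        preds = [estimate_com(model_a, res.vector, p)[1] for p in postures]
        assert np.ptp(preds) < 1e-12

    def test_unbiased_predictions_under_cop_noise(self, subject, model_d):
        """Mean predicted CoM over noisy replicates approaches truth;
        the spread shrinks like 1/sqrt(replicates)."""
        rng = np.random.default_rng(5)
        train = sample_postures(model_d, 30, rng)
        probe = sample_postures(model_d, 1, rng)[0]
        truth = com_weighted_sum(model_d, subject.params_for(model_d), probe)
        preds = []
        for _ in range(200):
            obs = generate_observations(
                subject, model_d, train, NoiseSpec(cop_noise_sd_mm=5.0,
                                                   angle_noise_sd_deg=0.0), rng
            )
            with pytest.warns(RuntimeWarning):
                res = identify_partial(obs, model_d)
            preds.append(estimate_com(model_d, res.vector, probe))
        preds = np.array(preds)
        se = preds.std(axis=0) / np.sqrt(len(preds))
        assert np.all(np.abs(preds.mean(axis=0) - truth) < 4 * se + 1e-6)


class TestEstimateCom:
    def test_zero_angles_sums_blocks(self, subject, model_d):
        V = true_sesc_vector(model_d, subject.params_for(model_d))
        d1 = np.array([0.1, 0.0, -0.2])
        p = Posture({j.name: (0.0,) * len(j.dof) for j in model_d.joints}, d1)
        expected = d1 + V.reshape(-1, 3).sum(axis=0)
        assert np.allclose(estimate_com(model_d, V, p), expected)

    def test_affine_linearity_in_v(self, model_d, rng):
        p = sample_postures(model_d, 1, rng)[0]
        V1, V2 = rng.normal(0, 0.1, (2, 27))
        lhs = estimate_com(model_d, V1 + V2, p)
        rhs = (
            estimate_com(model_d, V1, p)
            + estimate_com(model_d, V2, p)
            - p.root_position
        )
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_length_mismatch_rejected(self, model_d):
        p = Posture({j.name: (0.0,) * len(j.dof) for j in model_d.joints})
        with pytest.raises(ValueError, match="length"):
            estimate_com(model_d, np.zeros(12), p)
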