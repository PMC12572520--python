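"""Rigid registration: exact recovery, optimality, reflections, TRE formula."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ribalign as ra
from ribalign.errors import DegenerateInputError, PairingError, ParameterError
from ribalign.landmarks import LandmarkSet
from ribalign.registration import alignment_objective


def _random_instance(seed, n, noise):
    rng = np.random.default_rng(seed)
    p = rng.normal(0.0, 80.0, (n, 3))
    tf = ra.RigidTransform.from_euler(rng.uniform(-180, 180, 3), rng.uniform(-100, 100, 3))
    q = tf.apply(p) + rng.normal(0.0, noise, (n, 3))
    return p, q, tf


class TestExactRecovery:
    def test_identity_case(self, generic_landmarks):
        res = ra.estimate_rigid_transform(generic_landmarks, generic_landmarks)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.transform.translation, 0.0, atol=1e-12)
        assert res.fre_rms <= 1e-12

    def test_pure_translation(self, generic_landmarks):
        res = ra.estimate_rigid_transform(generic_landmarks, generic_landmarks + [10.0, -5.0, 3.0])
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, [10.0, -5.0, 3.0], atol=1e-9)
        assert res.fre_rms <= 1e-9

    def test_constructed_rotation_translation(self, generic_landmarks):
        tf = ra.RigidTransform.from_euler((0.0, 0.0, 90.0), (1.0, 2.0, 3.0))
        res = ra.estimate_rigid_transform(generic_landmarks, tf.apply(generic_landmarks))
        np.testing.assert_allclose(res.transform.rotation, tf.rotation, atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, tf.translation, atol=1e-9)
        assert res.fre_rms <= 1e-9

    @pytest.mark.parametrize("n", [3, 4, 5, 8])
    @pytest.mark.parametrize("seed", range(10))
    def test_noiseless_recovery_across_sizes_and_seeds(self, n, seed):
        p, q, tf = _random_instance(1000 * n + seed, n, noise=0.0)
        res = ra.estimate_rigid_transform(p, q)
        np.testing.assert_allclose(res.transform.rotation, tf.rotation, atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, tf.translation, atol=1e-9)
        assert res.fre_rms <= 1e-9
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_landmarks_trigger_reflection_correction(self):
        p = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 1.0], [10, 10, 0.5]])
        q = p * [1, 1, -1]  # mirror across z=0
        res = ra.estimate_rigid_transform(p, q)
        assert res.reflection_corrected
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestDiagnostics:
    def test_fre_and_residuals_are_consistent(self):
        p, q, _ = _random_instance(5, 6, noise=3.0)
        res = ra.estimate_rigid_transform(p, q)
        assert res.fre_rms**2 * len(p) == pytest.approx(
            np.sum(res.per_landmark_residual**2), rel=1e-9
        )

    def test_svd_factors_reconstruct_covariance(self):
        p, q, _ = _random_instance(6, 5, noise=2.0)
        res = ra.estimate_rigid_transform(p, q)
        H = res.svd_U @ np.diag(res.svd_S) @ res.svd_Vt
        np.testing.assert_allclose(H, res.covariance_H, rtol=1e-9, atol=1e-9)

    def test_fre_invariant_under_pair_permutation(self):
        p, q, _ = _random_instance(7, 6, noise=2.0)
        res = ra.estimate_rigid_transform(p, q)
        perm = np.random.default_rng(0).permutation(6)
        res_p = ra.estimate_rigid_transform(p[perm], q[perm])
        assert res.fre_rms == pytest.approx(res_p.fre_rms, rel=1e-12)

    def test_named_landmark_sets_check_pairing(self):
        a = LandmarkSet(["x", "y", "z"], np.eye(3) * 10, "model")
        b = LandmarkSet(["x", "z", "y"], np.eye(3) * 10, "patient")
        with pytest.raises(PairingError):
            ra.estimate_rigid_transform(a, b)

    def test_collinear_landmarks_are_degenerate(self):
        line = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3.0]])
        with pytest.raises(DegenerateInputError):
            ra.estimate_rigid_transform(line, line)

    def test_fewer_than_three_landmarks_rejected(self):
        two = np.array([[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(DegenerateInputError):
            ra.estimate_rigid_transform(two, two)


class TestEquivariance:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conjugation_by_common_rotation(self, seed):
        p, q, _ = _random_instance(seed, 5, noise=2.0)
        Q = ra.RigidTransform.from_euler((17.0, -40.0, 71.0), (0, 0, 0)).rotation
        base = ra.estimate_rigid_transform(p, q).transform
        rot = ra.estimate_rigid_transform(p @ Q.T, q @ Q.T).transform
        np.testing.assert_allclose(rot.rotation, Q @ base.rotation @ Q.T, atol=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_translating_patient_set_adds_to_T(self, seed):
        p, q, _ = _random_instance(seed, 5, noise=2.0)
        v = np.array([12.0, -7.0, 30.0])
        base = ra.estimate_rigid_transform(p, q).transform
        shift = ra.estimate_rigid_transform(p, q + v).transform
        np.testing.assert_allclose(shift.translation, base.translation + v, atol=1e-9)
        np.testing.assert_allclose(shift.rotation, base.rotation, atol=1e-12)


class TestApplyTransform:
    def test_identity_leaves_input(self, generic_landmarks):
        out = ra.apply_transform(ra.RigidTransform.identity(), generic_landmarks)
        np.testing.assert_array_equal(out, generic_landmarks)

    def test_inverse_round_trip(self, generic_landmarks):
        tf = ra.RigidTransform.from_euler((30, 20, -60), (5, 6, 7))
        back = ra.apply_transform(tf.inverse(), ra.apply_transform(tf, generic_landmarks))
        assert np.abs(back - generic_landmarks).max() < 1e-9

    def test_rigidity_preserves_pairwise_distances(self, generic_landmarks):
        tf = ra.RigidTransform.from_euler((45, -10, 120), (-20, 3, 9))
        moved = ra.apply_transform(tf, generic_landmarks)
        d0 = np.linalg.norm(generic_landmarks[:, None] - generic_landmarks[None], axis=2)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_mesh_topology_untouched(self, sphere_mesh_r100):
        tf = ra.RigidTransform.from_euler((10, 20, 30), (1, 2, 3))
        out = ra.apply_transform(tf, sphere_mesh_r100)
        np.testing.assert_array_equal(out.faces, sphere_mesh_r100.faces)


class TestBruteForceOracle:
    def test_noiseless_pair_reaches_near_zero_objective(self):
        p, q, _ = _random_instance(11, 5, noise=0.0)
        oracle = ra.brute_force_oracle(p, q, angle_step=5.0)
        scale = np.sum((q - q.mean(0)) ** 2)
        # Grid resolution bound: 5 degrees of rotation error at most.
        assert alignment_objective(oracle, p, q) <= scale * np.radians(5.0 * np.sqrt(3)) ** 2

    @pytest.mark.parametrize("seed,noise", [(0, 1.0), (1, 5.0), (2, 2.0)])
    def test_svd_solution_never_beaten_by_grid(self, seed, noise):
        p, q, _ = _random_instance(seed, 4, noise=noise)
        svd_obj = ra.estimate_rigid_transform(p, q).objective
        grid_obj = alignment_objective(ra.brute_force_oracle(p, q, angle_step=4.0), p, q)
        assert svd_obj <= grid_obj + 1e-9

    def test_coarse_step_rejected(self, generic_landmarks):
        with pytest.raises(ParameterError):
            ra.brute_force_oracle(generic_landmarks, generic_landmarks, angle_step=10.0)


class TestExpectedTre:
    def test_target_at_centroid_equals_fle_over_sqrt_n(self, generic_landmarks):
        c = generic_landmarks.mean(axis=0)
        tre = ra.expected_tre(generic_landmarks, c, fle_rms=2.0)
        assert tre == pytest.approx(2.0 / np.sqrt(5), rel=1e-12)

    def test_monotone_along_principal_axes(self, generic_landmarks):
        c = generic_landmarks.mean(axis=0)
        pc = generic_landmarks - c
        axes = np.linalg.svd(pc)[2]
        for axis in axes:
            tres = [ra.expected_tre(generic_landmarks, c + d * axis, 2.0) for d in (0, 50, 100, 200)]
            assert all(b >= a for a, b in zip(tres, tres[1:]))

    def test_degenerate_configuration_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(DegenerateInputError):
            ra.expected_tre(line, np.zeros(3), 1.0)

    def test_nonpositive_fle_rejected(self, generic_landmarks):
        with pytest.raises(ParameterError):
            ra.expected_tre(generic_landmarks, np.zeros(3), 0.0)
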