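import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_rigid_fit
from conftest import random_transform
from lapnav.errors import (
    DegenerateConfigurationError,
    InsufficientPointsError,
    MethodMismatchError,
)
from lapnav.geometry import Pose, RigidTransform, rotation_about_axis
from lapnav.registration import (
    LandmarkPair,
    Method,
    PatientOrientation,
    fiducial_residuals,
    flrm_register,
    slrm_initialize,
    slrm_reregister,
)


def make_pose(rotation, translation=(0, 0, 0)):
    return Pose(0.0, "pointer", RigidTransform(rotation, translation))


def make_pairs(P, Q):
    return [LandmarkPair(str(i), p, q) for i, (p, q) in enumerate(zip(P, Q))]


FIDUCIALS = np.array(
    [
        [0.0, 0.0, 0.0],
        [100.0, 0.0, 0.0],
        [0.0, 80.0, 0.0],
        [0.0, 0.0, 60.0],
        [70.0, 70.0, 30.0],
    ]
)


class TestSlrm:
    def test_translation_only(self):
        res = slrm_initialize(
            make_pose(np.eye(3)),
            "supine",
            LandmarkPair("ref", [0, 0, 0], [5, 5, 5]),
        )
        assert np.allclose(res.transform.rotation, np.eye(3))
        assert np.allclose(res.transform.translation, [5, 5, 5])
        assert res.method is Method.SLRM

    def test_prone_flips_about_longitudinal_and_stays_exact(self):
        ref = LandmarkPair("ref", [3, 4, 5], [10, -2, 7])
        res = slrm_initialize(make_pose(np.eye(3)), PatientOrientation.PRONE, ref)
        expected_rot = rotation_about_axis([1, 0, 0], np.pi)
        np.testing.assert_allclose(res.transform.rotation, expected_rot, atol=1e-12)
        # registered point still maps exactly
        np.testing.assert_allclose(
            res.transform.apply(ref.p_image), ref.p_patient, atol=1e-12
        )

    def test_tool_rotation_is_carried_over(self):
        R = rotation_about_axis([0, 0, 1], np.deg2rad(30))
        res = slrm_initialize(
            make_pose(R), "supine", LandmarkPair("ref", [0, 0, 0], [0, 0, 0])
        )
        np.testing.assert_allclose(res.transform.rotation, R, atol=1e-12)
        np.testing.assert_allclose(res.transform.translation, 0, atol=1e-12)

    def test_orientation_sample_averaging(self):
        rz = lambda d: rotation_about_axis([0, 0, 1], np.deg2rad(d))
        poses = [make_pose(rz(10)), make_pose(rz(20))]
        ref = LandmarkPair("ref", [0, 0, 0], [0, 0, 0])
        res = slrm_initialize(poses, "supine", ref)
        np.testing.assert_allclose(res.transform.rotation, rz(15), atol=1e-9)
        res_last = slrm_initialize(poses, "supine", ref, orientation_mode="last")
        np.testing.assert_allclose(res_last.transform.rotation, rz(20), atol=1e-12)

    def test_reregister_updates_offset_only(self):
        current = slrm_initialize(
            make_pose(np.eye(3)), "supine", LandmarkPair("r", [0, 0, 0], [5, 5, 5])
        )
        new = slrm_reregister(current, LandmarkPair("n", [10, 0, 0], [12, 1, 0]))
        assert new.transform.rotation is current.transform.rotation or np.array_equal(
            new.transform.rotation, current.transform.rotation
        )
        np.testing.assert_allclose(new.transform.translation, [2, 1, 0])

    def test_reregister_fixed_point_and_idempotence(self, rng):
        current = slrm_initialize(
            make_pose(random_transform(rng).rotation),
            "supine",
            LandmarkPair("r", rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3)),
        )
        # a pair already satisfied by the transform leaves it unchanged
        p_img = rng.uniform(-50, 50, 3)
        satisfied = LandmarkPair("s", p_img, current.transform.apply(p_img))
        again = slrm_reregister(current, satisfied)
        assert again.transform.is_close(current.transform, atol=1e-12)
        # re-registering twice with one pair is idempotent
        pair = LandmarkPair("n", rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3))
        once = slrm_reregister(current, pair)
        twice = slrm_reregister(once, pair)
        assert np.array_equal(once.transform.translation, twice.transform.translation)
        np.testing.assert_allclose(
            once.transform.apply(pair.p_image), pair.p_patient, atol=1e-12
        )

    def test_reregister_rejects_flrm_result(self):
        res = flrm_register(make_pairs(FIDUCIALS, FIDUCIALS))
        with pytest.raises(MethodMismatchError):
            slrm_reregister(res, LandmarkPair("n", [0, 0, 0], [1, 1, 1]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_registered_point_always_exact(self, seed):
        rng = np.random.default_rng(seed)
        pose = make_pose(random_transform(rng).rotation)
        ref = LandmarkPair("r", rng.uniform(-100, 100, 3), rng.uniform(-100, 100, 3))
        orientation = "prone" if rng.random() < 0.5 else "supine"
        res = slrm_initialize(pose, orientation, ref)
        np.testing.assert_allclose(
            res.transform.apply(ref.p_image), ref.p_patient, atol=1e-9
        )


class TestFlrm:
    def test_identity_on_identical_point_sets(self):
        res = flrm_register(make_pairs(FIDUCIALS, FIDUCIALS))
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-12)
        assert res.fre == pytest.approx(0.0, abs=1e-12)
        assert res.n_points == 5

    def test_exact_recovery_of_constructed_transform(self):
        T = RigidTransform(rotation_about_axis([0, 0, 1], np.pi / 2), [10, 0, 0])
        res = flrm_register(make_pairs(FIDUCIALS, T.apply(FIDUCIALS)))
        assert res.transform.is_close(T, atol=1e-9)
        assert res.fre < 1e-9

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            flrm_register(make_pairs(FIDUCIALS[:2], FIDUCIALS[:2]))

    def test_collinear_configuration_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
        with pytest.raises(DegenerateConfigurationError):
            flrm_register(make_pairs(line, line))

    def test_reflection_correction_produces_proper_rotation(self):
        # mirrored targets would be fitted best by a reflection; the
        # correction must still return det = +1
        planar = FIDUCIALS.copy()
        planar[:, 2] = [0.0, 0.0, 0.0, 1.0, -1.0]  # nearly coplanar
        mirrored = planar * np.array([1.0, 1.0, -1.0])
        res = flrm_register(make_pairs(planar, mirrored))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.fre > 0

    def test_noisy_fit_matches_brute_force_oracle(self, rng):
        T = random_transform(rng)
        Q = T.apply(FIDUCIALS) + rng.normal(0, 0.5, FIDUCIALS.shape)
        res = flrm_register(make_pairs(FIDUCIALS, Q))
        R_o, t_o, fre_o = brute_force_rigid_fit(FIDUCIALS, Q)
        np.testing.assert_allclose(res.transform.rotation, R_o, atol=1e-6)
        np.testing.assert_allclose(res.transform.translation, t_o, atol=1e-6)
        assert res.fre == pytest.approx(fre_o, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_translation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        T = random_transform(rng)
        Q = T.apply(FIDUCIALS) + rng.normal(0, 0.5, FIDUCIALS.shape)
        shift = rng.uniform(-50, 50, 3)
        base = flrm_register(make_pairs(FIDUCIALS, Q))
        shifted = flrm_register(make_pairs(FIDUCIALS + shift, Q + shift))
        np.testing.assert_allclose(
            shifted.transform.rotation, base.transform.rotation, atol=1e-9
        )
        expected_t = base.transform.translation + shift - shifted.transform.rotation @ shift
        np.testing.assert_allclose(shifted.transform.translation, expected_t, atol=1e-6)


class TestFiducialResiduals:
    def test_perfect_fit_zero_residuals(self):
        res = flrm_register(make_pairs(FIDUCIALS, FIDUCIALS))
        np.testing.assert_allclose(
            fiducial_residuals(res, make_pairs(FIDUCIALS, FIDUCIALS)), 0, atol=1e-12
        )

    def test_identity_fit_on_offset_pairs(self):
        pairs = make_pairs(FIDUCIALS, FIDUCIALS + np.array([3.0, 4.0, 0.0]))
        from lapnav.registration import RegistrationResult

        res = RegistrationResult(RigidTransform.identity(), Method.FLRM, 5, fre=5.0)
        np.testing.assert_allclose(fiducial_residuals(res, pairs), 5.0, atol=1e-12)

    def test_rms_equals_fre(self, rng):
        T = random_transform(rng)
        Q = T.apply(FIDUCIALS) + rng.normal(0, 1.0, FIDUCIALS.shape)
        pairs = make_pairs(FIDUCIALS, Q)
        res = flrm_register(pairs)
        rms = np.sqrt(np.mean(fiducial_residuals(res, pairs) ** 2))
        assert rms == pytest.approx(res.fre, abs=1e-12)
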