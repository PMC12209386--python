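"""Quaternion algebra, displacement conversion, joint angles and the
tremor-rating gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from subtremor.kinematics import (JointAngleSet, QuaternionStream,
                                  TremorRatingModel, compose_joint_angles,
                                  displacement_series, is_subclinical,
                                  joint_angles, mean_square_power,
                                  quat_conjugate, quat_multiply, quat_normalize,
                                  rotate_reference, tremor_rating)

IDENT = np.array([1.0, 0.0, 0.0, 0.0])


def random_unit_quats(n, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


class TestQuaternionAlgebra:
    def test_identity_element(self, rng):
        q = rng.standard_normal(4)
        assert np.allclose(quat_multiply(IDENT, q), q)
        assert np.allclose(quat_multiply(q, IDENT), q)

    def test_ij_equals_k(self):
        i = np.array([0.0, 1.0, 0.0, 0.0])
        j = np.array([0.0, 0.0, 1.0, 0.0])
        assert np.allclose(quat_multiply(i, j), [0.0, 0.0, 0.0, 1.0])

    def test_norm_multiplicativity(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a, b = rng.standard_normal((2, 4))
            prod = quat_multiply(a, b)
            assert np.linalg.norm(prod) == pytest.approx(
                np.linalg.norm(a) * np.linalg.norm(b), abs=1e-12, rel=1e-12)

    def test_conjugate_flips_vector_part(self):
        assert np.allclose(quat_conjugate(IDENT), IDENT)
        assert np.allclose(quat_conjugate([0.0, 0.0, 0.0, 1.0]),
                           [0.0, 0.0, 0.0, -1.0])

    def test_q_times_conjugate_is_norm_squared(self, rng):
        for _ in range(50):
            q = rng.standard_normal(4)
            out = quat_multiply(q, quat_conjugate(q))
            assert np.allclose(out, [np.dot(q, q), 0.0, 0.0, 0.0], atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            quat_multiply(np.array([np.nan, 0, 0, 0]), IDENT)

    finite_quat = st.lists(
        st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=4,
        max_size=4).map(np.array)

    @settings(max_examples=100, derandomize=True)
    @given(finite_quat)
    def test_conjugate_is_involution(self, q):
        assert np.array_equal(quat_conjugate(quat_conjugate(q)), q)

    @settings(max_examples=100, derandomize=True)
    @given(finite_quat, finite_quat)
    def test_conjugate_antihomomorphism(self, a, b):
        # (a b)* = b* a*
        lhs = quat_conjugate(quat_multiply(a, b))
        rhs = quat_multiply(quat_conjugate(b), quat_conjugate(a))
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestRotateReference:
    def test_identity_rotation(self):
        assert np.allclose(rotate_reference(IDENT), [1.0, 0.0, 0.0])

    def test_half_turn_about_z(self):
        assert np.allclose(rotate_reference(np.array([0.0, 0.0, 0.0, 1.0])),
                           [-1.0, 0.0, 0.0], atol=1e-12)

    def test_conjugation_sense_quarter_turn(self):
        # q* P q is the inverse of the active rotation: a +90 deg turn about
        # z maps (1,0,0) to (0,-1,0), not (0,+1,0)
        q = np.array([np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)])
        assert np.allclose(rotate_reference(q), [0.0, -1.0, 0.0], atol=1e-12)

    def test_matches_rotation_matrix_oracle(self):
        # independent oracle: R(q)^T applied to P, with R from scipy's
        # active-convention rotation matrix
        for q in random_unit_quats(200, seed=11):
            R = Rotation.from_quat(q[[1, 2, 3, 0]]).as_matrix()
            expected = R.T @ np.array([1.0, 0.0, 0.0])
            assert np.allclose(rotate_reference(q), expected, atol=1e-9)

    def test_preserves_unit_norm(self):
        out = rotate_reference(random_unit_quats(500, seed=3))
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            rotate_reference(np.zeros(4))

    def test_warns_on_denormalized_input(self):
        with pytest.warns(UserWarning):
            quat_normalize(np.array([1.1, 0.0, 0.0, 0.0]))


class TestDisplacementSeries:
    def _stream(self, quats):
        quats = np.asarray(quats, dtype=float)
        return QuaternionStream(times=np.arange(len(quats)) / 100.0, quats=quats)

    def test_constant_orientation_gives_zero(self):
        stream = self._stream(np.tile(IDENT, (10, 1)))
        disp = displacement_series(stream)
        assert np.all(disp.vectors == 0)

    def test_antipodal_step(self):
        stream = self._stream([IDENT, [0.0, 0.0, 0.0, 1.0]])
        disp = displacement_series(stream)
        assert np.allclose(disp.vectors[1], [-2.0, 0.0, 0.0], atol=1e-12)
        assert disp.magnitude[1] == pytest.approx(2.0)

    def test_first_sample_exactly_zero(self):
        disp = displacement_series(self._stream(random_unit_quats(20, seed=5)))
        assert np.all(disp.vectors[0] == 0.0)
        assert len(disp.magnitude) == 20

    def test_small_angle_arc_length(self):
        # rotation about z (orthogonal to P): |X(t)-X(0)| ~ |theta| for tiny theta
        theta = 0.01 * np.sin(2 * np.pi * 5 * np.arange(100) / 100.0)
        half = theta / 2
        quats = np.column_stack([np.cos(half), np.zeros_like(half),
                                 np.zeros_like(half), np.sin(half)])
        disp = displacement_series(self._stream(quats))
        mask = np.abs(theta) > 1e-4
        assert np.allclose(disp.magnitude[mask], np.abs(theta[mask]), rtol=0.01)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            displacement_series(self._stream(np.empty((0, 4))))


class TestJointAngles:
    def _identity_stream(self, n=10, site="hand"):
        return QuaternionStream(times=np.arange(n) / 100.0,
                                quats=np.tile(IDENT, (n, 1)), site=site)

    def test_identical_sensors_give_zero_angles(self):
        ja = joint_angles(self._identity_stream(), self._identity_stream(),
                          self._identity_stream())
        for series in ja.as_dict().values():
            assert np.allclose(series, 0.0, atol=1e-12)

    def test_pure_flexion_recovered(self):
        n = 50
        theta = 0.3 * np.sin(np.linspace(0, 2 * np.pi, n))
        rw, _ = compose_joint_angles(theta, np.zeros(n), np.zeros(n), np.zeros(n))
        hand = QuaternionStream(times=np.arange(n) / 100.0, quats=rw, site="hand")
        ja = joint_angles(hand, self._identity_stream(n, "forearm"),
                          self._identity_stream(n, "upperarm"))
        assert np.allclose(ja.wfe, theta, atol=1e-9)
        assert np.allclose(ja.waa, 0.0, atol=1e-9)

    def test_euler_round_trip(self):
        rng = np.random.default_rng(9)
        wfe, waa, efe, eps = 0.4 * rng.standard_normal((4, 30))
        rw, re = compose_joint_angles(wfe, waa, efe, eps)
        n = 30
        ua = self._identity_stream(n, "upperarm")
        forearm = QuaternionStream(times=ua.times, quats=re, site="forearm")
        from subtremor.kinematics import quat_multiply as qm
        hand = QuaternionStream(times=ua.times, quats=qm(re, rw), site="hand")
        ja = joint_angles(hand, forearm, ua)
        assert np.allclose(ja.wfe, wfe, atol=1e-9)
        assert np.allclose(ja.waa, waa, atol=1e-9)
        assert np.allclose(ja.efe, efe, atol=1e-9)
        assert np.allclose(ja.eps, eps, atol=1e-9)

    def test_time_base_mismatch_rejected(self):
        a = self._identity_stream(10)
        b = QuaternionStream(times=np.arange(10) / 50.0,
                             quats=np.tile(IDENT, (10, 1)), site="forearm")
        with pytest.raises(ValueError):
            joint_angles(a, b, self._identity_stream(10, "upperarm"))


class TestMeanSquareAndRating:
    def test_constant_series(self):
        assert mean_square_power(np.full(100, 3.0)) == pytest.approx(9.0)

    def test_sine_closed_form(self):
        t = np.arange(1000) / 100.0
        a = 0.7 * np.sin(2 * np.pi * 5 * t)  # whole periods over 10 s
        assert mean_square_power(a) == pytest.approx(0.7**2 / 2, abs=1e-6)

    def test_concatenation_invariance(self, rng):
        x = rng.standard_normal(64)
        assert mean_square_power(np.concatenate([x, x])) == pytest.approx(
            mean_square_power(x))

    def test_unit_powers_return_intercept(self):
        powers = {"WFE": 1.0, "WAA": 1.0, "EPS": 1.0, "EFE": 1.0}
        assert tremor_rating(powers) == pytest.approx(2.6496)

    def test_single_decade_increment(self):
        powers = {"WFE": 10.0, "WAA": 1.0, "EPS": 1.0, "EFE": 1.0}
        assert tremor_rating(powers) == pytest.approx(2.6496 + 0.3071)

    def test_global_decade_raises_by_coefficient_sum(self):
        base = {"WFE": 0.3, "WAA": 2.0, "EPS": 0.9, "EFE": 5.0}
        up = {k: 10 * v for k, v in base.items()}
        assert tremor_rating(up) - tremor_rating(base) == pytest.approx(
            0.3071 + 0.0731 + 0.1843 + 0.0988)

    def test_strictly_increasing_in_each_power(self):
        base = {"WFE": 1.0, "WAA": 1.0, "EPS": 1.0, "EFE": 1.0}
        r0 = tremor_rating(base)
        for joint in base:
            bumped = dict(base)
            bumped[joint] = 2.0
            assert tremor_rating(bumped) > r0

    def test_nonpositive_power_names_joint(self):
        with pytest.raises(ValueError, match="EPS"):
            tremor_rating({"WFE": 1.0, "WAA": 1.0, "EPS": 0.0, "EFE": 1.0})

    def test_configurable_log_base(self):
        model = TremorRatingModel(log_base=np.e)
        powers = {"WFE": np.e, "WAA": 1.0, "EPS": 1.0, "EFE": 1.0}
        assert tremor_rating(powers, model) == pytest.approx(2.6496 + 0.3071)

    @pytest.mark.parametrize("rating,expected", [
        (0.49, True), (0.5, False), (-3.0, True), (0.51, False)])
    def test_subclinical_gate_is_strict(self, rating, expected):
        assert is_subclinical(rating) is expected

    def test_non_finite_rating_rejected(self):
        with pytest.raises(ValueError):
            is_subclinical(float("nan"))
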