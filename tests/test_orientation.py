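"""Quaternion algebra, global motion angle and quality labelling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from imu_qc.errors import AlignmentError, EmptyInputError, InvalidQuaternionError
from imu_qc.orientation import (
    AngleSeries,
    QuaternionSeries,
    enforce_continuity,
    express_relative_to_initial,
    global_motion_angle,
    label_from_rmsd,
    quat_conjugate,
    quat_from_axis_angle,
    quat_multiply,
    quat_rotate,
    relative_orientation_series,
    rmsd_deg,
)

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _random_units(rng, n):
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def _as_matrix(q):
    # scipy uses scalar-last ordering
    return Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1)).as_matrix()


class TestQuatMultiply:
    def test_identity_and_inverse(self, rng):
        q = _random_units(rng, 1)[0]
        np.testing.assert_allclose(quat_multiply(IDENTITY, q), q, atol=1e-12)
        np.testing.assert_allclose(
            np.abs(quat_multiply(q, quat_conjugate(q))), IDENTITY, atol=1e-12
        )

    def test_matches_rotation_matrix_oracle(self, rng):
        """Hamilton product composes rotations exactly like matrix products."""
        a = _random_units(rng, 1000)
        b = _random_units(rng, 1000)
        ours = _as_matrix(quat_multiply(a, b))
        oracle = _as_matrix(a) @ _as_matrix(b)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_rotate_matches_matrix(self, rng):
        q = _random_units(rng, 50)
        v = rng.standard_normal((50, 3))
        ours = quat_rotate(q, v)
        oracle = np.einsum("nij,nj->ni", _as_matrix(q), v)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(InvalidQuaternionError):
            quat_multiply(np.zeros(4), IDENTITY)


class TestRelativeOrientation:
    def _series(self, rng, n=40):
        t = np.arange(n) / 100.0
        return QuaternionSeries(t, enforce_continuity(_random_units(rng, n)))

    def test_equal_streams_give_identity(self, rng):
        s = self._series(rng)
        rel = relative_orientation_series(s, s)
        np.testing.assert_allclose(np.abs(rel.q[:, 0]), 1.0, atol=1e-12)

    def test_identity_proximal_reproduces_distal_rotation(self):
        t = np.arange(5) / 100.0
        q30 = quat_from_axis_angle([0, 0, 1], np.full(5, np.radians(30.0)))
        prox = QuaternionSeries(t, np.tile(IDENTITY, (5, 1)))
        rel = relative_orientation_series(prox, QuaternionSeries(t, q30))
        np.testing.assert_allclose(rel.q, q30, atol=1e-12)

    def test_reconstruction_roundtrip(self, rng):
        """q_prox ⊗ q_rel recovers q_dist up to quaternion sign."""
        prox, dist = self._series(rng), self._series(rng)
        rel = relative_orientation_series(prox, dist)
        back = quat_multiply(prox.q, rel.q)
        dots = np.abs(np.sum(back * dist.q, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-9)

    def test_timestamp_mismatch_raises(self, rng):
        a = self._series(rng)
        b = QuaternionSeries(a.t + 0.5, a.q)
        with pytest.raises(AlignmentError):
            relative_orientation_series(a, b)


class TestExpressRelativeToInitial:
    def test_constant_series_becomes_identity(self, rng):
        q = _random_units(rng, 1)
        s = QuaternionSeries(np.arange(6) / 10.0, np.tile(q, (6, 1)))
        out = express_relative_to_initial(s)
        np.testing.assert_allclose(np.abs(out.q[:, 0]), 1.0, atol=1e-12)

    def test_first_output_is_identity(self, rng):
        s = QuaternionSeries(
            np.arange(4) / 10.0, enforce_continuity(_random_units(rng, 4))
        )
        out = express_relative_to_initial(s)
        np.testing.assert_allclose(np.abs(out.q[0]), [1, 0, 0, 0], atol=1e-12)

    def test_reapplying_initial_recovers_input(self, rng):
        s = QuaternionSeries(
            np.arange(30) / 10.0, enforce_continuity(_random_units(rng, 30))
        )
        out = express_relative_to_initial(s)
        back = quat_multiply(s.q[0], out.q)
        dots = np.abs(np.sum(back * s.q, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-9)

    def test_empty_series_raises(self):
        s = QuaternionSeries(np.array([]), np.zeros((0, 4)))
        with pytest.raises(EmptyInputError):
            express_relative_to_initial(s)


class TestGlobalMotionAngle:
    def test_identity_series_gives_zero(self):
        s = QuaternionSeries(np.arange(3) / 10.0, np.tile(IDENTITY, (3, 1)))
        np.testing.assert_allclose(global_motion_angle(s).deg, 0.0)

    def test_axis_angle_roundtrip(self, rng):
        angles = rng.uniform(0.0, 179.0, size=200)
        axes = rng.standard_normal((200, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        q = np.array(
            [quat_from_axis_angle(ax, np.radians(a)) for ax, a in zip(axes, angles)]
        )
        s = QuaternionSeries(np.arange(200) / 100.0, q)
        np.testing.assert_allclose(global_motion_angle(s).deg, angles, atol=1e-6)

    def test_invariant_to_sign_flip(self, rng):
        q = _random_units(rng, 100)
        t = np.arange(100) / 100.0
        a1 = global_motion_angle(QuaternionSeries(t, q)).deg
        a2 = global_motion_angle(QuaternionSeries(t, -q)).deg
        np.testing.assert_allclose(a1, a2, atol=1e-12)


class TestRmsd:
    def _angles(self, values):
        values = np.asarray(values, dtype=float)
        return AngleSeries(np.arange(len(values)) / 100.0, values)

    def test_identical_series_give_zero_and_symmetry(self, rng):
        a = self._angles(rng.uniform(0, 90, 50))
        b = self._angles(rng.uniform(0, 90, 50))
        assert rmsd_deg(a, a) == 0.0
        assert rmsd_deg(a, b) == pytest.approx(rmsd_deg(b, a))
        assert rmsd_deg(a, b) > 0.0

    def test_constant_offset(self):
        a = self._angles([10.0, 20.0, 30.0, 40.0])
        b = self._angles([13.0, 23.0, 33.0, 43.0])
        assert rmsd_deg(a, b) == pytest.approx(3.0)

    def test_hand_computed_two_sample_value(self):
        # offsets {3, 4} -> sqrt((9 + 16) / 2)
        a = self._angles([0.0, 0.0])
        b = self._angles([3.0, 4.0])
        assert rmsd_deg(a, b) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            rmsd_deg(self._angles([1.0, 2.0]), self._angles([1.0]))


class TestQualityLabel:
    @pytest.mark.parametrize(
        "rmsd,category",
        [
            (0.9, "good"),       # typical seated trunk segment
            (5.0, "good"),       # boundary: good band is inclusive at 5
            (5.01, "tolerable"),
            (10.0, "tolerable"), # bad means strictly larger than 10
            (10.01, "bad"),
            (0.0, "good"),
        ],
    )
    def test_thresholds(self, rmsd, category):
        assert label_from_rmsd(rmsd).category == category

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError):
            label_from_rmsd(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_partition_has_no_gaps_or_overlaps(self, rmsd):
        """Every non-negative RMSD lands in exactly one category."""
        label = label_from_rmsd(rmsd)
        memberships = [rmsd <= 5.0, 5.0 < rmsd <= 10.0, rmsd > 10.0]
        assert sum(memberships) == 1
        assert label.category == ("good", "tolerable", "bad")[memberships.index(True)]
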