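"""Quaternion algebra, joint-orientation series and quality labelling.

Conventions
-----------
Quaternions are scalar-first ``[w, x, y, z]`` with the Hamilton product, so
``quat_multiply(a, b)`` is the rotation *b* followed by *a* when rotations
act on column vectors.  A joint orientation is the relative orientation
between the modules strapped to the two adjacent body segments, expressed
relative to its value at the start of a task segment; the scalar *global
motion* angle extracted from it is the quantity whose accuracy the quality
control judges.

Quality categories follow the clinical-gait reliability bands: a segment is
*good* when its RMSD from the gold standard is at most 5 degrees, *tolerable*
up to 10 degrees, and *bad* beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, EmptyInputError, InvalidQuaternionError

__all__ = [
    "GOOD_MAX_DEG",
    "TOLERABLE_MAX_DEG",
    "CATEGORIES",
    "Quaternion",
    "QuaternionSeries",
    "AngleSeries",
    "QualityLabel",
    "quat_normalize",
    "quat_conjugate",
    "quat_multiply",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_from_rotvec",
    "quat_to_rotvec",
    "enforce_continuity",
    "relative_orientation_series",
    "express_relative_to_initial",
    "global_motion_angle",
    "rmsd_deg",
    "label_from_rmsd",
]

#: RMSD bands (degrees) separating good / tolerable / bad segments.
GOOD_MAX_DEG = 5.0
TOLERABLE_MAX_DEG = 10.0
CATEGORIES = ("good", "tolerable", "bad")

_NORM_EPS = 1e-12

# A plain ndarray of shape (4,) or (n, 4); alias used in signatures.
Quaternion = np.ndarray


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return *q* scaled to unit norm; raise on (near-)zero quaternions."""
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise InvalidQuaternionError(f"expected last axis 4, got shape {q.shape}")
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < _NORM_EPS):
        raise InvalidQuaternionError("zero-norm quaternion")
    return q / norm


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b, renormalized. Broadcasts over leading axes."""
    a = quat_normalize(a)
    b = quat_normalize(b)
    w1, x1, y1, z1 = (a[..., i] for i in range(4))
    w2, x2, y2, z2 = (b[..., i] for i in range(4))
    out = np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )
    return quat_normalize(out)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) *v* by unit quaternion(s) *q* (R(q) v)."""
    q = quat_normalize(q)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def quat_from_axis_angle(axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) for rotation of ``angle_rad`` about a fixed axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < _NORM_EPS:
        raise InvalidQuaternionError("zero-norm rotation axis")
    axis = axis / n
    angle_rad = np.asarray(angle_rad, dtype=float)
    half = angle_rad / 2.0
    w = np.cos(half)
    s = np.sin(half)
    return np.stack(
        [w, s * axis[0], s * axis[1], s * axis[2]],
        axis=-1,
    )


def quat_from_rotvec(rotvec: np.ndarray) -> np.ndarray:
    """Quaternion(s) from rotation vector(s) (axis * angle, radians)."""
    rotvec = np.asarray(rotvec, dtype=float)
    angle = np.linalg.norm(rotvec, axis=-1, keepdims=True)
    small = angle[..., 0] < 1e-12
    axis = np.where(angle > 1e-12, rotvec / np.where(angle > 0, angle, 1.0), 0.0)
    half = angle[..., 0] / 2.0
    w = np.cos(half)
    s = np.sin(half)
    q = np.concatenate([w[..., None], s[..., None] * axis], axis=-1)
    q[small] = np.array([1.0, 0.0, 0.0, 0.0])
    return q


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Rotation vector(s) (radians) of unit quaternion(s), angle in [0, pi]."""
    q = quat_normalize(q)
    # force w >= 0 so the extracted angle is the geodesic one
    q = np.where(q[..., :1] < 0, -q, q)
    vnorm = np.linalg.norm(q[..., 1:], axis=-1)
    angle = 2.0 * np.arctan2(vnorm, q[..., 0])
    scale = np.where(vnorm > 1e-12, angle / np.where(vnorm > 0, vnorm, 1.0), 2.0)
    # for tiny angles sin(a/2) ~ a/2, so v * 2 recovers the rotvec
    return q[..., 1:] * scale[..., None]


def enforce_continuity(q: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive samples satisfy dot >= 0.

    The two antipodal quaternions represent the same rotation; picking the
    hemisphere-continuous representative prevents spurious 360 degree jumps
    in angles derived from the series.
    """
    q = np.asarray(q, dtype=float).copy()
    if q.ndim != 2 or len(q) == 0:
        return q
    dots = np.sum(q[1:] * q[:-1], axis=1)
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


@dataclass(frozen=True)
class QuaternionSeries:
    """Unit quaternions over a strictly increasing time base (seconds)."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise InvalidQuaternionError(f"expected (n, 4) quaternions, got {q.shape}")
        if len(t) != len(q):
            raise AlignmentError("timestamps and quaternions differ in length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise AlignmentError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", quat_normalize(q))

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, start: int, end: int) -> "QuaternionSeries":
        return QuaternionSeries(self.t[start:end], self.q[start:end])


@dataclass(frozen=True)
class AngleSeries:
    """Scalar angle (degrees, >= 0) over time."""

    t: np.ndarray
    deg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        deg = np.asarray(self.deg, dtype=float)
        if len(t) != len(deg):
            raise AlignmentError("timestamps and angles differ in length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "deg", deg)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class QualityLabel:
    """Good / tolerable / bad category with the RMSD that produced it."""

    category: str
    rmsd: float


def _check_same_time(a_t: np.ndarray, b_t: np.ndarray) -> None:
    if len(a_t) != len(b_t):
        raise AlignmentError("series lengths differ")
    if len(a_t) and not np.allclose(a_t, b_t, atol=1e-9):
        raise AlignmentError("series timestamps differ")


def relative_orientation_series(
    proximal: QuaternionSeries, distal: QuaternionSeries
) -> QuaternionSeries:
    """Joint orientation: per-sample conj(q_prox) ⊗ q_dist, sign-continuous."""
    _check_same_time(proximal.t, distal.t)
    rel = quat_multiply(quat_conjugate(proximal.q), distal.q)
    return QuaternionSeries(proximal.t, enforce_continuity(rel))


def express_relative_to_initial(rel: QuaternionSeries) -> QuaternionSeries:
    """Re-reference a series to its first sample (first output = identity)."""
    if len(rel) == 0:
        raise EmptyInputError("cannot re-reference an empty series")
    out = quat_multiply(quat_conjugate(rel.q[0]), rel.q)
    return QuaternionSeries(rel.t, enforce_continuity(out))


def global_motion_angle(rel0: QuaternionSeries) -> AngleSeries:
    """Scalar rotation angle since segment start, from the quaternion scalar.

    theta(t) = 2 * acos(|w(t)|), in degrees; the |.| makes the angle
    invariant to the q -> -q sign ambiguity and keeps it in [0, 180].
    """
    w = np.clip(np.abs(rel0.q[:, 0]), 0.0, 1.0)
    return AngleSeries(rel0.t, np.degrees(2.0 * np.arccos(w)))


def rmsd_deg(est: AngleSeries, ref: AngleSeries) -> float:
    """Root-mean-squared difference between two angle series (degrees)."""
    _check_same_time(est.t, ref.t)
    if len(est) == 0:
        raise EmptyInputError("cannot compute RMSD of empty series")
    d = est.deg - ref.deg
    return float(np.sqrt(np.mean(d * d)))


def label_from_rmsd(rmsd: float) -> QualityLabel:
    """Map an RMSD (degrees) to its quality category.

    rmsd <= 5 -> good; 5 < rmsd <= 10 -> tolerable; rmsd > 10 -> bad.
    """
    rmsd = float(rmsd)
    if rmsd < 0 or not np.isfinite(rmsd):
        raise ValueError(f"RMSD must be a finite non-negative value, got {rmsd}")
    if rmsd <= GOOD_MAX_DEG:
        category = "good"
    elif rmsd <= TOLERABLE_MAX_DEG:
        category = "tolerable"
    else:
        category = "bad"
    return QualityLabel(category, rmsd)
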