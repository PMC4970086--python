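"""Resampling, cross-correlation synchronization and segmentation.

Raw AHRS modules record at 60 Hz on their own clock while the gold-standard
reference runs at 100 Hz; this module brings every stream onto the reference
grid (linear resampling, integer-lag cross-correlation alignment) and cuts
the aligned trial into the per-task, per-joint segments that the feature
extractor and the quality labeller consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    EmptyInputError,
    FlatSignalError,
    IngestionError,
)
from .orientation import (
    AngleSeries,
    QuaternionSeries,
    enforce_continuity,
    express_relative_to_initial,
    global_motion_angle,
    quat_normalize,
    relative_orientation_series,
)

__all__ = [
    "PHASES",
    "JOINTS",
    "JOINT_MODULES",
    "MODULES",
    "RawImuSeries",
    "SegmentAnnotation",
    "ImuSegment",
    "PreparedTrial",
    "resample_linear",
    "resample_quaternions",
    "xcorr_sync",
    "prepare_trial",
    "slice_segments",
]

#: Task phases of a timed-up-and-go trial, in execution order.
PHASES = ("sit", "sit_to_stand", "walk1", "walk2", "turn", "turn_to_sit")

#: Joints tracked by adjacent module pairs.
JOINTS = ("trunk", "hip", "knee", "ankle")

#: (proximal module, distal module) pair defining each joint.
JOINT_MODULES = {
    "trunk": ("pelvis", "trunk_upper"),
    "hip": ("pelvis", "thigh"),
    "knee": ("thigh", "shank"),
    "ankle": ("shank", "foot"),
}

MODULES = ("trunk_upper", "pelvis", "thigh", "shank", "foot")


@dataclass(frozen=True)
class RawImuSeries:
    """Raw 9-axis IMU stream: accel in g, gyro in deg/s, mag in field units."""

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        for name in ("accel", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(t), 3):
                raise IngestionError(
                    f"{name} must have shape ({len(t)}, 3), got {arr.shape}"
                )
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "t", t)

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, start: int, end: int) -> "RawImuSeries":
        return RawImuSeries(
            self.t[start:end],
            self.accel[start:end],
            self.gyro[start:end],
            self.mag[start:end],
        )


@dataclass(frozen=True)
class SegmentAnnotation:
    """Half-open sample range [start, end) of one phase for one joint."""

    trial_id: str
    phase: str
    joint: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise AnnotationError(f"unknown phase {self.phase!r}")
        if self.joint not in JOINTS:
            raise AnnotationError(f"unknown joint {self.joint!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class ImuSegment:
    """All aligned streams of one (trial, phase, joint) segment."""

    trial_id: str
    phase: str
    joint: str
    raw_prox: RawImuSeries
    raw_dist: RawImuSeries
    ahrs_prox: QuaternionSeries
    ahrs_dist: QuaternionSeries
    ref: QuaternionSeries  # gold-standard joint orientation

    def __len__(self) -> int:
        return len(self.raw_prox)


@dataclass
class PreparedTrial:
    """One trial with every stream on the 100 Hz reference grid."""

    trial_id: str
    participant: int
    raw: dict[str, RawImuSeries] = field(default_factory=dict)
    ahrs: dict[str, QuaternionSeries] = field(default_factory=dict)
    ref: dict[str, QuaternionSeries] = field(default_factory=dict)
    lag: int = 0
    sync_joint: str = ""


def _uniform_grid(t: np.ndarray, target_hz: float) -> np.ndarray:
    n_new = int(np.floor((t[-1] - t[0]) * target_hz + 1e-9)) + 1
    return t[0] + np.arange(n_new) / target_hz


def resample_linear(series: RawImuSeries, target_hz: float) -> RawImuSeries:
    """Linearly interpolate every channel onto a uniform grid.

    The grid starts at the first original timestamp and spans the original
    time range at ``target_hz``.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if len(series) < 2:
        raise EmptyInputError("need at least two samples to resample")
    t = series.t
    if np.any(np.diff(t) <= 0):
        raise IngestionError("timestamps must be strictly increasing")
    new_t = _uniform_grid(t, target_hz)
    cols = {}
    for name in ("accel", "gyro", "mag"):
        arr = getattr(series, name)
        cols[name] = np.column_stack(
            [np.interp(new_t, t, arr[:, k]) for k in range(3)]
        )
    return RawImuSeries(new_t, cols["accel"], cols["gyro"], cols["mag"])


def resample_quaternions(series: QuaternionSeries, target_hz: float) -> QuaternionSeries:
    """Resample a quaternion series by component-wise lerp + renormalization.

    Adequate for modest rate changes (60 -> 100 Hz) where consecutive
    rotations are close; sign continuity is enforced before interpolating.
    """
    if len(series) < 2:
        raise EmptyInputError("need at least two samples to resample")
    t = series.t
    if np.any(np.diff(t) <= 0):
        raise IngestionError("timestamps must be strictly increasing")
    q = enforce_continuity(series.q)
    new_t = _uniform_grid(t, target_hz)
    new_q = np.column_stack([np.interp(new_t, t, q[:, k]) for k in range(4)])
    return QuaternionSeries(new_t, quat_normalize(new_q))


def _as_array(signal) -> np.ndarray:
    if isinstance(signal, AngleSeries):
        return np.asarray(signal.deg, dtype=float)
    return np.asarray(signal, dtype=float)


def xcorr_sync(a, b, max_lag: int) -> int:
    """Integer lag of *b* relative to *a* maximizing normalized correlation.

    A positive result means *b* is a delayed copy of *a*:
    ``xcorr_sync(a, shift(a, k), max_lag) == k`` for any non-constant signal
    and ``|k| <= max_lag``.  Ties are broken toward the smallest |lag|.
    """
    x = _as_array(a)
    y = _as_array(b)
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise FlatSignalError("cross-correlation undefined on flat signal")
    x = x - np.mean(x)
    y = y - np.mean(y)
    best_lag = 0
    best_val = -np.inf
    # visit lags in order of increasing magnitude so that strict improvement
    # implements the smallest-|lag| tie rule
    for mag in range(0, max_lag + 1):
        for lag in ((0,) if mag == 0 else (-mag, mag)):
            if lag >= 0:
                xs = x[: len(x) - lag] if lag else x
                ys = y[lag:]
            else:
                xs = x[-lag:]
                ys = y[: len(y) + lag]
            n = min(len(xs), len(ys))
            if n < 2:
                continue
            xs, ys = xs[:n], ys[:n]
            denom = np.linalg.norm(xs) * np.linalg.norm(ys)
            if denom < 1e-12:
                continue
            val = float(np.dot(xs, ys) / denom)
            if val > best_val + 1e-12:
                best_val = val
                best_lag = lag
    return best_lag


def _joint_angle(
    quats: Mapping[str, QuaternionSeries], joint: str
) -> AngleSeries:
    prox, dist = JOINT_MODULES[joint]
    rel = relative_orientation_series(quats[prox], quats[dist])
    return global_motion_angle(express_relative_to_initial(rel))


def _shift_indices(n_ref: int, n_est: int, lag: int) -> np.ndarray:
    # ref index i maps to estimate index i + lag; clamp-pad the edges
    idx = np.arange(n_ref) + lag
    return np.clip(idx, 0, n_est - 1)


def prepare_trial(
    trial_id: str,
    participant: int,
    raw: Mapping[str, RawImuSeries],
    ahrs: Mapping[str, QuaternionSeries],
    ref: Mapping[str, QuaternionSeries],
    target_hz: float = 100.0,
    max_lag: int = 100,
) -> PreparedTrial:
    """Resample AHRS-side streams, synchronize to the reference and align.

    The synchronization signal is the global-motion angle of the most mobile
    joint (largest angular-velocity variance of its AHRS-derived angle); the
    estimated integer lag is applied to every AHRS-side stream so that all
    returned streams share the reference timestamps.
    """
    raw_rs = {m: resample_linear(s, target_hz) for m, s in raw.items()}
    ahrs_rs = {m: resample_quaternions(s, target_hz) for m, s in ahrs.items()}
    n_est = min(len(s) for s in list(raw_rs.values()) + list(ahrs_rs.values()))
    raw_rs = {m: s.slice(0, n_est) for m, s in raw_rs.items()}
    ahrs_rs = {m: s.slice(0, n_est) for m, s in ahrs_rs.items()}

    # pick the synchronization joint: highest variance of the angle increments
    est_angles = {j: _joint_angle(ahrs_rs, j) for j in JOINTS if j in
                  {jj for jj in JOINTS if all(m in ahrs_rs for m in JOINT_MODULES[jj])}}
    if not est_angles:
        raise EmptyInputError("no complete joint module pair available")
    sync_joint = max(est_angles, key=lambda j: float(np.var(np.diff(est_angles[j].deg))))
    ref_angle = global_motion_angle(express_relative_to_initial(ref[sync_joint]))
    lag = xcorr_sync(ref_angle, est_angles[sync_joint], max_lag)

    n_ref = min(len(s) for s in ref.values())
    t_ref = next(iter(ref.values())).t[:n_ref]
    idx = _shift_indices(n_ref, n_est, lag)

    prepared = PreparedTrial(trial_id=trial_id, participant=participant,
                             lag=lag, sync_joint=sync_joint)
    for m, s in raw_rs.items():
        prepared.raw[m] = RawImuSeries(t_ref, s.accel[idx], s.gyro[idx], s.mag[idx])
    for m, s in ahrs_rs.items():
        prepared.ahrs[m] = QuaternionSeries(t_ref, s.q[idx])
    for j, s in ref.items():
        prepared.ref[j] = QuaternionSeries(t_ref, s.q[:n_ref])
    return prepared


def _validate_annotations(
    annotations: Sequence[SegmentAnnotation], n_samples: int
) -> None:
    by_joint: dict[tuple[str, str], list[SegmentAnnotation]] = {}
    for ann in annotations:
        if ann.end > n_samples:
            raise AnnotationError(
                f"annotation [{ann.start}, {ann.end}) exceeds stream length {n_samples}"
            )
        by_joint.setdefault((ann.trial_id, ann.joint), []).append(ann)
    for (trial_id, joint), anns in by_joint.items():
        for prev, cur in zip(anns, anns[1:]):
            if cur.start < prev.end:
                raise AnnotationError(
                    f"overlapping/unordered annotations for {trial_id}/{joint}: "
                    f"[{prev.start},{prev.end}) then [{cur.start},{cur.end})"
                )


def slice_segments(
    trial: PreparedTrial, annotations: Sequence[SegmentAnnotation]
) -> list[ImuSegment]:
    """Cut a prepared trial into per-(phase, joint) segments.

    Annotations must be in phase order per joint, non-overlapping, and within
    bounds; output order follows the annotation order.
    """
    n = min(len(s) for s in trial.raw.values()) if trial.raw else 0
    _validate_annotations(annotations, n)
    segments = []
    for ann in annotations:
        prox, dist = JOINT_MODULES[ann.joint]
        segments.append(
            ImuSegment(
                trial_id=ann.trial_id,
                phase=ann.phase,
                joint=ann.joint,
                raw_prox=trial.raw[prox].slice(ann.start, ann.end),
                raw_dist=trial.raw[dist].slice(ann.start, ann.end),
                ahrs_prox=trial.ahrs[prox].slice(ann.start, ann.end),
                ahrs_dist=trial.ahrs[dist].slice(ann.start, ann.end),
                ref=trial.ref[ann.joint].slice(ann.start, ann.end),
            )
        )
    return segments
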