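"""Synthetic timed-up-and-go cohorts with a parametric AHRS error model.

The generator emulates the study design this package targets: participants
perform 5 m timed-up-and-go trials (sit, sit-to-stand, two walking bouts, a
180-degree turn, turn-to-sit) at three speeds, three repetitions each, with
modules on the upper trunk, pelvis, thigh, shank and foot tracking the
trunk, hip, knee and ankle joints.

Ground truth comes from smooth analytic joint-angle profiles; raw 60 Hz
accelerometer / gyroscope / magnetometer signals are derived from the true
kinematics (finite-difference angular velocity, gravity rotated into the
module frame, a homogeneous magnetic field rotated into the module frame)
plus seeded Gaussian noise, so gyroscope integration reproduces the true
orientation to numerical precision when noise is disabled.

The commercial AHRS fusion filter is deliberately *not* re-implemented:
orientation estimates are the truth composed with a heading-axis drift whose
rate follows the two accuracy drivers the quality-control method is built
around — a persistent magnetic-field difference between the modules of a
pair (floor-proximal perturbations decay with module height, so ankle >
knee >> hip/trunk) and angular velocity beyond the fusion filter's nominal
operating range.  Per-trial random perturbation amplitudes, drift-sign and
gain jitter spread the resulting segment RMSD across the good / tolerable /
bad bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigError
from .orientation import (
    QuaternionSeries,
    enforce_continuity,
    quat_conjugate,
    quat_from_axis_angle,
    quat_from_rotvec,
    quat_multiply,
    quat_rotate,
    quat_to_rotvec,
)
from .prep import JOINTS, MODULES, PHASES, RawImuSeries, SegmentAnnotation

__all__ = [
    "CohortConfig",
    "PerturbationConfig",
    "ErrorModelConfig",
    "NoiseConfig",
    "GroundTruthTrial",
    "SyntheticDataset",
    "generate_trial",
    "inject_magnetic_perturbation",
    "corrupt_orientation",
    "generate_cohort",
    "SEVERE_FLOOR_AMPLITUDE",
    "MODULE_HEIGHT_M",
    "SPEED_FACTORS",
]

#: typical module height above the floor (m) — drives the magnetic decay
MODULE_HEIGHT_M = {
    "trunk_upper": 1.30,
    "pelvis": 1.00,
    "thigh": 0.70,
    "shank": 0.35,
    "foot": 0.10,
}

#: speed condition -> scaling of angular-velocity amplitude (durations scale
#: with the inverse)
SPEED_FACTORS = {"slow": 0.7, "natural": 1.0, "fast": 1.4}
_SPEED_ORDER = ("natural", "slow", "fast")

#: base phase durations at natural speed (s)
BASE_PHASE_DURATION_S = {
    "sit": 3.0,
    "sit_to_stand": 1.5,
    "walk1": 2.5,
    "walk2": 2.5,
    "turn": 2.0,
    "turn_to_sit": 2.0,
}

#: posture excursion of each joint across the sit-to-stand transfer (deg)
POSTURE_EXCURSION_DEG = {"trunk": 15.0, "hip": 70.0, "knee": 80.0, "ankle": 20.0}

#: flexion-extension oscillation amplitude while walking (deg)
WALK_AMPLITUDE_DEG = {"trunk": 4.0, "hip": 20.0, "knee": 32.0, "ankle": 14.0}

#: postural sway amplitude while seated (deg)
SIT_SWAY_DEG = {"trunk": 1.0, "hip": 0.8, "knee": 0.5, "ankle": 0.5}

_WALK_FREQ_HZ = 0.9         # base flexion-extension frequency
_TURN_OSC_FACTOR = 0.6      # stepping amplitude during the turn
_ENV_RAMP_S = 0.3           # oscillation on/off ramp
_MARGIN_START_S = 0.6       # lead-in before the sit phase (sync headroom)
_MARGIN_END_S = 0.3
_BOUNCE_G = 0.12            # vertical acceleration bounce amplitude (g)
_MAG_WORLD = np.array([0.5, 0.0, -math.sqrt(3.0) / 2.0])  # unit field, dip ~60 deg

#: perturbation amplitude that reliably ruins a floor-proximal segment
SEVERE_FLOOR_AMPLITUDE = 0.8


@dataclass
class PerturbationConfig:
    """Floor-borne magnetic disturbance field."""

    floor_amplitude: float = 0.8   # max fractional field distortion at floor level
    decay_m: float = 0.4           # spatial decay length (m)
    wobble: float = 0.2            # slow temporal modulation fraction
    wobble_hz: float = 0.3

    def __post_init__(self) -> None:
        if self.floor_amplitude < 0 or self.decay_m <= 0:
            raise ConfigError("perturbation amplitudes/decay must be non-negative")


@dataclass
class ErrorModelConfig:
    """Parametric AHRS orientation-error model."""

    drift_gain_deg_s: float = 30.0   # deg/s heading drift per unit field deviation
    vel_gain: float = 0.05           # deg/s drift per deg/s of gyro norm above omega0
    omega0_deg_s: float = 150.0      # nominal operating-range ceiling
    drift_jitter_sd: float = 0.25    # lognormal sigma on the per-module drift gain
    orient_noise_deg: float = 0.3    # white orientation noise per sample
    ref_noise_deg: float = 0.2       # gold-standard orientation noise


@dataclass
class NoiseConfig:
    gyro_sd_deg_s: float = 1.0
    accel_sd_g: float = 0.02
    mag_sd: float = 0.005


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort."""

    n_participants: int = 20
    trials_per_participant: int = 9  # 3 speeds x 3 repetitions
    raw_rate_hz: float = 60.0
    ref_rate_hz: float = 100.0
    seed: int = 0
    max_sync_offset_samples: int = 20  # reference-grid samples the AHRS clock lags
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    error_model: ErrorModelConfig = field(default_factory=ErrorModelConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.trials_per_participant <= 0:
            raise ConfigError("participant/trial counts must be positive")
        if self.raw_rate_hz <= 0 or self.ref_rate_hz <= 0:
            raise ConfigError("sampling rates must be positive")


@dataclass
class GroundTruthTrial:
    """One trial: true kinematics, raw signals, reference and estimates."""

    participant: int
    trial_index: int
    trial_id: str
    speed: str
    t_offset_s: float
    offset_samples: int
    duration_s: float
    raw: dict[str, RawImuSeries]
    module_truth: dict[str, QuaternionSeries]
    ref: dict[str, QuaternionSeries]
    annotations: list[SegmentAnnotation]
    floor_amplitude: float = 0.0
    mag_amplitude: dict[str, float] = field(default_factory=dict)
    ahrs: dict[str, QuaternionSeries] | None = None


@dataclass
class SyntheticDataset:
    config: CohortConfig
    trials: list[GroundTruthTrial]
    annotations: list[SegmentAnnotation]

    @property
    def n_segments(self) -> int:
        return len(self.annotations)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _envelope(t: np.ndarray, t0: float, t1: float, ramp: float) -> np.ndarray:
    return _smoothstep((t - t0) / ramp) * _smoothstep((t1 - t) / ramp)


class _TrialKinematics:
    """Analytic joint-angle / heading profiles for one trial."""

    def __init__(self, speed_factor: float, amp_factor: float,
                 cadence_factor: float, rng: np.random.Generator) -> None:
        self.f = speed_factor
        self.amp = amp_factor
        self.walk_freq = _WALK_FREQ_HZ * speed_factor * cadence_factor
        self.osc_phase = {j: rng.uniform(0.0, 2.0 * math.pi) for j in JOINTS}
        self.sway_phase = rng.uniform(0.0, 2.0 * math.pi)

        bounds = {}
        t = _MARGIN_START_S
        for phase in PHASES:
            d = BASE_PHASE_DURATION_S[phase] / speed_factor
            bounds[phase] = (t, t + d)
            t += d
        self.phase_bounds = bounds
        self.duration = t + _MARGIN_END_S

    def _oscillation(self, t: np.ndarray, joint: str) -> np.ndarray:
        amp = WALK_AMPLITUDE_DEG[joint] * self.amp
        out = np.zeros_like(t)
        for phase, factor in (("walk1", 1.0), ("walk2", 1.0),
                              ("turn", _TURN_OSC_FACTOR)):
            t0, t1 = self.phase_bounds[phase]
            env = _envelope(t, t0, t1, _ENV_RAMP_S)
            out += env * factor * amp * np.sin(
                2.0 * math.pi * self.walk_freq * (t - t0) + self.osc_phase[joint]
            )
        # seated postural sway (also covers the lead-in margin)
        t0, t1 = self.phase_bounds["sit"]
        env = _envelope(t, 0.0, t1, _ENV_RAMP_S)
        out += env * SIT_SWAY_DEG[joint] * np.sin(
            2.0 * math.pi * 0.25 * t + self.sway_phase
        )
        return out

    def _posture(self, t: np.ndarray, joint: str) -> np.ndarray:
        e = POSTURE_EXCURSION_DEG[joint] * self.amp
        t0, t1 = self.phase_bounds["sit_to_stand"]
        up = _minimum_jerk((t - t0) / (t1 - t0))
        t0, t1 = self.phase_bounds["turn_to_sit"]
        down = _minimum_jerk((t - t0) / (t1 - t0))
        return e * (up - down)

    def joint_angles(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """True joint angle (deg) for each joint at times *t*."""
        return {j: self._posture(t, j) + self._oscillation(t, j) for j in JOINTS}

    def heading(self, t: np.ndarray) -> np.ndarray:
        """Whole-body heading (rad): 180-degree change during the turn."""
        t0, t1 = self.phase_bounds["turn"]
        return math.pi * _minimum_jerk((t - t0) / (t1 - t0))

    def pelvis_sway(self, t: np.ndarray) -> np.ndarray:
        """Lateral pelvis sway (deg) about the y axis while stepping."""
        env = np.zeros_like(t)
        for phase, factor in (("walk1", 1.0), ("walk2", 1.0),
                              ("turn", _TURN_OSC_FACTOR)):
            t0, t1 = self.phase_bounds[phase]
            env += factor * _envelope(t, t0, t1, _ENV_RAMP_S)
        return 3.0 * env * np.sin(
            2.0 * math.pi * self.walk_freq * t + self.sway_phase
        )

    def vertical_bounce(self, t: np.ndarray) -> np.ndarray:
        """Vertical acceleration bounce (g) at twice the step frequency."""
        env = np.zeros_like(t)
        for phase in ("walk1", "walk2", "turn"):
            t0, t1 = self.phase_bounds[phase]
            env += _envelope(t, t0, t1, _ENV_RAMP_S)
        return _BOUNCE_G * self.f * env * np.sin(
            4.0 * math.pi * self.walk_freq * t
        )

    def module_quats(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """True orientation of every module at times *t* (world frame)."""
        angles = self.joint_angles(t)
        qz = quat_from_axis_angle([0, 0, 1], self.heading(t))
        qy = quat_from_axis_angle([0, 1, 0], np.radians(self.pelvis_sway(t)))
        qx = {j: quat_from_axis_angle([1, 0, 0], np.radians(angles[j]))
              for j in JOINTS}
        out = {}
        out["pelvis"] = quat_multiply(qz, qy)
        out["trunk_upper"] = quat_multiply(out["pelvis"], qx["trunk"])
        out["thigh"] = quat_multiply(out["pelvis"], qx["hip"])
        out["shank"] = quat_multiply(out["thigh"], qx["knee"])
        out["foot"] = quat_multiply(out["shank"], qx["ankle"])
        return out


def _participant_factors(cfg: CohortConfig, participant: int) -> tuple[float, float]:
    """Anthropometric heterogeneity: per-participant amplitude/cadence scale."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9001, participant]))
    amp = float(np.clip(1.0 + 0.12 * rng.standard_normal(), 0.75, 1.30))
    cadence = float(np.clip(1.0 + 0.08 * rng.standard_normal(), 0.80, 1.25))
    return amp, cadence


def _gyro_from_quats(q: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity (deg/s) from finite orientation steps."""
    steps = quat_multiply(quat_conjugate(q[:-1]), q[1:])
    rv = quat_to_rotvec(steps) / dt
    gyro = np.vstack([rv, rv[-1:]])
    return np.degrees(gyro)


def _small_rotation_noise(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    if sd_deg <= 0:
        return np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    rv = rng.normal(0.0, math.radians(sd_deg), size=(n, 3))
    return quat_from_rotvec(rv)


def generate_trial(
    cfg: CohortConfig,
    participant: int,
    trial_index: int,
    rng: np.random.Generator,
) -> GroundTruthTrial:
    """Generate ground-truth kinematics and raw signals for one trial."""
    speed = _SPEED_ORDER[trial_index % len(_SPEED_ORDER)]
    amp_f, cad_f = _participant_factors(cfg, participant)
    kin = _TrialKinematics(SPEED_FACTORS[speed], amp_f, cad_f, rng)

    offset_samples = int(rng.integers(0, cfg.max_sync_offset_samples + 1))
    t_off = offset_samples / cfg.ref_rate_hz
    if t_off >= _MARGIN_START_S:
        raise ConfigError("max_sync_offset_samples exceeds the lead-in margin")

    dt = 1.0 / cfg.raw_rate_hz
    n_raw = int(np.floor((kin.duration - t_off) * cfg.raw_rate_hz)) + 1
    t_local = np.arange(n_raw) * dt
    t_world = t_local + t_off

    quats = kin.module_quats(t_world)
    bounce = kin.vertical_bounce(t_world)
    a_world = np.column_stack(
        [np.zeros_like(bounce), np.zeros_like(bounce), 1.0 + bounce]
    )
    noise = cfg.noise
    raw = {}
    module_truth = {}
    for m in MODULES:
        q = quats[m]
        qc = quat_conjugate(q)
        gyro = _gyro_from_quats(q, dt)
        accel = quat_rotate(qc, a_world)
        mag = quat_rotate(qc, _MAG_WORLD)
        if noise.gyro_sd_deg_s > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_sd_deg_s, gyro.shape)
        if noise.accel_sd_g > 0:
            accel = accel + rng.normal(0.0, noise.accel_sd_g, accel.shape)
        if noise.mag_sd > 0:
            mag = mag + rng.normal(0.0, noise.mag_sd, mag.shape)
        raw[m] = RawImuSeries(t_local, accel, gyro, mag)
        module_truth[m] = QuaternionSeries(t_local, enforce_continuity(q))

    n_ref = int(np.floor(kin.duration * cfg.ref_rate_hz)) + 1
    t_ref = np.arange(n_ref) / cfg.ref_rate_hz
    angles = kin.joint_angles(t_ref)
    ref = {}
    for j in JOINTS:
        q_joint = quat_from_axis_angle([1, 0, 0], np.radians(angles[j]))
        q_noise = _small_rotation_noise(rng, n_ref, cfg.error_model.ref_noise_deg)
        ref[j] = QuaternionSeries(
            t_ref, enforce_continuity(quat_multiply(q_joint, q_noise))
        )

    trial_id = f"P{participant:02d}_T{trial_index:02d}"
    annotations = []
    for phase in PHASES:
        t0, t1 = kin.phase_bounds[phase]
        start = int(round(t0 * cfg.ref_rate_hz))
        end = min(int(round(t1 * cfg.ref_rate_hz)), n_ref)
        for joint in JOINTS:
            annotations.append(
                SegmentAnnotation(trial_id, phase, joint, start, end)
            )

    return GroundTruthTrial(
        participant=participant,
        trial_index=trial_index,
        trial_id=trial_id,
        speed=speed,
        t_offset_s=t_off,
        offset_samples=offset_samples,
        duration_s=kin.duration,
        raw=raw,
        module_truth=module_truth,
        ref=ref,
        annotations=annotations,
    )


def inject_magnetic_perturbation(
    trial: GroundTruthTrial,
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
    amplitude: float | None = None,
) -> GroundTruthTrial:
    """Scale magnetometer signals by a floor-proximal disturbance field.

    The fractional distortion at a module is ``amplitude * exp(-h / decay)``
    with *h* the module height, so foot/shank modules see much more than
    pelvis/trunk.  ``amplitude`` defaults to a per-trial uniform draw in
    [0, floor_amplitude]; zero leaves the magnetometer untouched.
    """
    p = cfg.perturbation
    if amplitude is None:
        if rng is None:
            raise ValueError("provide either an rng or an explicit amplitude")
        amplitude = float(rng.uniform(0.0, p.floor_amplitude))
    trial.floor_amplitude = amplitude
    for m in MODULES:
        amp_m = amplitude * math.exp(-MODULE_HEIGHT_M[m] / p.decay_m)
        trial.mag_amplitude[m] = amp_m
        if amp_m == 0.0:
            continue
        t = trial.raw[m].t
        phase = rng.uniform(0.0, 2.0 * math.pi) if rng is not None else 0.0
        wobble = 1.0 + p.wobble * np.sin(2.0 * math.pi * p.wobble_hz * t + phase)
        scale = 1.0 + amp_m * wobble
        trial.raw[m].mag[:] = trial.raw[m].mag * scale[:, None]
    return trial


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def corrupt_orientation(
    trial: GroundTruthTrial,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> dict[str, QuaternionSeries]:
    """Derive per-module AHRS orientation estimates from the error model.

    Each module accumulates a heading-axis drift at a rate driven by its
    local magnetic-field deviation and by angular velocity beyond the
    nominal range; per-module random sign and lognormal gain jitter plus
    white orientation noise make the resulting joint error stochastic but
    feature-predictable.
    """
    em = cfg.error_model
    dt = 1.0 / cfg.raw_rate_hz
    win = max(1, int(round(0.5 * cfg.raw_rate_hz)))
    ahrs = {}
    for m in MODULES:
        raw = trial.raw[m]
        truth = trial.module_truth[m].q
        n = len(raw)
        dev = np.abs(np.linalg.norm(raw.mag, axis=1) - 1.0)
        gyro_norm = _moving_average(np.linalg.norm(raw.gyro, axis=1), win)
        rate = em.drift_gain_deg_s * dev + em.vel_gain * np.maximum(
            0.0, gyro_norm - em.omega0_deg_s
        )
        sign = float(rng.choice([-1.0, 1.0]))
        jitter = float(np.exp(rng.normal(0.0, em.drift_jitter_sd)))
        delta_deg = sign * jitter * np.cumsum(rate) * dt
        q_err = quat_from_axis_angle([0, 0, 1], np.radians(delta_deg))
        est = quat_multiply(q_err, truth)
        est = quat_multiply(est, _small_rotation_noise(rng, n, em.orient_noise_deg))
        ahrs[m] = QuaternionSeries(raw.t, enforce_continuity(est))
    trial.ahrs = ahrs
    return ahrs


def generate_cohort(cfg: CohortConfig, out_dir=None) -> SyntheticDataset:
    """Generate a full cohort; deterministic for a fixed config seed.

    When ``out_dir`` is given the cohort is also written to the standard CSV
    layout (see :mod:`imu_qc.io`) together with a segment-count summary.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants * cfg.trials_per_participant)
    trials: list[GroundTruthTrial] = []
    annotations: list[SegmentAnnotation] = []
    for p in range(cfg.n_participants):
        for ti in range(cfg.trials_per_participant):
            rng = np.random.default_rng(children[p * cfg.trials_per_participant + ti])
            trial = generate_trial(cfg, p, ti, rng)
            inject_magnetic_perturbation(trial, cfg, rng)
            corrupt_orientation(trial, cfg, rng)
            trials.append(trial)
            annotations.extend(trial.annotations)
    dataset = SyntheticDataset(cfg, trials, annotations)
    if out_dir is not None:
        from . import io as _io

        _io.write_dataset(dataset, out_dir)
    return dataset
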