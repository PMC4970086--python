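"""The 16 raw-signal features and their normalization.

Per joint-segment the classifier sees, for the proximal (module 1) and
distal (module 2) module of the pair:

==========  =============================================================
f1, f2      mean magnetic-field magnitude minus the calibration reference
f3, f4      population variance of the magnetic-field magnitude
f5, f6      mean accelerometer norm (g, gravity included)
f7, f8      mean gyroscope norm (deg/s)
f9--f11     proportion of angular velocity on each axis, module 1
f12--f14    proportion of angular velocity on each axis, module 2
f15         module 1 minus module 2 mean magnetic-field magnitude
f16         the same inter-module difference on the *previous* segment
==========  =============================================================

"Magnetic field" is summarized by the Euclidean norm of the magnetometer
triplet, which is orientation-invariant and therefore characterizes the
environment rather than the pose.  Axis proportions are means of absolute
per-axis angular velocity divided by their sum, so they always add to one;
a motionless segment falls back to the uninformative (1/3, 1/3, 1/3).

Before entering the network, features are passed through a signed square
root (sign(x) * sqrt(|x|); several features can be negative), standardized
with training-partition statistics, and clipped to +-3 standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFeatureError, EmptyInputError, NotFittedError
from .prep import ImuSegment, RawImuSeries

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "extract_features",
    "FeatureNormalizer",
    "fit_normalizer",
    "apply_normalizer",
    "signed_sqrt",
]

N_FEATURES = 16
FEATURE_NAMES = tuple(f"f{i}" for i in range(1, N_FEATURES + 1))

#: z-score clip bound (standard deviations).
CLIP_SD = 3.0


def _axis_proportions(gyro: np.ndarray) -> np.ndarray:
    means = np.mean(np.abs(gyro), axis=0)
    total = float(np.sum(means))
    if total <= 0.0:
        return np.full(3, 1.0 / 3.0)
    return means / total


def _module_stats(raw: RawImuSeries, mag_reference: float):
    mag_norm = np.linalg.norm(raw.mag, axis=1)
    return (
        float(np.mean(mag_norm) - mag_reference),
        float(np.var(mag_norm)),  # population variance
        float(np.mean(np.linalg.norm(raw.accel, axis=1))),
        float(np.mean(np.linalg.norm(raw.gyro, axis=1))),
        _axis_proportions(raw.gyro),
        float(np.mean(mag_norm)),
    )


def _inter_module_mag_diff(segment: ImuSegment) -> float:
    m1 = float(np.mean(np.linalg.norm(segment.raw_prox.mag, axis=1)))
    m2 = float(np.mean(np.linalg.norm(segment.raw_dist.mag, axis=1)))
    return m1 - m2


def extract_features(
    segment: ImuSegment,
    previous: ImuSegment | None = None,
    mag_reference: float = 1.0,
) -> np.ndarray:
    """Compute the 16-entry feature vector for one joint-segment.

    ``previous`` is the preceding segment of the same joint within the
    trial; when absent (first phase of a trial) f16 falls back to f15.
    """
    if len(segment) == 0:
        raise EmptyInputError("cannot extract features from an empty segment")
    if mag_reference <= 0:
        raise ValueError("mag_reference must be positive")

    dev1, var1, acc1, gyr1, prop1, _ = _module_stats(segment.raw_prox, mag_reference)
    dev2, var2, acc2, gyr2, prop2, _ = _module_stats(segment.raw_dist, mag_reference)
    f15 = _inter_module_mag_diff(segment)
    f16 = _inter_module_mag_diff(previous) if previous is not None else f15

    return np.array(
        [dev1, dev2, var1, var2, acc1, acc2, gyr1, gyr2,
         *prop1, *prop2, f15, f16]
    )


def signed_sqrt(x: np.ndarray) -> np.ndarray:
    """sign(x) * sqrt(|x|); compresses dynamic range, preserves sign."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x))


@dataclass
class FeatureNormalizer:
    """Signed-sqrt transform + z-score with training statistics, clipped.

    Fitted on the training partition only and persisted with the trained
    network so validation data is normalized with identical statistics.
    """

    mean_: np.ndarray | None = field(default=None)
    sd_: np.ndarray | None = field(default=None)
    clip_sd: float = CLIP_SD

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, X: np.ndarray) -> "FeatureNormalizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(X) < 2:
            raise EmptyInputError("need at least two training vectors")
        Z = signed_sqrt(X)
        mean = Z.mean(axis=0)
        sd = Z.std(axis=0)  # population SD
        for i, s in enumerate(sd):
            if s <= 1e-12:
                raise DegenerateFeatureError(
                    f"feature f{i + 1} has zero variance on the training set"
                )
        self.mean_ = mean
        self.sd_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("normalizer must be fitted before use")
        X = np.asarray(X, dtype=float)
        z = (signed_sqrt(X) - self.mean_) / self.sd_
        return np.clip(z, -self.clip_sd, self.clip_sd)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        if not self.fitted:
            raise NotFittedError("normalizer must be fitted before export")
        return {
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "clip_sd": self.clip_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        out = cls(clip_sd=float(d.get("clip_sd", CLIP_SD)))
        out.mean_ = np.asarray(d["mean"], dtype=float)
        out.sd_ = np.asarray(d["sd"], dtype=float)
        return out


def fit_normalizer(training: np.ndarray) -> FeatureNormalizer:
    """Fit normalization statistics on a (n, 16) training feature matrix."""
    return FeatureNormalizer().fit(training)


def apply_normalizer(model: FeatureNormalizer, v: np.ndarray) -> np.ndarray:
    """Normalize feature vector(s) with a fitted model."""
    return model.transform(v)
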