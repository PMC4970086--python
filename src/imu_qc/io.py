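"""CSV/YAML persistence for cohorts, feature tables and configs.

Layout of a cohort directory::

    cohort.yaml                 generator config + summary
    annotations.csv             trial_id,phase,joint,start,end  (0-based, half-open)
    trials/<trial_id>/
        meta.yaml               participant, trial index, speed
        raw_<module>.csv        time,ax,ay,az,gx,gy,gz,mx,my,mz
        ahrs_<module>.csv       time,w,x,y,z
        ref_<joint>.csv         time,w,x,y,z

Quaternions are scalar-first Hamilton-convention; time is in seconds on
the stream's own clock (AHRS-side streams are *not* pre-synchronized to
the reference — that is the signal-preparation stage's job).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .orientation import QuaternionSeries
from .prep import JOINTS, MODULES, RawImuSeries, SegmentAnnotation
from .synthetic import (
    CohortConfig,
    ErrorModelConfig,
    NoiseConfig,
    PerturbationConfig,
)

__all__ = [
    "write_quaternion_csv",
    "read_quaternion_csv",
    "write_raw_csv",
    "read_raw_csv",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_dataset",
    "load_dataset",
    "load_cohort_config",
]

_FLOAT_FMT = "%.9g"

_RAW_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
_QUAT_COLUMNS = ["time", "w", "x", "y", "z"]


def write_quaternion_csv(path, series: QuaternionSeries) -> None:
    df = pd.DataFrame(
        np.column_stack([series.t, series.q]), columns=_QUAT_COLUMNS
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_quaternion_csv(path) -> QuaternionSeries:
    df = pd.read_csv(path)
    return QuaternionSeries(df["time"].to_numpy(), df[["w", "x", "y", "z"]].to_numpy())


def write_raw_csv(path, series: RawImuSeries) -> None:
    df = pd.DataFrame(
        np.column_stack([series.t, series.accel, series.gyro, series.mag]),
        columns=_RAW_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_raw_csv(path) -> RawImuSeries:
    df = pd.read_csv(path)
    return RawImuSeries(
        df["time"].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(),
        df[["gx", "gy", "gz"]].to_numpy(),
        df[["mx", "my", "mz"]].to_numpy(),
    )


def write_annotations_csv(path, annotations) -> None:
    df = pd.DataFrame(
        [
            {"trial_id": a.trial_id, "phase": a.phase, "joint": a.joint,
             "start": a.start, "end": a.end}
            for a in annotations
        ]
    )
    df.to_csv(path, index=False)


def read_annotations_csv(path) -> list[SegmentAnnotation]:
    df = pd.read_csv(path)
    return [
        SegmentAnnotation(str(r.trial_id), str(r.phase), str(r.joint),
                          int(r.start), int(r.end))
        for r in df.itertuples()
    ]


@dataclass
class LoadedTrial:
    """A trial re-read from disk; quacks like a GroundTruthTrial for prep."""

    participant: int
    trial_id: str
    speed: str
    raw: dict[str, RawImuSeries] = field(default_factory=dict)
    ahrs: dict[str, QuaternionSeries] = field(default_factory=dict)
    ref: dict[str, QuaternionSeries] = field(default_factory=dict)


@dataclass
class LoadedDataset:
    config: dict
    trials: list[LoadedTrial]
    annotations: list[SegmentAnnotation]

    @property
    def n_segments(self) -> int:
        return len(self.annotations)


def write_dataset(dataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    summary = {
        "config": asdict(cfg) if not isinstance(cfg, dict) else cfg,
        "n_trials": len(dataset.trials),
        "n_segments": len(dataset.annotations),
    }
    (out / "cohort.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    write_annotations_csv(out / "annotations.csv", dataset.annotations)
    for trial in dataset.trials:
        tdir = out / "trials" / trial.trial_id
        tdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "participant": int(trial.participant),
            "trial_id": trial.trial_id,
            "speed": getattr(trial, "speed", ""),
        }
        (tdir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
        for m, series in trial.raw.items():
            write_raw_csv(tdir / f"raw_{m}.csv", series)
        if trial.ahrs:
            for m, series in trial.ahrs.items():
                write_quaternion_csv(tdir / f"ahrs_{m}.csv", series)
        for j, series in trial.ref.items():
            write_quaternion_csv(tdir / f"ref_{j}.csv", series)


def load_dataset(path) -> LoadedDataset:
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {root}")
    cohort = yaml.safe_load((root / "cohort.yaml").read_text()) if (
        root / "cohort.yaml"
    ).exists() else {}
    annotations = read_annotations_csv(root / "annotations.csv")
    trials = []
    for tdir in sorted((root / "trials").iterdir()):
        if not tdir.is_dir():
            continue
        meta = yaml.safe_load((tdir / "meta.yaml").read_text())
        trial = LoadedTrial(
            participant=int(meta["participant"]),
            trial_id=str(meta["trial_id"]),
            speed=str(meta.get("speed", "")),
        )
        for m in MODULES:
            raw_path = tdir / f"raw_{m}.csv"
            if raw_path.exists():
                trial.raw[m] = read_raw_csv(raw_path)
            ahrs_path = tdir / f"ahrs_{m}.csv"
            if ahrs_path.exists():
                trial.ahrs[m] = read_quaternion_csv(ahrs_path)
        for j in JOINTS:
            ref_path = tdir / f"ref_{j}.csv"
            if ref_path.exists():
                trial.ref[j] = read_quaternion_csv(ref_path)
        trials.append(trial)
    return LoadedDataset(config=cohort.get("config", {}), trials=trials,
                         annotations=annotations)


def load_cohort_config(path) -> CohortConfig:
    """Build a CohortConfig from a YAML file (missing keys -> defaults)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "config" in doc:  # accept a cohort.yaml summary as well
        doc = doc["config"]
    sub = {
        "perturbation": PerturbationConfig,
        "error_model": ErrorModelConfig,
        "noise": NoiseConfig,
    }
    kwargs = {}
    for key, value in doc.items():
        if key in sub:
            kwargs[key] = sub[key](**value)
        else:
            kwargs[key] = value
    return CohortConfig(**kwargs)
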