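"""Sensitivity/specificity, pre/post-QC accuracy tables and the pipeline.

Sensitivity is the proportion of *good* segments the classifier accepts;
specificity the proportion of *bad* segments it rejects.  Tolerable
segments enter neither metric — they are quality-graded but deliberately
kept out of both definitions — although their post-QC fate shows up in the
label-distribution report.

``run_pipeline`` drives the whole method end to end: signal preparation,
quality labelling against the reference, feature extraction, normalization
fitted on the training participants only, class-balanced network training
(with a small inner-fold grid over the L2 penalty and the gain operating
point), and accept/reject evaluation on the held-out participants.  The train/validation split is
always at the participant level; a leak guard raises if training rows ever
include a validation participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SplitLeakError, UndefinedMetricError
from .features import FEATURE_NAMES, FeatureNormalizer, extract_features
from .network import (
    NetworkParams,
    TrainingConfig,
    TrainingReport,
    balanced_gains,
    predict_accept,
    train,
)
from .orientation import (
    express_relative_to_initial,
    global_motion_angle,
    label_from_rmsd,
    relative_orientation_series,
    rmsd_deg,
)
from .prep import JOINTS, PHASES, ImuSegment, prepare_trial, slice_segments

__all__ = [
    "ConfusionCounts",
    "confusion_from",
    "sensitivity",
    "specificity",
    "segment_quality",
    "build_segment_table",
    "pre_post_table",
    "label_distribution",
    "PipelineResult",
    "run_pipeline",
]

#: display order of the pooled phases in the pre/post table
_TABLE_PHASES = ("sit", "sit_to_stand", "walk", "turn", "turn_to_sit")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-category totals and per-category accepted counts."""

    n_good: int
    n_tolerable: int
    n_bad: int
    n_accepted_good: int
    n_accepted_tolerable: int
    n_accepted_bad: int

    def __post_init__(self) -> None:
        for cat in ("good", "tolerable", "bad"):
            total = getattr(self, f"n_{cat}")
            acc = getattr(self, f"n_accepted_{cat}")
            if not (0 <= acc <= total):
                raise ValueError(f"accepted {cat} count outside [0, {total}]")


def confusion_from(labels: Sequence[str], accepted: Iterable[bool]) -> ConfusionCounts:
    labels = [lab.category if hasattr(lab, "category") else str(lab) for lab in labels]
    accepted = list(accepted)
    if len(labels) != len(accepted):
        raise ValueError("labels and accept flags differ in length")
    counts = {}
    for cat in ("good", "tolerable", "bad"):
        idx = [i for i, lab in enumerate(labels) if lab == cat]
        counts[f"n_{cat}"] = len(idx)
        counts[f"n_accepted_{cat}"] = sum(bool(accepted[i]) for i in idx)
    return ConfusionCounts(**counts)


def sensitivity(c: ConfusionCounts) -> float:
    """Fraction of good segments accepted."""
    if c.n_good == 0:
        raise UndefinedMetricError("sensitivity undefined without good segments")
    return c.n_accepted_good / c.n_good


def specificity(c: ConfusionCounts) -> float:
    """Fraction of bad segments rejected."""
    if c.n_bad == 0:
        raise UndefinedMetricError("specificity undefined without bad segments")
    return (c.n_bad - c.n_accepted_bad) / c.n_bad


def segment_quality(segment: ImuSegment) -> tuple[float, str]:
    """RMSD (deg) of the estimated vs reference global joint angle + label."""
    rel = relative_orientation_series(segment.ahrs_prox, segment.ahrs_dist)
    est_angle = global_motion_angle(express_relative_to_initial(rel))
    ref_angle = global_motion_angle(express_relative_to_initial(segment.ref))
    rmsd = rmsd_deg(est_angle, ref_angle)
    return rmsd, label_from_rmsd(rmsd).category


def build_segment_table(
    dataset,
    target_hz: float = 100.0,
    max_lag: int = 100,
    mag_reference: float = 1.0,
) -> pd.DataFrame:
    """Prep every trial and emit one row per joint-segment.

    Columns: participant, trial_id, speed, phase, joint, f1..f16, rmsd,
    label.  f16 uses the previous phase of the same joint within the trial
    (first phase falls back to f15).
    """
    anns_by_trial: dict[str, list] = {}
    for ann in dataset.annotations:
        anns_by_trial.setdefault(ann.trial_id, []).append(ann)
    rows = []
    for trial in dataset.trials:
        prepared = prepare_trial(
            trial.trial_id, trial.participant, trial.raw, trial.ahrs,
            trial.ref, target_hz=target_hz, max_lag=max_lag,
        )
        segments = slice_segments(prepared, anns_by_trial[trial.trial_id])
        previous: dict[str, ImuSegment] = {}
        for seg in segments:
            feats = extract_features(seg, previous.get(seg.joint), mag_reference)
            previous[seg.joint] = seg
            rmsd, label = segment_quality(seg)
            row = {
                "participant": trial.participant,
                "trial_id": trial.trial_id,
                "speed": getattr(trial, "speed", ""),
                "phase": seg.phase,
                "joint": seg.joint,
            }
            row.update(dict(zip(FEATURE_NAMES, feats)))
            row["rmsd"] = rmsd
            row["label"] = label
            rows.append(row)
    return pd.DataFrame(rows)


def _pooled_phase(phase: str) -> str:
    return "walk" if phase in ("walk1", "walk2") else phase


def pre_post_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(task, joint) counts and mean (SD) RMSD before/after clean-up.

    Requires columns phase, joint, rmsd, label, accepted.  The two walking
    bouts are pooled into a single "walk" row.
    """
    required = {"phase", "joint", "rmsd", "label", "accepted"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    df = table.assign(task=table["phase"].map(_pooled_phase))
    out = []
    for task in _TABLE_PHASES:
        for joint in JOINTS:
            cell = df[(df["task"] == task) & (df["joint"] == joint)]
            if cell.empty:
                continue
            kept = cell[cell["accepted"]]
            out.append(
                {
                    "task": task,
                    "joint": joint,
                    "n_total": len(cell),
                    "n_good": int((cell["label"] == "good").sum()),
                    "rmsd_mean": cell["rmsd"].mean(),
                    "rmsd_sd": cell["rmsd"].std(ddof=0),
                    "n_accepted": len(kept),
                    "rmsd_accepted_mean": kept["rmsd"].mean() if len(kept) else np.nan,
                    "rmsd_accepted_sd": kept["rmsd"].std(ddof=0) if len(kept) else np.nan,
                }
            )
    return pd.DataFrame(out)


def label_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Per-joint label fractions before and (if available) after clean-up."""
    rows = []
    for joint in JOINTS:
        sub = table[table["joint"] == joint]
        if sub.empty:
            continue
        row = {"joint": joint, "n": len(sub)}
        for cat in ("good", "tolerable", "bad"):
            row[f"{cat}_frac"] = float((sub["label"] == cat).mean())
        if "accepted" in sub.columns:
            kept = sub[sub["accepted"]]
            row["n_accepted"] = len(kept)
            for cat in ("good", "tolerable", "bad"):
                row[f"{cat}_frac_post"] = (
                    float((kept["label"] == cat).mean()) if len(kept) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _assert_no_leak(
    rows: pd.DataFrame, allowed_participants: Iterable[int]
) -> None:
    allowed = set(allowed_participants)
    seen = set(rows["participant"].unique())
    extra = seen - allowed
    if extra:
        raise SplitLeakError(
            f"training rows include validation participants {sorted(extra)}"
        )


@dataclass
class PipelineResult:
    table: pd.DataFrame
    net: NetworkParams
    normalizer: FeatureNormalizer
    gains: Mapping[str, float]
    l2: float
    accept_mass: float
    train_participants: list[int]
    val_participants: list[int]
    training_report: TrainingReport
    metrics: dict[str, float]
    qc_table: pd.DataFrame
    distribution: pd.DataFrame
    train_config: TrainingConfig = field(default=None)


def _metric_pair(rows: pd.DataFrame) -> tuple[float, float]:
    counts = confusion_from(rows["label"].tolist(), rows["accepted"].tolist())
    sens = sensitivity(counts) if counts.n_good else float("nan")
    spec = specificity(counts) if counts.n_bad else float("nan")
    return sens, spec


def _select_hyperparams(
    table: pd.DataFrame,
    train_participants: list[int],
    base_cfg: TrainingConfig,
    l2_grid: Sequence[float],
    accept_mass_grid: Sequence[float],
) -> tuple[float, float]:
    """Pick the L2 penalty and the gain operating point on an inner fold.

    The network is trained repeatedly on the inner-training participants
    and scored by min(sensitivity, specificity) on the inner-validation
    participants — the balance criterion the training loop is judged by.
    Explicit gains in the config bypass the accept-mass search.
    """
    if base_cfg.gains is not None:
        accept_mass_grid = (0.5,)
    if len(l2_grid) == 1 and len(accept_mass_grid) == 1:
        return float(l2_grid[0]), float(accept_mass_grid[0])
    n_inner = max(1, len(train_participants) // 3)
    inner_val = set(train_participants[-n_inner:])
    inner_train = [p for p in train_participants if p not in inner_val]
    tr = table[table["participant"].isin(inner_train)]
    va = table[table["participant"].isin(inner_val)]
    if tr.empty or va.empty:
        return float(l2_grid[len(l2_grid) // 2]), float(accept_mass_grid[0])
    norm = FeatureNormalizer().fit(tr[list(FEATURE_NAMES)].to_numpy())
    Xtr = norm.transform(tr[list(FEATURE_NAMES)].to_numpy())
    Xva = norm.transform(va[list(FEATURE_NAMES)].to_numpy())
    labels = tr["label"].tolist()
    best = (float(l2_grid[0]), float(accept_mass_grid[0]))
    best_score = -np.inf
    for mass in accept_mass_grid:
        gains = base_cfg.gains if base_cfg.gains is not None else balanced_gains(
            labels, accept_mass=float(mass)
        )
        for l2 in l2_grid:
            cfg = TrainingConfig(
                seed=base_cfg.seed, learning_rate=base_cfg.learning_rate,
                max_epochs=base_cfg.max_epochs, l2=float(l2),
                gains=gains, tol=base_cfg.tol,
            )
            net, _ = train(Xtr, labels, cfg)
            va_rows = va.assign(accepted=predict_accept(net, Xva))
            sens, spec = _metric_pair(va_rows)
            score = np.nanmin([sens, spec])
            if score > best_score + 1e-12:
                best_score = score
                best = (float(l2), float(mass))
    return best


def run_pipeline(
    dataset,
    split_seed: int = 0,
    train_config: TrainingConfig | None = None,
    l2_grid: Sequence[float] = (1e-4, 1e-3, 1e-2),
    accept_mass_grid: Sequence[float] = (0.5, 0.6, 0.7),
    target_hz: float = 100.0,
    max_lag: int = 100,
    mag_reference: float = 1.0,
) -> PipelineResult:
    """End-to-end run: prep, label, featurize, train, evaluate held-out.

    ``dataset`` is a :class:`~imu_qc.synthetic.SyntheticDataset` or a cohort
    directory path.  Participants are shuffled with ``split_seed`` and split
    50/50; normalization statistics, class gains and the network are fitted
    on the training half only.
    """
    if isinstance(dataset, (str, Path)):
        from .io import load_dataset

        dataset = load_dataset(dataset)
    table = build_segment_table(
        dataset, target_hz=target_hz, max_lag=max_lag, mag_reference=mag_reference
    )

    participants = sorted(table["participant"].unique())
    perm = np.random.default_rng(split_seed).permutation(len(participants))
    half = len(participants) // 2
    train_p = [participants[i] for i in perm[:half]]
    val_p = [participants[i] for i in perm[half:]]

    train_rows = table[table["participant"].isin(train_p)]
    _assert_no_leak(train_rows, train_p)

    base_cfg = train_config or TrainingConfig()
    l2, accept_mass = _select_hyperparams(
        train_rows, train_p, base_cfg, l2_grid, accept_mass_grid
    )
    cfg = TrainingConfig(
        seed=base_cfg.seed, learning_rate=base_cfg.learning_rate,
        max_epochs=base_cfg.max_epochs, l2=l2, gains=base_cfg.gains,
        tol=base_cfg.tol,
    )

    normalizer = FeatureNormalizer().fit(train_rows[list(FEATURE_NAMES)].to_numpy())
    X_train = normalizer.transform(train_rows[list(FEATURE_NAMES)].to_numpy())
    gains = dict(cfg.gains) if cfg.gains is not None else balanced_gains(
        train_rows["label"].tolist(), accept_mass=accept_mass
    )
    cfg.gains = gains
    net, training_report = train(X_train, train_rows["label"].tolist(), cfg)

    X_all = normalizer.transform(table[list(FEATURE_NAMES)].to_numpy())
    table = table.assign(accepted=predict_accept(net, X_all))
    val_rows = table[table["participant"].isin(val_p)]
    train_rows = table[table["participant"].isin(train_p)]

    tr_sens, tr_spec = _metric_pair(train_rows)
    va_sens, va_spec = _metric_pair(val_rows)
    metrics = {
        "training_sensitivity": tr_sens,
        "training_specificity": tr_spec,
        "validation_sensitivity": va_sens,
        "validation_specificity": va_spec,
    }

    return PipelineResult(
        table=table,
        net=net,
        normalizer=normalizer,
        gains=gains,
        l2=l2,
        accept_mass=accept_mass,
        train_participants=train_p,
        val_participants=val_p,
        training_report=training_report,
        metrics=metrics,
        qc_table=pre_post_table(val_rows),
        distribution=label_distribution(val_rows),
        train_config=cfg,
    )
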