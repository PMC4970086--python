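"""The 16-6-1 feedforward quality-control classifier.

A single hidden layer of six tanh units feeding one tanh output keeps the
model small enough not to overfit a few thousand segments while still
capturing interactions between the environment and motion features.  The
accept target is +1 for *good* segments and -1 for *tolerable*/*bad* ones;
class imbalance is handled by per-category error gains in a weighted
sum-of-squared-errors loss,

    L = sum_i g(c_i) (s_i - y_i)^2 + lambda ||W||^2,

with an L2 penalty on the weights (not the biases).  Training is full-batch
gradient backpropagation with a bold-driver step size: steps that would
increase the loss are rejected and the step size halved, which makes the
loss curve monotone non-increasing and the whole procedure deterministic
for a fixed seed.  A segment is accepted iff the output score is strictly
positive (a score of exactly zero is conservatively rejected).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateTrainingError
from .features import FeatureNormalizer, N_FEATURES
from .orientation import CATEGORIES

__all__ = [
    "NetworkParams",
    "TrainingConfig",
    "TrainingReport",
    "init_network",
    "forward",
    "predict_accept",
    "balanced_gains",
    "weighted_sse",
    "train",
    "save_model",
    "load_model",
]


@dataclass
class NetworkParams:
    """Weights and biases of the 16-6-1 network."""

    w_hidden: np.ndarray  # (n_hidden, n_inputs)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray     # (n_hidden,)
    b_out: float

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.w_hidden.copy(), self.b_hidden.copy(), self.w_out.copy(),
            float(self.b_out),
        )


@dataclass
class TrainingConfig:
    seed: int = 0
    learning_rate: float = 1e-4
    max_epochs: int = 8000
    l2: float = 1e-3
    #: per-category error gains; None -> balanced N/(3 N_class)
    gains: Mapping[str, float] | None = None
    #: stop when the relative loss improvement stays below this
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be positive")
        if self.gains is not None and any(g <= 0 for g in self.gains.values()):
            raise ValueError("class gains must be positive")


@dataclass
class TrainingReport:
    final_sse: float
    epochs: int
    sensitivity: float
    specificity: float
    loss_curve: np.ndarray = field(repr=False, default=None)


#: default initialization scale: weights uniform in [-scale, scale]
INIT_SCALE = 0.5


def init_network(
    seed: int, n_inputs: int = N_FEATURES, n_hidden: int = 6,
    scale: float = INIT_SCALE,
) -> NetworkParams:
    """Small symmetric random weights from a seeded generator."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        w_hidden=rng.uniform(-scale, scale, size=(n_hidden, n_inputs)),
        b_hidden=rng.uniform(-scale, scale, size=n_hidden),
        w_out=rng.uniform(-scale, scale, size=n_hidden),
        b_out=float(rng.uniform(-scale, scale)),
    )


def forward(net: NetworkParams, x: np.ndarray) -> np.ndarray | float:
    """Network score(s) in (-1, 1) for input vector(s)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != net.n_inputs:
        raise ValueError(
            f"expected {net.n_inputs} inputs, got {X.shape[1]}"
        )
    h = np.tanh(X @ net.w_hidden.T + net.b_hidden)
    s = np.tanh(h @ net.w_out + net.b_out)
    return float(s[0]) if single else s


def predict_accept(net: NetworkParams, x: np.ndarray) -> bool | np.ndarray:
    """Accept iff the score is strictly positive."""
    s = forward(net, x)
    if np.isscalar(s):
        return bool(s > 0.0)
    return s > 0.0


def balanced_gains(
    labels: Sequence[str], accept_mass: float = 0.5
) -> dict[str, float]:
    """Per-category error gains balancing the accept/reject sides.

    With a single binary accept target, "balancing" means the accepted
    category (*good*, target +1) and the rejected categories (*tolerable*
    and *bad*, target -1) contribute a fixed split of the total error
    mass: good segments carry ``accept_mass * N / N_good`` and the reject
    side shares the remaining mass uniformly, so rarer categories are
    automatically worth more per segment.  ``accept_mass`` sets the
    sensitivity/specificity operating point (0.5 = symmetric); the
    pipeline selects it on an inner training fold.  All three gains remain
    individually overridable via TrainingConfig.
    """
    if not 0.0 < accept_mass < 1.0:
        raise ValueError("accept_mass must be in (0, 1)")
    labels = list(labels)
    n = len(labels)
    gains: dict[str, float] = {}
    n_good = labels.count("good")
    n_reject = sum(labels.count(c) for c in CATEGORIES if c != "good")
    if n_good:
        gains["good"] = accept_mass * n / n_good
    for cat in ("tolerable", "bad"):
        if labels.count(cat):
            gains[cat] = (1.0 - accept_mass) * n / n_reject
    return gains


def _targets_weights(
    labels: Sequence[str], gains: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([1.0 if lab == "good" else -1.0 for lab in labels])
    w = np.array([gains[lab] for lab in labels])
    return y, w


def weighted_sse(
    net: NetworkParams, X: np.ndarray, y: np.ndarray, w: np.ndarray,
    l2: float,
) -> float:
    """The training objective at the given parameters."""
    s = forward(net, X)
    penalty = l2 * (np.sum(net.w_hidden**2) + np.sum(net.w_out**2))
    return float(np.sum(w * (s - y) ** 2) + penalty)


def _loss_grad(net: NetworkParams, X, y, w, l2):
    h = np.tanh(X @ net.w_hidden.T + net.b_hidden)
    s = np.tanh(h @ net.w_out + net.b_out)
    e = s - y
    loss = float(np.sum(w * e * e) + l2 * (np.sum(net.w_hidden**2) + np.sum(net.w_out**2)))
    ds = 2.0 * w * e * (1.0 - s * s)           # (n,)
    g_wout = h.T @ ds + 2.0 * l2 * net.w_out   # (n_hidden,)
    g_bout = float(np.sum(ds))
    dh = np.outer(ds, net.w_out) * (1.0 - h * h)
    g_whid = dh.T @ X + 2.0 * l2 * net.w_hidden
    g_bhid = dh.sum(axis=0)
    return loss, (g_whid, g_bhid, g_wout, g_bout)


def train(
    X: np.ndarray,
    labels: Sequence[str],
    cfg: TrainingConfig | None = None,
) -> tuple[NetworkParams, TrainingReport]:
    """Fit the classifier on normalized features and quality categories.

    Returns the trained parameters and a report with the final weighted SSE,
    the number of epochs run and the training-set sensitivity/specificity.
    """
    from .report import ConfusionCounts, confusion_from, sensitivity, specificity

    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=float)
    labels = [lab.category if hasattr(lab, "category") else str(lab) for lab in labels]
    n_good = labels.count("good")
    if n_good == 0 or n_good == len(labels):
        raise DegenerateTrainingError(
            "training set must contain both good and non-good examples"
        )
    gains = dict(cfg.gains) if cfg.gains is not None else balanced_gains(labels)
    missing = set(labels) - set(gains)
    if missing:
        raise ValueError(f"no error gain configured for categories {sorted(missing)}")
    y, w = _targets_weights(labels, gains)

    net = init_network(cfg.seed, n_inputs=X.shape[1])
    lr = cfg.learning_rate
    loss, grads = _loss_grad(net, X, y, w, cfg.l2)
    losses = [loss]
    epochs = 0
    for _ in range(cfg.max_epochs):
        trial = NetworkParams(
            net.w_hidden - lr * grads[0],
            net.b_hidden - lr * grads[1],
            net.w_out - lr * grads[2],
            net.b_out - lr * grads[3],
        )
        new_loss, new_grads = _loss_grad(trial, X, y, w, cfg.l2)
        epochs += 1
        if new_loss <= loss:
            improvement = loss - new_loss
            net, loss, grads = trial, new_loss, new_grads
            lr *= 1.1
            losses.append(loss)
            if improvement < cfg.tol * max(1.0, loss):
                break
        else:
            lr *= 0.5
            losses.append(loss)
            if lr < 1e-16:
                break

    accepted = predict_accept(net, X)
    counts = confusion_from(labels, accepted)
    sens = sensitivity(counts) if counts.n_good else float("nan")
    spec = specificity(counts) if counts.n_bad else float("nan")
    report = TrainingReport(
        final_sse=loss, epochs=epochs, sensitivity=sens, specificity=spec,
        loss_curve=np.asarray(losses),
    )
    return net, report


def _config_hash(cfg: TrainingConfig) -> str:
    payload = {k: (dict(v) if isinstance(v, Mapping) else v)
               for k, v in asdict(cfg).items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def save_model(
    path: str | Path,
    net: NetworkParams,
    normalizer: FeatureNormalizer,
    gains: Mapping[str, float],
    cfg: TrainingConfig,
) -> None:
    """Persist architecture, weights, normalization and training metadata."""
    doc = {
        "architecture": [net.n_inputs, len(net.b_hidden), 1],
        "w_hidden": net.w_hidden.tolist(),
        "b_hidden": net.b_hidden.tolist(),
        "w_out": net.w_out.tolist(),
        "b_out": net.b_out,
        "normalizer": normalizer.to_dict(),
        "gains": dict(gains),
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> tuple[NetworkParams, FeatureNormalizer, dict]:
    doc = json.loads(Path(path).read_text())
    net = NetworkParams(
        w_hidden=np.asarray(doc["w_hidden"], dtype=float),
        b_hidden=np.asarray(doc["b_hidden"], dtype=float),
        w_out=np.asarray(doc["w_out"], dtype=float),
        b_out=float(doc["b_out"]),
    )
    normalizer = FeatureNormalizer.from_dict(doc["normalizer"])
    meta = {k: doc[k] for k in ("architecture", "gains", "seed", "config_hash")}
    return net, normalizer, meta
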