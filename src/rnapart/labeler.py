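"""The windowed exterior-loop labeler and its training regime.

The network maps a one-hot encoded window (5 x L) to a per-position
probability of the base lying in an exterior loop.  It is built from
four blocks: a 4-layer 1D-CNN (kernel ``K``, ``C`` channels, relu), a
single bidirectional LSTM (``U`` units per direction) followed by batch
normalization, a 2-layer ResNet of position-wise FC layers (width
``N``, relu, shortcut joining the two FC outputs) followed by batch
normalization, and a 2-node softmax output per position.  Dropout
(default rate 0.1) acts inside the conv/LSTM/ResNet blocks, and
padding positions are masked out of every layer's effective input, so
predictions are invariant to whatever symbol sits under the padding.

Training minimizes masked cross-entropy with Adam and early stopping
(default patience 10, best-epoch weights restored).  Transfer training
runs the same scheme twice: first on a large coarse (noisy-label)
corpus, then — from the stage-1 weights, with identical
hyper-parameters, no freezing and no learning-rate drop — on the
smaller accurate corpus.  Hyper-parameters ``K, C, U, N`` are searched
with a sequential model-based (Gaussian-process, expected-improvement)
optimizer, and the top models by validation MCC form an ensemble whose
prediction is the mean of the member probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .metrics import base_confusion, compute_metrics
from .windows import WindowSet, encode_window_set, make_windows, stitch_predictions

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "WindowDataset",
    "Labeler",
    "LabelerEnsemble",
    "build_model",
    "train",
    "transfer_train",
    "tune_hyperparameters",
    "ensemble_predict",
    "predict_labels",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    K: conv kernel size (odd); C: conv channels; U: LSTM units per
    direction; N: ResNet FC width; L: window length; dropout rate.
    """

    K: int = 5
    C: int = 32
    U: int = 32
    N: int = 64
    L: int = 200
    dropout: float = 0.1

    def __post_init__(self) -> None:
        for name in ("K", "C", "U", "N", "L"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
            setattr(self, name, int(v))
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    monitor: str = "val_mcc"  # or "val_loss"

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("val_mcc", "val_loss"):
            raise ValueError("monitor must be 'val_mcc' or 'val_loss'")


@dataclass
class WindowDataset:
    """Encoded windows (n, 5, L), labels (n, L), masks (n, L)."""

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.mask)):
            raise ValueError("x, y, mask must have equal first dimensions")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def window_length(self) -> int:
        return self.x.shape[2]

    def subset(self, idx) -> "WindowDataset":
        return WindowDataset(self.x[idx], self.y[idx], self.mask[idx])


class Labeler:
    """Per-position exterior-loop classifier over fixed-length windows."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        stack: list[nn.Layer] = [nn.MaskMul()]
        f_in = 5
        for _ in range(4):
            stack += [
                nn.Conv1D(f_in, c.C, c.K, rng),
                nn.ReLU(),
                nn.Dropout(c.dropout),
                nn.MaskMul(),
            ]
            f_in = c.C
        stack += [
            nn.BiLSTM(c.C, c.U, rng),
            nn.Dropout(c.dropout),
            nn.MaskMul(),
            nn.BatchNorm(2 * c.U),
            nn.ResNetLayer(2 * c.U, c.N, rng),
            nn.Dropout(c.dropout),
            nn.ResNetLayer(c.N, c.N, rng),
            nn.Dropout(c.dropout),
            nn.BatchNorm(c.N),
            nn.Dense(c.N, 2, rng),
        ]
        self.stack = stack

    # -- plumbing ----------------------------------------------------------

    def _set_mode(self, mask: np.ndarray, train: bool, rng) -> None:
        for layer in self.stack:
            layer.mask = mask
            layer.train = train
            layer.rng = rng

    def num_params(self) -> int:
        return sum(p.size for layer in self.stack for p in layer.params.values())

    def get_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for layer in self.stack:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, nn.BatchNorm):
                d["__running_mean"] = layer.running_mean.copy()
                d["__running_var"] = layer.running_var.copy()
            state.append(d)
        return state

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, d in zip(self.stack, state):
            for k in layer.params:
                layer.params[k][...] = d[k]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = d["__running_mean"]
                layer.running_var[...] = d["__running_var"]

    # -- forward / training steps -----------------------------------------

    def _forward(self, x: np.ndarray, mask: np.ndarray, train: bool, rng=None) -> np.ndarray:
        """Logits (B, L, 2) from encoded windows (B, 5, L)."""
        self._set_mode(np.asarray(mask, dtype=float), train, rng)
        h = np.transpose(np.asarray(x, dtype=float), (0, 2, 1))
        for layer in self.stack:
            h = layer.forward(h)
        return h

    def predict_proba(self, x: np.ndarray, mask: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-1 (exterior) probability per window position, eval mode."""
        out = np.empty(mask.shape, dtype=float)
        for s in range(0, len(x), batch_size):
            sl = slice(s, s + batch_size)
            logits = self._forward(x[sl], mask[sl], train=False)
            out[sl] = nn.softmax(logits)[:, :, 1]
        return out

    def train_step(self, x, y, mask, rng) -> float:
        logits = self._forward(x, mask, train=True, rng=rng)
        loss, dlogits, _ = nn.softmax_cross_entropy(logits, np.asarray(y, dtype=int), mask)
        grad = dlogits
        for layer in reversed(self.stack):
            grad = layer.backward(grad)
        return loss


def build_model(config: ModelConfig, seed: int = 0) -> Labeler:
    """Construct an untrained labeler from an architecture config."""
    return Labeler(config, seed=seed)


def _validation_scores(labeler: Labeler, val: WindowDataset, batch_size: int) -> tuple[float, Optional[float]]:
    """(val cross-entropy, val base-level MCC) in eval mode."""
    losses = []
    weights = []
    preds = []
    for s in range(0, len(val), batch_size):
        sl = slice(s, s + batch_size)
        logits = labeler._forward(val.x[sl], val.mask[sl], train=False)
        loss, _, probs = nn.softmax_cross_entropy(logits, val.y[sl].astype(int), val.mask[sl])
        losses.append(loss)
        weights.append(val.mask[sl].sum())
        preds.append(probs[:, :, 1])
    w = np.asarray(weights, dtype=float)
    val_loss = float(np.average(losses, weights=w)) if w.sum() > 0 else 0.0
    prob = np.concatenate(preds)
    pred = (prob >= 0.5).astype(np.int8)
    counts = base_confusion(pred.ravel(), val.y.astype(np.int8).ravel(), val.mask.ravel())
    return val_loss, compute_metrics(counts).mcc


def train(
    labeler: Labeler,
    train_set: WindowDataset,
    val_set: WindowDataset,
    tc: TrainConfig,
) -> tuple[Labeler, list[dict]]:
    """Early-stopped Adam training on masked cross-entropy.

    Stops when the monitored validation metric has not improved for
    ``tc.patience`` epochs and restores the best-epoch weights.
    Returns the trained labeler and a per-epoch history.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train_set.window_length != labeler.config.L:
        raise ValueError(
            f"dataset window length {train_set.window_length} != model L {labeler.config.L}"
        )
    rng = np.random.default_rng(tc.seed)
    adam = nn.Adam(lr=tc.learning_rate)
    best_metric = -np.inf
    best_state = labeler.get_state()
    wait = 0
    history: list[dict] = []
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for s in range(0, len(order), tc.batch_size):
            idx = order[s : s + tc.batch_size]
            loss = labeler.train_step(train_set.x[idx], train_set.y[idx], train_set.mask[idx], rng)
            adam.step(labeler.stack)
            epoch_losses.append(loss)
        val_loss, val_mcc = _validation_scores(labeler, val_set, tc.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_mcc": val_mcc,
            }
        )
        if tc.monitor == "val_mcc":
            # undefined MCC (degenerate one-class predictions, common in
            # the first epochs) falls back to loss so training can leave
            # the degenerate regime; any defined MCC outranks it
            metric = val_mcc if val_mcc is not None else -1e6 - val_loss
        else:
            metric = -val_loss
        if metric > best_metric:
            best_metric = metric
            best_state = labeler.get_state()
            wait = 0
        else:
            wait += 1
            if wait >= tc.patience:
                break
    labeler.set_state(best_state)
    return labeler, history


def transfer_train(
    labeler: Labeler,
    coarse_train: WindowDataset,
    coarse_val: WindowDataset,
    accurate_train: WindowDataset,
    accurate_val: WindowDataset,
    tc: TrainConfig,
) -> tuple[Labeler, dict[str, list[dict]]]:
    """Two-stage training: pre-train on coarse, then trans-train on accurate.

    Stage 2 continues from the stage-1 weights with identical
    hyper-parameters (no layer freezing, no learning-rate drop); the
    optimizer state restarts.  An empty accurate set degenerates to
    pre-training only.
    """
    labeler, hist1 = train(labeler, coarse_train, coarse_val, tc)
    if len(accurate_train) == 0:
        return labeler, {"pretrain": hist1, "transtrain": []}
    labeler, hist2 = train(labeler, accurate_train, accurate_val, tc)
    return labeler, {"pretrain": hist1, "transtrain": hist2}


# ---------------------------------------------------------------------------
# hyper-parameter search

DEFAULT_SPACE = {"K": (3, 11), "C": (16, 128), "U": (16, 128), "N": (32, 256)}


def _sample_config(space: dict, rng: np.random.Generator, L: int, dropout: float) -> ModelConfig:
    vals = {}
    for name, (lo, hi) in space.items():
        v = int(rng.integers(lo, hi + 1))
        if name == "K" and v % 2 == 0:  # conv kernels must be odd
            v += 1 if v < hi else -1
        vals[name] = v
    return ModelConfig(L=L, dropout=dropout, **vals)


def _config_to_unit(cfg: ModelConfig, space: dict) -> list[float]:
    return [
        (getattr(cfg, name) - lo) / max(hi - lo, 1)
        for name, (lo, hi) in space.items()
    ]


def tune_hyperparameters(
    space: dict,
    budget: int,
    train_set: WindowDataset,
    val_set: WindowDataset,
    tc: TrainConfig,
    seed: int = 0,
    L: int | None = None,
    dropout: float = 0.1,
    n_init: int = 5,
) -> list[tuple[ModelConfig, Optional[float]]]:
    """Sequential model-based search over (K, C, U, N).

    The first ``n_init`` trials sample the space at random; later
    trials fit a Gaussian-process surrogate to the validation MCCs and
    pick the candidate with maximal expected improvement.  Returns all
    trials sorted by validation MCC, best first; fully reproducible
    under a fixed seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty search space")
    if L is None:
        L = train_set.window_length
    rng = np.random.default_rng(seed)
    trials: list[tuple[ModelConfig, Optional[float]]] = []
    X: list[list[float]] = []
    yv: list[float] = []
    for t in range(budget):
        if t < n_init or len(yv) < 2:
            cfg = _sample_config(space, rng, L, dropout)
        else:
            cfg = _propose_ei(space, rng, X, yv, L, dropout)
        model = build_model(cfg, seed=tc.seed)
        model, _ = train(model, train_set, val_set, tc)
        _, mcc = _validation_scores(model, val_set, tc.batch_size)
        trials.append((cfg, mcc))
        X.append(_config_to_unit(cfg, space))
        yv.append(mcc if mcc is not None else -1.0)
    trials.sort(key=lambda t: t[1] if t[1] is not None else -np.inf, reverse=True)
    return trials


def _propose_ei(space, rng, X, yv, L, dropout, n_candidates: int = 128) -> ModelConfig:
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True, random_state=0
    )
    gp.fit(np.asarray(X), np.asarray(yv))
    best = max(yv)
    cands = [_sample_config(space, rng, L, dropout) for _ in range(n_candidates)]
    Xc = np.asarray([_config_to_unit(c, space) for c in cands])
    mu, sd = gp.predict(Xc, return_std=True)
    sd = np.maximum(sd, 1e-9)
    z = (mu - best) / sd
    ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
    return cands[int(np.argmax(ei))]


# ---------------------------------------------------------------------------
# ensembling and label binarization


@dataclass
class LabelerEnsemble:
    """Mean-probability ensemble of trained labelers.

    ``selection`` records the metric each member scored when chosen
    (e.g. validation MCC).
    """

    members: list[Labeler]
    selection: list[Optional[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        Ls = {m.config.L for m in self.members}
        if len(Ls) != 1:
            raise ValueError(f"ensemble members have mismatched window lengths {Ls}")

    @property
    def window_length(self) -> int:
        return self.members[0].config.L

    def predict_window_probs(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        probs = [m.predict_proba(x, mask) for m in self.members]
        return np.mean(probs, axis=0)

    def predict_sequence(self, sequence: str, step: int | None = None) -> np.ndarray:
        """Per-base exterior probability for a full-length sequence.

        Defaults to half-overlapping inference windows (step = L // 2),
        averaging predictions on bases covered twice.
        """
        L = self.window_length
        if step is None:
            step = max(L // 2, 1)
        ws = make_windows(sequence, L=L, step=step)
        x, mask = encode_window_set(ws)
        return stitch_predictions(self.predict_window_probs(x, mask), ws)


def ensemble_predict(ensemble: LabelerEnsemble, window_set: WindowSet) -> np.ndarray:
    """Mean member probabilities stitched onto the parent sequence."""
    if window_set.window_length != ensemble.window_length:
        raise ValueError(
            f"window set L={window_set.window_length} != ensemble "
            f"L={ensemble.window_length}"
        )
    x, mask = encode_window_set(window_set)
    return stitch_predictions(ensemble.predict_window_probs(x, mask), window_set)


def predict_labels(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize per-base probabilities; ties at the threshold go to 1."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    probs = np.asarray(probabilities, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(labeler: Labeler, directory) -> None:
    """Write config manifest (JSON) plus weights (NPZ) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "config.json", "w") as fh:
        json.dump(asdict(labeler.config), fh, indent=2)
    flat = {}
    for li, d in enumerate(labeler.get_state()):
        for k, v in d.items():
            flat[f"{li}:{k}"] = v
    np.savez(directory / "weights.npz", **flat)


def load_checkpoint(directory) -> Labeler:
    directory = Path(directory)
    with open(directory / "config.json") as fh:
        cfg = ModelConfig(**json.load(fh))
    labeler = Labeler(cfg)
    data = np.load(directory / "weights.npz")
    state: list[dict[str, np.ndarray]] = [dict() for _ in labeler.stack]
    for key in data.files:
        li, name = key.split(":", 1)
        state[int(li)][name] = data[key]
    labeler.set_state(state)
    return labeler
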