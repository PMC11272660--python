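"""Trainable binary linear readout over encoder features.

The readout is a single linear unit (weights + bias) on the feature vector,
trained with SGD (classical momentum) on the binary cross-entropy-with-
logits loss.  Two protocols are supported:

- ``fixed``: a set number of epochs (default 10), each epoch resampling a
  fixed number of stimuli per class with replacement (default 1,500).
- ``earlystop``: up to 40 epochs with patience 5 on the fraction correct of
  a fixed validation set (80 + 80 canvases composed once), 400 resamples
  per class per epoch.

Every presented canvas is composed freshly (new scale, rotation, jitter,
and background realization), so the model effectively never sees the same
input twice — the extreme augmentation regime the encoders are evaluated
under.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compose import Condition, compose_canvas
from .filters import encode_raw
from .stimuli import Pool

__all__ = [
    "Readout", "TrainConfig", "init_readout", "resample_epoch", "train",
    "predict", "TrainingDiverged",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class Readout:
    """Weights and bias of the binary linear classifier."""

    weights: np.ndarray
    bias: float = 0.0
    epochs_trained: int = 0

    def logit(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights + self.bias


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the SGD training protocols."""

    protocol: str = "fixed"       # 'fixed' | 'earlystop'
    epochs: int = 10              # fixed protocol
    per_class: int = 1500         # resamples per class per epoch
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    shuffle: bool = True
    max_epochs: int = 40          # earlystop protocol
    patience: int = 5
    val_per_class: int = 80

    def __post_init__(self) -> None:
        if self.protocol not in ("fixed", "earlystop"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if min(self.epochs, self.per_class, self.batch_size,
               self.max_epochs, self.patience, self.val_per_class) < 1:
            raise ValueError("all counts must be positive")
        if self.lr < 0 or not 0.0 <= self.momentum < 1.0:
            raise ValueError("invalid lr/momentum")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


def init_readout(n_inputs: int, rng: np.random.Generator,
                 dtype=np.float64) -> Readout:
    """Kaiming-uniform initialization: w ~ U(-1/sqrt(n), 1/sqrt(n)), b = 0."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    bound = 1.0 / np.sqrt(n_inputs)
    return Readout(weights=rng.uniform(-bound, bound, n_inputs).astype(dtype),
                   bias=0.0)


def resample_epoch(pool: Pool, per_class: int,
                   rng: np.random.Generator) -> list:
    """Draw per_class stimuli per class with replacement.

    Returns a list of (stimulus, label) with label 1 for the positive class
    (faces) and 0 for the negative class.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    ip = rng.integers(0, len(pool.pos), per_class)
    ineg = rng.integers(0, len(pool.neg), per_class)
    return [(pool.pos[i], 1) for i in ip] + [(pool.neg[i], 0) for i in ineg]


def predict(r: Readout, features: np.ndarray):
    """1 (positive class) iff w.f + b > 0; ties go to the negative class."""
    z = np.asarray(features) @ r.weights + r.bias
    return (z > 0).astype(int)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _compose_features(items, bank_or_banks, condition, rng):
    """Compose each (stimulus, label) freshly and encode it.

    ``bank_or_banks`` may be a single FilterBank or a list; a list returns a
    list of feature matrices computed from a single shared canvas stream.
    """
    banks = bank_or_banks if isinstance(bank_or_banks, list) else [bank_or_banks]
    # banks sharing a kernel family and channel geometry share raw responses
    keys = [(b.model_kind == "lgn",
             tuple((c.wavelength, c.n, c.pad) for c in b.channels))
            for b in banks]
    feats = [np.empty((len(items), b.unit_count), dtype=b.dtype)
             for b in banks]
    labels = np.empty(len(items), dtype=banks[0].dtype)
    for i, (stim, lab) in enumerate(items):
        canvas = compose_canvas(stim, condition, rng, dtype=banks[0].dtype)
        raw_cache, patch_cache = {}, {}
        for j, b in enumerate(banks):
            if keys[j] not in raw_cache:
                raw_cache[keys[j]] = encode_raw(canvas, b, patch_cache)
            feats[j][i] = b.features(raw_cache[keys[j]])
        labels[i] = lab
    if isinstance(bank_or_banks, list):
        return feats, labels
    return feats[0], labels


def _sgd_epoch(readout, velocity, X, y, cfg, order):
    """One pass of minibatch SGD over pre-encoded features, in place."""
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        xb, yb = X[idx], y[idx]
        z = readout.logit(xb)
        if not np.all(np.isfinite(z)):
            raise TrainingDiverged("non-finite logits during training")
        g = (_sigmoid(z) - yb) / len(idx)
        gw = xb.T @ g
        gb = g.sum()
        velocity[0] = cfg.momentum * velocity[0] + gw
        velocity[1] = cfg.momentum * velocity[1] + gb
        readout.weights = readout.weights - cfg.lr * velocity[0]
        readout.bias = readout.bias - cfg.lr * velocity[1]


def fit_features(X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator,
                 init_rng: np.random.Generator | None = None) -> Readout:
    """Train a readout on a fixed feature matrix (no composition stream).

    Runs ``cfg.epochs`` shuffled passes of minibatch SGD over (X, y); used
    for feature-level experiments and diagnostics where the encoder is
    bypassed.
    """
    init_rng = init_rng if init_rng is not None else rng
    X = np.asarray(X)
    readout = init_readout(X.shape[1], init_rng, X.dtype)
    velocity = [np.zeros(X.shape[1], dtype=X.dtype), 0.0]
    y = np.asarray(y, dtype=X.dtype)
    for _ in range(cfg.epochs):
        order = (rng.permutation(len(y)) if cfg.shuffle
                 else np.arange(len(y)))
        _sgd_epoch(readout, velocity, X, y, cfg, order)
        readout.epochs_trained += 1
    return readout


def train(bank, train_pool: Pool, condition: Condition, cfg: TrainConfig,
          rng: np.random.Generator, val_pool: Pool | None = None,
          init_rng: np.random.Generator | None = None):
    """Train a readout for one bank (see :func:`train_multi` for several)."""
    outs = train_multi([bank], train_pool, condition, cfg, rng,
                       val_pool=val_pool, init_rng=init_rng)
    return outs[0]


def train_multi(banks: list, train_pool: Pool, condition: Condition,
                cfg: TrainConfig, rng: np.random.Generator,
                val_pool: Pool | None = None,
                init_rng: np.random.Generator | None = None) -> list:
    """Train one readout per bank on a shared freshly-composed canvas stream.

    Composition and resampling randomness comes from ``rng`` and is
    identical for every bank (the canvas stream does not depend on the
    model); weight initialization uses ``init_rng`` (defaults to ``rng``).
    Returns a list of trained :class:`Readout`.
    """
    init_rng = init_rng if init_rng is not None else rng
    readouts = [init_readout(b.unit_count, init_rng, b.dtype) for b in banks]
    velocities = [[np.zeros(b.unit_count, dtype=b.dtype), 0.0] for b in banks]

    if cfg.protocol == "earlystop":
        if val_pool is None:
            raise ValueError("earlystop protocol requires a validation pool")
        vp = min(cfg.val_per_class, len(val_pool.pos), len(val_pool.neg))
        vidx_p = rng.choice(len(val_pool.pos), vp, replace=False)
        vidx_n = rng.choice(len(val_pool.neg), vp, replace=False)
        vitems = ([(val_pool.pos[i], 1) for i in vidx_p]
                  + [(val_pool.neg[i], 0) for i in vidx_n])
        Xv, yv = _compose_features(vitems, banks, condition, rng)
        n_epochs = cfg.max_epochs
    else:
        n_epochs = cfg.epochs

    best = [-np.inf] * len(banks)
    stale = [0] * len(banks)
    done = [False] * len(banks)
    for _ in range(n_epochs):
        items = resample_epoch(train_pool, cfg.per_class, rng)
        X, y = _compose_features(items, banks, condition, rng)
        order = (rng.permutation(len(y)) if cfg.shuffle
                 else np.arange(len(y)))
        for j, b in enumerate(banks):
            if done[j]:
                continue
            _sgd_epoch(readouts[j], velocities[j], X[j], y, cfg, order)
            readouts[j].epochs_trained += 1
            if cfg.protocol == "earlystop":
                acc = float(np.mean(predict(readouts[j], Xv[j]) == yv))
                if acc > best[j]:
                    best[j], stale[j] = acc, 0
                else:
                    stale[j] += 1
                    if stale[j] >= cfg.patience:
                        done[j] = True
        if all(done):
            break
    return readouts
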