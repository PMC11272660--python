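"""Split/train/test orchestration, percent correct, d', and condition grids.

Each experiment repeat draws a fresh class-wise random split of the stimulus
pool (50/50, or 50/10/40 when a validation set is needed), trains a readout
on freshly-composed canvases from the training half, and evaluates a single
forward pass over resampled, freshly-composed canvases from the test half.
Repeats are seeded as base_seed + i with independent sub-streams for
splitting, weight initialization, and the resampling/composition stream, so
every run is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .compose import BackgroundSpec, Condition, NuisanceSpec
from .filters import FilterBank, build_bank
from .readout import Readout, TrainConfig, _compose_features, predict, \
    resample_epoch, train_multi
from .stimuli import Pool

DPRIME_CLIP = 5.15
RATE_CLAMP = 0.005  # symmetric ceiling: 2 * Z(0.995) = 5.15

__all__ = [
    "SplitPlan", "PerformanceRecord", "ConditionGrid", "make_split",
    "evaluate", "dprime", "run_grid", "records_to_frame", "DPRIME_CLIP",
]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint per-class index lists for train/validation/test."""

    scheme: str
    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray
    val_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    val_neg: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        for a, b, c in ((self.train_pos, self.val_pos, self.test_pos),
                        (self.train_neg, self.val_neg, self.test_neg)):
            parts = np.concatenate([a, b, c])
            if len(np.unique(parts)) != len(parts):
                raise ValueError("split index lists overlap")


@dataclass(frozen=True)
class PerformanceRecord:
    """Per-split performance for one model under one condition."""

    model_kind: str
    background: str
    scale_min: float
    rot_max: float
    repeat: int
    seed: int
    percent_correct: float
    hit_rate: float
    false_alarm_rate: float
    d_prime: float


@dataclass(frozen=True)
class ConditionGrid:
    """Cartesian grid of backgrounds x scale levels x rotation levels."""

    backgrounds: tuple = ("mid_gray",)
    scale_levels: tuple = (1.0, 0.7, 0.5)
    rot_levels: tuple = (0.0, 15.0, 45.0, 90.0, 180.0)
    n_repeats: int = 100

    def conditions(self):
        for bg in self.backgrounds:
            spec = bg if isinstance(bg, BackgroundSpec) else BackgroundSpec(bg)
            for s in self.scale_levels:
                for r in self.rot_levels:
                    yield Condition(background=spec,
                                    nuisance=NuisanceSpec(scale_min=s,
                                                          rot_max=r))


def make_split(n_per_class: int, scheme: str = "half",
               seed: int | np.random.Generator = 0) -> SplitPlan:
    """Uniformly random disjoint per-class partition.

    ``half``: 50/50 train/test.  ``tvt``: 50/10/40 train/validation/test.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if scheme == "half":
        if n_per_class < 2:
            raise ValueError("need at least 2 stimuli per class")
        cuts = (n_per_class // 2, n_per_class // 2)
    elif scheme == "tvt":
        if n_per_class < 10:
            raise ValueError("need at least 10 stimuli per class for tvt")
        n_train = n_per_class // 2
        n_val = n_per_class // 10
        cuts = (n_train, n_val)
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")

    def _split(perm):
        a = perm[:cuts[0]]
        b = perm[cuts[0]:cuts[0] + (cuts[1] if scheme == "tvt" else 0)]
        c = perm[cuts[0] + len(b):]
        return a, b, c

    tp, vp, sp = _split(rng.permutation(n_per_class))
    tn, vn, sn = _split(rng.permutation(n_per_class))
    return SplitPlan(scheme=scheme, train_pos=tp, train_neg=tn,
                     test_pos=sp, test_neg=sn, val_pos=vp, val_neg=vn)


def dprime(hit_rate: float, false_alarm_rate: float) -> float:
    """Sensitivity index d' = Z(hit) - Z(false alarm), clipped at +/-5.15.

    Rates are clamped to [0.005, 0.995] so the symmetric 99.5%-correct
    ceiling is exactly 5.15.
    """
    h = float(np.clip(hit_rate, RATE_CLAMP, 1.0 - RATE_CLAMP))
    f = float(np.clip(false_alarm_rate, RATE_CLAMP, 1.0 - RATE_CLAMP))
    d = norm.ppf(h) - norm.ppf(f)
    return float(np.clip(d, -DPRIME_CLIP, DPRIME_CLIP))


def _subset_pool(pool: Pool, idx_pos, idx_neg) -> Pool:
    return Pool(pos=[pool.pos[i] for i in idx_pos],
                neg=[pool.neg[i] for i in idx_neg],
                pos_label=pool.pos_label, neg_label=pool.neg_label)


def _scores(readout: Readout, X: np.ndarray, y: np.ndarray):
    pred = predict(readout, X)
    hit = float(np.mean(pred[y == 1] == 1))
    fa = float(np.mean(pred[y == 0] == 1))
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    pc = (hit * n1 + (1.0 - fa) * n0) / (n1 + n0)
    return pc, hit, fa


def evaluate(readout: Readout, bank: FilterBank, test_pool: Pool,
             condition: Condition, rng: np.random.Generator,
             per_class: int = 1500) -> dict:
    """Single-pass evaluation on resampled, freshly-composed test canvases.

    Returns a dict with percent_correct, hit_rate, false_alarm_rate, d_prime.
    """
    items = resample_epoch(test_pool, per_class, rng)
    X, y = _compose_features(items, bank, condition, rng)
    pc, hit, fa = _scores(readout, X, y)
    return {"percent_correct": pc, "hit_rate": hit, "false_alarm_rate": fa,
            "d_prime": dprime(hit, fa)}


def _run_condition_repeat(banks: dict, pool: Pool, condition: Condition,
                          cfg: TrainConfig, seed: int, repeat: int,
                          test_per_class: int):
    """One split/train/test run of all models on a shared canvas stream."""
    ss = np.random.SeedSequence(seed)
    split_rng, init_rng, stream_rng = (np.random.default_rng(s)
                                       for s in ss.spawn(3))
    scheme = "tvt" if cfg.protocol == "earlystop" else "half"
    n_per_class = min(len(pool.pos), len(pool.neg))
    plan = make_split(n_per_class, scheme, split_rng)
    train_pool = _subset_pool(pool, plan.train_pos, plan.train_neg)
    test_pool = _subset_pool(pool, plan.test_pos, plan.test_neg)
    val_pool = (None if scheme == "half"
                else _subset_pool(pool, plan.val_pos, plan.val_neg))

    kinds = list(banks)
    readouts = train_multi([banks[k] for k in kinds], train_pool, condition,
                           cfg, stream_rng, val_pool=val_pool,
                           init_rng=init_rng)

    items = resample_epoch(test_pool, test_per_class, stream_rng)
    X, y = _compose_features(items, [banks[k] for k in kinds], condition,
                             stream_rng)
    records = []
    for j, k in enumerate(kinds):
        pc, hit, fa = _scores(readouts[j], X[j], y)
        records.append(PerformanceRecord(
            model_kind=k, background=condition.background.kind,
            scale_min=condition.nuisance.scale_min,
            rot_max=condition.nuisance.rot_max, repeat=repeat, seed=seed,
            percent_correct=pc, hit_rate=hit, false_alarm_rate=fa,
            d_prime=dprime(hit, fa)))
    return records, readouts


def records_to_frame(records: list) -> pd.DataFrame:
    cols = ["model_kind", "background", "scale_min", "rot_max", "repeat",
            "seed", "percent_correct", "hit_rate", "false_alarm_rate",
            "d_prime"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def run_grid(grid: ConditionGrid, model_kinds, pool: Pool, base_seed: int,
             cfg: TrainConfig | None = None, test_per_class: int = 1500,
             canvas_size: int = 340, store_weights: bool = False,
             dtype=np.float64):
    """Repeated split/train/test runs over a condition grid.

    All requested model kinds are trained per repeat on a shared composed
    canvas stream (composition does not depend on the model).  Returns a
    tidy DataFrame of per-repeat records; with ``store_weights=True`` also
    returns ``{(model_kind, background, scale_min, rot_max):
    (n_repeats, n_units) weight matrix}`` for consistency-lesion analyses.
    """
    cfg = cfg or TrainConfig()
    banks = {k: build_bank(k, canvas_size, dtype=dtype) for k in model_kinds}
    records, weights = [], {}
    for condition in grid.conditions():
        per_run_w = {k: [] for k in banks}
        for rep in range(grid.n_repeats):
            recs, readouts = _run_condition_repeat(
                banks, pool, condition, cfg, base_seed + rep, rep,
                test_per_class)
            records.extend(recs)
            if store_weights:
                for k, r in zip(banks, readouts):
                    per_run_w[k].append(r.weights.copy())
        if store_weights:
            for k in banks:
                key = (k, condition.background.kind,
                       condition.nuisance.scale_min,
                       condition.nuisance.rot_max)
                weights[key] = np.stack(per_run_w[k])
    df = records_to_frame(records)
    return (df, weights) if store_weights else df
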