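"""The packaged synthetic benchmark: fixed conditions, scales, and seeds.

The reference experiments run 100 train/test splits with 1,500 resamples
per class per epoch over a ~1,700-image-per-class pool; at that scale a
single condition costs hours on one CPU.  The packaged benchmark keeps the
protocol (fresh composition per presentation, SGD readout, repeated random
splits, median summaries) but runs at reduced scale — a 60-per-class
synthetic pool, a few hundred resamples per class per epoch, and around
ten repeats — with single-precision encoding for throughput.  The three
standing experiments:

- ``run_ordering``: all four encoders on a mid-gray background with no
  scale/rotation variation (jitter always on), the cell used to compare
  model families.
- ``run_rotation_trend``: the V1-simple encoder across rotation levels
  {0, 15, 45, 90, 180} degrees at 50% scale variation on mid-gray.
- ``run_lesion_reference``: the V1-simple encoder at 50% scale, 45 degree
  rotation on blurred scenes — the condition used for channel and
  weight-consistency lesions — storing per-run weights.

Repeat i of every experiment uses seed base_seed + i (shared splits across
conditions act as common random numbers, tightening between-condition
comparisons).
"""

from __future__ import annotations

import numpy as np

from .compose import BackgroundSpec, Condition, NuisanceSpec
from .evaluate import ConditionGrid, run_grid
from .readout import TrainConfig
from .stimuli import Pool, generate_pool

BENCH_SEED = 2025
POOL_PER_CLASS = 120

ORDERING_MODELS = ("simple", "complex", "linear", "lgn")
ORDERING_CFG = TrainConfig(epochs=6, per_class=200, batch_size=2)
ORDERING_TEST_PER_CLASS = 250
ORDERING_REPEATS = 8

TREND_ROTATIONS = (0.0, 15.0, 45.0, 90.0, 180.0)
TREND_SCALE_MIN = 0.5
TREND_CFG = TrainConfig(epochs=4, per_class=150, batch_size=4)
TREND_TEST_PER_CLASS = 150
TREND_REPEATS = 6

LESION_CONDITION = Condition(BackgroundSpec("scene_blurred"),
                             NuisanceSpec(scale_min=0.5, rot_max=45.0))
LESION_CFG = TrainConfig(epochs=4, per_class=150, batch_size=4)
LESION_TEST_PER_CLASS = 150
LESION_REPEATS = 6

__all__ = [
    "BENCH_SEED", "POOL_PER_CLASS", "ORDERING_MODELS", "ORDERING_CFG",
    "ORDERING_TEST_PER_CLASS", "ORDERING_REPEATS", "TREND_ROTATIONS",
    "TREND_SCALE_MIN", "TREND_CFG", "TREND_TEST_PER_CLASS", "TREND_REPEATS",
    "LESION_CONDITION", "LESION_CFG", "LESION_TEST_PER_CLASS",
    "LESION_REPEATS", "benchmark_pool", "run_ordering", "run_rotation_trend",
    "run_lesion_reference",
]


def benchmark_pool(seed: int = BENCH_SEED, n_per_class: int = POOL_PER_CLASS
                   ) -> Pool:
    """The luminance-matched face/non-face pool used by the benchmark."""
    return generate_pool(n_per_class, seed=seed)


def run_ordering(pool: Pool, base_seed: int = BENCH_SEED,
                 repeats: int = ORDERING_REPEATS,
                 models=ORDERING_MODELS):
    """Model-family comparison cell: mid-gray, no scale/rotation variation."""
    grid = ConditionGrid(backgrounds=("mid_gray",), scale_levels=(1.0,),
                         rot_levels=(0.0,), n_repeats=repeats)
    return run_grid(grid, list(models), pool, base_seed, cfg=ORDERING_CFG,
                    test_per_class=ORDERING_TEST_PER_CLASS, dtype=np.float32)


def run_rotation_trend(pool: Pool, base_seed: int = BENCH_SEED,
                       repeats: int = TREND_REPEATS,
                       rotations=TREND_ROTATIONS):
    """V1-simple across rotation levels at 50% scale variation, mid-gray."""
    grid = ConditionGrid(backgrounds=("mid_gray",),
                         scale_levels=(TREND_SCALE_MIN,),
                         rot_levels=tuple(rotations), n_repeats=repeats)
    return run_grid(grid, ["simple"], pool, base_seed, cfg=TREND_CFG,
                    test_per_class=TREND_TEST_PER_CLASS, dtype=np.float32)


def run_lesion_reference(pool: Pool, base_seed: int = BENCH_SEED,
                         repeats: int = LESION_REPEATS):
    """Full V1-simple runs at the lesion reference condition, with weights.

    Returns (records, weights) where weights is the (n_runs, n_units)
    matrix consumed by weight-sign-consistency lesions.
    """
    grid = ConditionGrid(backgrounds=(LESION_CONDITION.background,),
                         scale_levels=(LESION_CONDITION.nuisance.scale_min,),
                         rot_levels=(LESION_CONDITION.nuisance.rot_max,),
                         n_repeats=repeats)
    df, weights = run_grid(grid, ["simple"], pool, base_seed, cfg=LESION_CFG,
                           test_per_class=LESION_TEST_PER_CLASS,
                           dtype=np.float32, store_weights=True)
    key = ("simple", LESION_CONDITION.background.kind,
           LESION_CONDITION.nuisance.scale_min,
           LESION_CONDITION.nuisance.rot_max)
    return df, weights[key]
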