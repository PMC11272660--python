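"""Simulated lesions: channel knockouts and weight-sign-consistency subsets.

Two families of lesion are supported, both followed by re-initialization and
retraining of the readout on the reduced feature set:

- channel lesions drop or keep whole spatial-frequency channels;
- consistency lesions keep (or drop) the units whose trained classifier
  weight had the same nonzero sign in at least a threshold number of runs
  of the full model under one fixed condition.

Lesioning never alters surviving kernels — it only removes units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compose import Condition
from .evaluate import _run_condition_repeat, records_to_frame
from .filters import FilterBank
from .readout import TrainConfig
from .stimuli import Pool

LESION_MODES = ("drop_channels", "keep_channels", "keep_consistent",
                "drop_consistent")

__all__ = ["LesionSpec", "SignConsistency", "apply_channel_lesion",
           "consistency_sets", "unit_subset_from_consistency",
           "run_lesion_experiment", "LESION_MODES"]


@dataclass(frozen=True)
class LesionSpec:
    """Which units to remove or retain."""

    mode: str
    channels: tuple = ()
    consistency_threshold: int = 0

    def __post_init__(self) -> None:
        if self.mode not in LESION_MODES:
            raise ValueError(f"unknown lesion mode {self.mode!r}")
        if self.mode in ("drop_channels", "keep_channels"):
            if not self.channels:
                raise ValueError("channel lesion requires a channel subset")
            if any(c not in (0, 1, 2, 3) for c in self.channels):
                raise ValueError("channels must be drawn from {0,1,2,3}")
        elif self.consistency_threshold < 1:
            raise ValueError("consistency_threshold must be >= 1")


@dataclass
class SignConsistency:
    """Per-unit weight-sign counts across runs and the derived kept sets."""

    signs: np.ndarray       # (n_units, n_runs), entries in {-1, 0, +1}
    threshold: int

    @property
    def n_runs(self) -> int:
        return self.signs.shape[1]

    def kept(self, threshold: int | None = None) -> np.ndarray:
        """Indices of units with identical nonzero sign in >= threshold runs."""
        t = self.threshold if threshold is None else threshold
        pos = (self.signs > 0).sum(axis=1)
        neg = (self.signs < 0).sum(axis=1)
        return np.flatnonzero((pos >= t) | (neg >= t))

    @property
    def kept_units(self) -> np.ndarray:
        return self.kept()


def apply_channel_lesion(bank: FilterBank, spec: LesionSpec) -> FilterBank:
    """Bank restricted to the kept spatial-frequency channels.

    Kernels of surviving channels are untouched; the readout downstream
    must be re-initialized and retrained on the reduced feature set.
    """
    if spec.mode == "keep_channels":
        kept = sorted(set(spec.channels))
    elif spec.mode == "drop_channels":
        kept = [c for c in range(len(bank.channels)) if c not in spec.channels]
    else:
        raise ValueError("apply_channel_lesion requires a channel mode")
    if not kept:
        raise ValueError("lesion would remove every channel")
    return FilterBank(model_kind=bank.model_kind,
                      canvas_size=bank.canvas_size,
                      channels=[bank.channels[c] for c in kept],
                      matrices=[bank.matrices[c] for c in kept])


def consistency_sets(weights: np.ndarray, threshold: int) -> SignConsistency:
    """Sign-consistency analysis of classifier weights across runs.

    ``weights`` is (n_runs, n_units); a unit is kept iff its weight sign is
    identical and nonzero in at least ``threshold`` runs.  Exactly-zero
    weights count as sign-inconsistent.
    """
    w = np.atleast_2d(np.asarray(weights))
    n_runs = w.shape[0]
    if not 1 <= threshold <= n_runs:
        raise ValueError("threshold must lie in [1, n_runs]")
    return SignConsistency(signs=np.sign(w).T.astype(int), threshold=threshold)


def unit_subset_from_consistency(bank: FilterBank, sc: SignConsistency,
                                 mode: str) -> FilterBank:
    """Bank keeping (or dropping) the sign-consistent units."""
    kept = sc.kept_units
    if mode == "drop_consistent":
        kept = np.setdiff1d(np.arange(sum(bank.channel_counts)), kept)
    if len(kept) == 0:
        raise ValueError("lesion would remove every unit")
    return bank.subset(kept)


def run_lesion_experiment(bank: FilterBank, spec: LesionSpec, pool: Pool,
                          condition: Condition, cfg: TrainConfig,
                          base_seed: int, n_repeats: int,
                          test_per_class: int = 1500,
                          base_weights: np.ndarray | None = None):
    """Retrain and evaluate a lesioned model under one condition.

    Channel modes act on the bank directly.  Consistency modes require
    ``base_weights`` — the (n_runs, n_units) weight matrix of a completed
    full-model experiment under the same condition — and raise a dependency
    error without it.  Repeats are seeded exactly as in
    :func:`earlyvision.evaluate.run_grid` (seed = base_seed + i), so a
    lesion that keeps every unit reproduces the full-model records bit for
    bit.
    """
    if spec.mode in ("drop_channels", "keep_channels"):
        lesioned = apply_channel_lesion(bank, spec)
    else:
        if base_weights is None:
            raise ValueError("consistency lesions require base_weights from "
                             "a completed full-model experiment")
        sc = consistency_sets(base_weights, spec.consistency_threshold)
        lesioned = unit_subset_from_consistency(bank, sc, spec.mode)

    records = []
    for rep in range(n_repeats):
        recs, _ = _run_condition_repeat(
            {bank.model_kind: lesioned}, pool, condition, cfg,
            base_seed + rep, rep, test_per_class)
        records.extend(recs)
    return records_to_frame(records)
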