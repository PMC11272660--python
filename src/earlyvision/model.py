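"""Model-object interface: FaceDecoder / FaceDecoderResults.

``FaceDecoder`` bundles a stimulus pool, an encoder bank, a presentation
condition, and a training configuration; ``fit`` runs one (or many) full
split/train/test rounds and returns a ``FaceDecoderResults`` carrying the
trained readout(s), the per-repeat performance records, and a ``summary()``
table.  The lower-level operations live in :mod:`earlyvision.stimuli`,
:mod:`~.compose`, :mod:`~.filters`, :mod:`~.readout`, :mod:`~.evaluate`,
and :mod:`~.lesion`; this class only orchestrates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compose import Condition, compose_canvas
from .evaluate import _run_condition_repeat, records_to_frame
from .filters import build_bank, encode
from .readout import TrainConfig, predict
from .stimuli import GeneratorParams, Pool, generate_pool

__all__ = ["FaceDecoder", "FaceDecoderResults"]


class FaceDecoder:
    """Binary image-category decoder over a fixed early-vision encoder.

    Parameters
    ----------
    pool : Pool
        Two-class stimulus pool; each fit draws its own train/test split.
    model_kind : str
        Encoder family: 'simple', 'complex', 'linear', or 'lgn'.
    condition : Condition
        Background kind and nuisance (scale/rotation/jitter) ranges under
        which every canvas — training and test — is composed.
    train_config : TrainConfig
        SGD protocol hyperparameters.
    """

    def __init__(self, pool: Pool, model_kind: str = "simple",
                 condition: Condition | None = None,
                 train_config: TrainConfig | None = None,
                 canvas_size: int = 340, dtype=np.float64):
        self.pool = pool
        self.model_kind = model_kind
        self.condition = condition or Condition()
        self.train_config = train_config or TrainConfig()
        self.bank = build_bank(model_kind, canvas_size, dtype=dtype)

    @classmethod
    def from_generator(cls, n_per_class: int = 60,
                       params: GeneratorParams | None = None,
                       seed: int = 0, task: str = "face", **kwargs):
        """Build a decoder over a freshly generated synthetic pool."""
        pool = generate_pool(n_per_class, params, seed=seed, task=task)
        return cls(pool, **kwargs)

    def fit(self, seed: int = 0, n_repeats: int = 1,
            test_per_class: int = 1500) -> "FaceDecoderResults":
        """Run n_repeats split/train/test rounds (seeds seed + i)."""
        records, readouts = [], []
        for rep in range(n_repeats):
            recs, ros = _run_condition_repeat(
                {self.model_kind: self.bank}, self.pool, self.condition,
                self.train_config, seed + rep, rep, test_per_class)
            records.extend(recs)
            readouts.append(ros[0])
        return FaceDecoderResults(model=self, readouts=readouts,
                                  records=records_to_frame(records))


@dataclass
class FaceDecoderResults:
    """Fit results: trained readouts, per-repeat records, summaries."""

    model: FaceDecoder
    readouts: list
    records: pd.DataFrame

    @property
    def params(self) -> np.ndarray:
        """Weights of the (last) trained readout."""
        return self.readouts[-1].weights

    @property
    def weight_matrix(self) -> np.ndarray:
        """(n_repeats, n_units) stack of trained weights."""
        return np.stack([r.weights for r in self.readouts])

    @property
    def median_percent_correct(self) -> float:
        return float(self.records["percent_correct"].median())

    @property
    def median_d_prime(self) -> float:
        return float(self.records["d_prime"].median())

    def predict_stimuli(self, stimuli, seed: int = 0) -> np.ndarray:
        """Compose and classify stimuli with the last trained readout."""
        rng = np.random.default_rng(seed)
        feats = np.stack([
            encode(compose_canvas(s, self.model.condition, rng),
                   self.model.bank).values
            for s in stimuli])
        return predict(self.readouts[-1], feats)

    def summary(self) -> str:
        m = self.model
        rec = self.records
        cc = ", ".join(str(c) for c in m.bank.channel_counts)
        lines = [
            "FaceDecoder Results",
            "=" * 58,
            f"Encoder:            V1/LGN bank '{m.model_kind}'",
            f"Units (by channel): {m.bank.unit_count}  ({cc})",
            f"Background:         {m.condition.background.kind}",
            f"Scale range:        [{m.condition.nuisance.scale_min:.2f}, 1.00]",
            f"Rotation range:     +/-{m.condition.nuisance.rot_max:.0f} deg",
            f"Jitter range:       +/-{m.condition.nuisance.jitter_max} px",
            f"Protocol:           {m.train_config.protocol} "
            f"({m.train_config.epochs} epochs, "
            f"{m.train_config.per_class}/class/epoch)",
            f"Pool:               {len(m.pool.pos)} {m.pool.pos_label} / "
            f"{len(m.pool.neg)} {m.pool.neg_label}",
            f"Repeats:            {len(rec)}",
            "-" * 58,
            f"Median percent correct: {rec['percent_correct'].median():.3f}",
            f"IQR percent correct:    [{rec['percent_correct'].quantile(0.25):.3f}, "
            f"{rec['percent_correct'].quantile(0.75):.3f}]",
            f"Median hit rate:        {rec['hit_rate'].median():.3f}",
            f"Median false alarms:    {rec['false_alarm_rate'].median():.3f}",
            f"Median d':              {rec['d_prime'].median():.3f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_distribution(self, ax=None):
        """Violin-style plot of the percent-correct distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        vals = self.records["percent_correct"].to_numpy()
        ax.violinplot(vals, showmedians=True)
        ax.set_ylabel("fraction correct")
        ax.set_xticks([1])
        ax.set_xticklabels([self.model.model_kind])
        return ax
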