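"""Dataset and result I/O: PNG stimuli, CSV manifests/results, JSON readouts.

Stimuli are stored as 8-bit grayscale+alpha PNG (lossy to 8 bits); result
tables round-trip losslessly through CSV with a one-line metadata header
embedding the run-configuration hash and base seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .readout import Readout
from .stimuli import GeneratorParams, Pool, Stimulus

RESULT_COLUMNS = ["model_kind", "background", "scale_min", "rot_max",
                  "repeat", "seed", "percent_correct", "hit_rate",
                  "false_alarm_rate", "d_prime"]

__all__ = [
    "FormatError", "RunConfig", "config_hash", "load_config", "save_config",
    "save_stimulus", "load_stimulus", "save_pool", "load_pool",
    "save_canvas", "load_canvas",
    "save_results", "load_results", "save_readout", "load_readout",
    "save_generator_params", "load_generator_params",
    "save_lesion_manifest", "load_lesion_manifest", "save_median_summary",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk schema."""


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one experiment run."""

    experiment: str = "default"
    n_per_class: int = 60
    pool_seed: int = 0
    base_seed: int = 0
    models: tuple = ("simple",)
    backgrounds: tuple = ("mid_gray",)
    scale_levels: tuple = (1.0,)
    rot_levels: tuple = (0.0,)
    n_repeats: int = 1
    epochs: int = 10
    per_class: int = 1500
    batch_size: int = 64
    test_per_class: int = 1500
    outdir: str = "results"


_CONFIG_KEYS = set(RunConfig.__dataclass_fields__)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical JSON form of a config."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Strict YAML config load; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    for k in ("models", "backgrounds", "scale_levels", "rot_levels"):
        if k in data and isinstance(data[k], list):
            data[k] = tuple(data[k])
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stimuli

def save_stimulus(stim: Stimulus, path) -> None:
    """Write a stimulus as 8-bit grayscale+alpha PNG (un-premultiplied)."""
    alpha = np.clip(stim.alpha, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lum = np.where(alpha > 0, stim.pixels / np.maximum(alpha, 1e-12), 0.0)
    arr = np.stack([np.clip(np.round(lum), 0, 255),
                    np.round(alpha * 255)], axis=-1).astype(np.uint8)
    Image.fromarray(arr, mode="LA").save(path)


def load_stimulus(path, label: str, sublabel: str | None = None) -> Stimulus:
    img = Image.open(path).convert("LA")
    arr = np.asarray(img, dtype=float)
    alpha = arr[..., 1] / 255.0
    pixels = arr[..., 0] * alpha  # back to premultiplied storage
    return Stimulus(pixels=pixels, alpha=alpha, label=label, sublabel=sublabel)


def save_pool(pool: Pool, outdir, seed: int | None = None) -> Path:
    """Write a pool as PNGs plus a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cls, stims in (("pos", pool.pos), ("neg", pool.neg)):
        label = pool.pos_label if cls == "pos" else pool.neg_label
        for i, s in enumerate(stims):
            name = f"{label}_{i:04d}.png"
            save_stimulus(s, outdir / name)
            rows.append({"filename": name, "label": s.label,
                         "sublabel": s.sublabel or "", "seed": seed})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_pool(outdir) -> Pool:
    outdir = Path(outdir)
    manifest = outdir / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"no manifest.csv in {outdir}")
    df = pd.read_csv(manifest, keep_default_na=False)
    required = {"filename", "label", "sublabel"}
    if not required <= set(df.columns):
        raise FormatError(f"manifest missing columns {required - set(df.columns)}")
    labels = [l for l in df["label"].unique()]
    if len(labels) != 2:
        raise FormatError("manifest must contain exactly two labels")
    pos_label = "face" if "face" in labels else labels[0]
    neg_label = next(l for l in labels if l != pos_label)
    pools = {pos_label: [], neg_label: []}
    for _, row in df.iterrows():
        stim = load_stimulus(outdir / row["filename"], row["label"],
                             row["sublabel"] or None)
        pools[row["label"]].append(stim)
    return Pool(pos=pools[pos_label], neg=pools[neg_label],
                pos_label=pos_label, neg_label=neg_label)


def save_canvas(canvas: np.ndarray, path) -> None:
    """Write a composed canvas as 8-bit grayscale PNG."""
    arr = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_canvas(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float)


_GEN_KEYS = set(GeneratorParams.__dataclass_fields__)


def save_generator_params(params: GeneratorParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)


def load_generator_params(path) -> GeneratorParams:
    """Strict key/value generator config; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - _GEN_KEYS
    if unknown:
        raise FormatError(f"unknown generator keys: {sorted(unknown)}")
    for k, v in data.items():
        if isinstance(v, list):
            data[k] = tuple(v)
    params = GeneratorParams(**data)
    params.validate()
    return params


def save_lesion_manifest(kept_units, path, mode: str = "",
                         cfg_hash: str = "") -> None:
    """Kept-unit indices of a lesioned bank, as JSON."""
    payload = {"mode": mode, "config": cfg_hash,
               "kept_units": np.asarray(kept_units, dtype=int).tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_lesion_manifest(path):
    with open(path) as fh:
        payload = json.load(fh)
    if "kept_units" not in payload:
        raise FormatError("lesion manifest missing kept_units")
    return np.asarray(payload["kept_units"], dtype=int), payload


def save_median_summary(df: pd.DataFrame, path, cfg_hash: str = "",
                        base_seed: int = 0) -> None:
    """Per-condition median percent correct and d', as JSON."""
    med = (df.groupby(["model_kind", "background", "scale_min", "rot_max"])
           [["percent_correct", "d_prime"]].median())
    payload = {"config": cfg_hash, "seed": int(base_seed), "medians": [
        {"model_kind": k[0], "background": k[1], "scale_min": k[2],
         "rot_max": k[3], "percent_correct": row["percent_correct"],
         "d_prime": row["d_prime"]}
        for k, row in med.iterrows()]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# results and readouts

def save_results(df: pd.DataFrame, path, cfg_hash: str = "",
                 base_seed: int = 0) -> None:
    """Lossless CSV round-trip with an embedded metadata header line."""
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results missing columns {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(f"# earlyvision-results config={cfg_hash} seed={base_seed}\n")
        df[RESULT_COLUMNS].to_csv(fh, index=False)


def load_results(path):
    """Load a results CSV; returns (DataFrame, metadata dict)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# earlyvision-results"):
            raise FormatError("not an earlyvision results file")
        meta = dict(tok.split("=", 1) for tok in header.split()[2:])
        df = pd.read_csv(fh)
    if list(df.columns) != RESULT_COLUMNS:
        raise FormatError("results file has unexpected columns")
    return df, meta


def save_readout(readout: Readout, path, cfg_hash: str = "",
                 seed: int = 0) -> None:
    payload = {"weights": np.asarray(readout.weights, dtype=float).tolist(),
               "bias": float(readout.bias),
               "epochs_trained": int(readout.epochs_trained),
               "config": cfg_hash, "seed": int(seed)}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_readout(path) -> Readout:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return Readout(weights=np.asarray(payload["weights"], dtype=float),
                       bias=float(payload["bias"]),
                       epochs_trained=int(payload.get("epochs_trained", 0)))
    except KeyError as exc:
        raise FormatError(f"readout file missing field {exc}") from exc
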