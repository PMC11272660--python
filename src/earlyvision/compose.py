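"""Background synthesis, nuisance transforms, and canvas compositing.

A stimulus is presented by (1) drawing a random down-scaling factor and
rotation angle and applying them about the 256x256 canvas center, (2)
building a 340x340 background of the configured kind, and (3) alpha
compositing the stimulus window at the canvas center plus an integer jitter
of up to +/-42 px per axis — exactly the margin (340-256)/2, so the
foreground always lands fully inside the canvas.

Stimulus pixels are stored premultiplied by alpha (zero outside the mask),
so geometric interpolation and compositing are
``out = fg_premultiplied + (1 - alpha) * background``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stimuli import Stimulus, gen_scene

BG_SIZE = 340
STIM_SIZE = 256
JITTER_MAX = (BG_SIZE - STIM_SIZE) // 2  # 42 px

BACKGROUND_KINDS = (
    "mid_gray", "image_mean_gray", "pink_noise", "pixelated_white",
    "pixelated_binary", "pixelated_image_sampled",
    "scene_high_contrast", "scene_blurred",
)

__all__ = [
    "BackgroundSpec", "NuisanceSpec", "Condition", "BG_SIZE", "STIM_SIZE",
    "JITTER_MAX", "BACKGROUND_KINDS", "make_background", "blur_scene",
    "transform_stim", "place_on_canvas", "compose_canvas",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Which background to composite onto, with its fixed parameters."""

    kind: str = "mid_gray"
    block_size: int = 4          # pixelated kinds
    blur_sd: float = 3.0         # scene_blurred
    contrast_factor: float = 0.5  # scene_blurred
    pink_rms: float = 40.0       # pink_noise RMS contrast about mean 128
    scene_count: int = 48        # size of the fixed scene library
    scene_seed: int = 7          # library generation seed

    def __post_init__(self) -> None:
        if self.kind not in BACKGROUND_KINDS:
            raise ValueError(f"unknown background kind {self.kind!r}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.scene_count < 1:
            raise ValueError("scene_count must be >= 1")


@dataclass(frozen=True)
class NuisanceSpec:
    """Ranges of the presentation nuisances.

    scale is drawn uniformly from [scale_min, 1] (isotropic down-scaling),
    rotation uniformly from [-rot_max, +rot_max] degrees, and jitter as
    integer offsets uniform on [-jitter_max, +jitter_max] per axis.
    """

    scale_min: float = 1.0
    rot_max: float = 0.0
    jitter_max: int = JITTER_MAX

    def __post_init__(self) -> None:
        if not 0.0 < self.scale_min <= 1.0:
            raise ValueError("scale_min must lie in (0, 1]")
        if not 0.0 <= self.rot_max <= 180.0:
            raise ValueError("rot_max must lie in [0, 180] degrees")
        if not 0 <= self.jitter_max <= JITTER_MAX:
            raise ValueError(f"jitter_max must lie in [0, {JITTER_MAX}]")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: background kind + nuisance ranges."""

    background: BackgroundSpec = BackgroundSpec()
    nuisance: NuisanceSpec = NuisanceSpec()


def _blocks(rng_values: np.ndarray, block: int, size: int) -> np.ndarray:
    full = np.kron(rng_values, np.ones((block, block)))
    return full[:size, :size]


def blur_scene(scene: np.ndarray, contrast_factor: float = 0.5,
               blur_sd: float = 3.0) -> np.ndarray:
    """Reduce a scene's contrast about its own mean, then Gaussian blur."""
    m = scene.mean()
    reduced = m + contrast_factor * (scene - m)
    return ndimage.gaussian_filter(reduced, blur_sd)


def make_background(spec: BackgroundSpec, rng: np.random.Generator,
                    stim: Stimulus | None = None,
                    size: int = BG_SIZE) -> np.ndarray:
    """Build a size x size background canvas of the requested kind.

    ``image_mean_gray`` and ``pixelated_image_sampled`` require the stimulus
    being presented (they use its foreground luminance).
    """
    if spec.kind in ("image_mean_gray", "pixelated_image_sampled"):
        if stim is None:
            raise ValueError(f"background kind {spec.kind!r} requires a stimulus")
        fg = stim.alpha > 0
        fg_vals = stim.pixels[fg] / np.maximum(stim.alpha[fg], 1e-12)

    if spec.kind == "mid_gray":
        return np.full((size, size), 128.0)
    if spec.kind == "image_mean_gray":
        return np.full((size, size), float(fg_vals.mean()))
    if spec.kind == "pink_noise":
        white = rng.standard_normal((size, size))
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.fftfreq(size)[None, :]
        f = np.hypot(fy, fx)
        f[0, 0] = np.inf  # zero out DC; mean set explicitly below
        tex = np.real(np.fft.ifft2(np.fft.fft2(white) / f))
        tex = tex / tex.std() * spec.pink_rms
        return np.clip(128.0 + tex, 0.0, 255.0)
    nb = -(-size // spec.block_size)  # ceil
    if spec.kind == "pixelated_white":
        vals = rng.integers(0, 256, (nb, nb)).astype(float)
        return _blocks(vals, spec.block_size, size)
    if spec.kind == "pixelated_binary":
        vals = rng.integers(0, 2, (nb, nb)).astype(float) * 255.0
        return _blocks(vals, spec.block_size, size)
    if spec.kind == "pixelated_image_sampled":
        vals = rng.choice(fg_vals, size=(nb, nb))
        return _blocks(vals, spec.block_size, size)
    if spec.kind in ("scene_high_contrast", "scene_blurred"):
        lib = _scene_library(spec, size)
        idx = int(rng.integers(spec.scene_count))
        return lib[idx].astype(float)
    raise ValueError(f"unknown background kind {spec.kind!r}")


_SCENE_CACHE: dict = {}


def _scene_library(spec: BackgroundSpec, size: int) -> np.ndarray:
    """Fixed library of scene backgrounds, mirroring a finite scene set.

    Scene presentations draw from a pre-generated pool (as a curated scene
    image set would be reused across presentations) rather than
    synthesizing a new texture per canvas.  The library is determined by
    (scene_seed, scene_count, size) and cached; blurred variants store the
    contrast-reduced, Gaussian-blurred version of the same scenes.
    """
    key = (spec.kind, spec.scene_seed, spec.scene_count, size,
           spec.contrast_factor, spec.blur_sd)
    if key not in _SCENE_CACHE:
        rng = np.random.default_rng(spec.scene_seed)
        scenes = np.stack([gen_scene(size, rng)
                           for _ in range(spec.scene_count)])
        if spec.kind == "scene_blurred":
            scenes = np.stack([blur_scene(s, spec.contrast_factor,
                                          spec.blur_sd) for s in scenes])
        _SCENE_CACHE[key] = scenes.astype(np.float32)
    return _SCENE_CACHE[key]


def transform_stim(s: Stimulus, n: NuisanceSpec,
                   rng: np.random.Generator) -> Stimulus:
    """Apply a random isotropic down-scaling then rotation about the center.

    Both the (premultiplied) pixels and the alpha channel are resampled with
    the same bilinear interpolation; the area outside the transformed support
    is transparent.  The output stays 256x256.  With ``scale_min=1`` and
    ``rot_max=0`` the input is returned unchanged (bit-exact identity).
    """
    u = rng.uniform(n.scale_min, 1.0)
    theta = np.deg2rad(rng.uniform(-n.rot_max, n.rot_max))
    if n.scale_min == 1.0 and n.rot_max == 0.0:
        return s

    # inverse map for ndimage.affine_transform: scale by 1/u, rotate by -theta
    c, si = np.cos(theta), np.sin(theta)
    rot_inv = np.array([[c, si], [-si, c]])
    m = rot_inv / u
    center = (STIM_SIZE - 1) / 2.0
    offset = np.array([center, center]) - m @ np.array([center, center])
    px = ndimage.affine_transform(s.pixels, m, offset=offset, order=1,
                                  mode="constant", cval=0.0)
    al = ndimage.affine_transform(s.alpha, m, offset=offset, order=1,
                                  mode="constant", cval=0.0)
    return replace(s, pixels=np.clip(px, 0.0, 255.0), alpha=np.clip(al, 0.0, 1.0))


def place_on_canvas(s: Stimulus, bg: np.ndarray, rng: np.random.Generator,
                    jitter_max: int = JITTER_MAX) -> np.ndarray:
    """Alpha-composite the stimulus at center + integer jitter.

    Jitter is drawn uniformly on [-jitter_max, +jitter_max]^2; because the
    foreground sits inside its 256x256 window and the margin is 42 px per
    side, every alpha > 0 pixel lands inside the 340x340 canvas.
    """
    if s.pixels.shape != (STIM_SIZE, STIM_SIZE):
        raise ValueError("stimulus must be 256x256")
    if bg.shape != (BG_SIZE, BG_SIZE):
        raise ValueError("background must be 340x340")
    jy, jx = rng.integers(-jitter_max, jitter_max + 1, size=2)
    top = (BG_SIZE - STIM_SIZE) // 2 + int(jy)
    left = (BG_SIZE - STIM_SIZE) // 2 + int(jx)
    out = bg.astype(s.pixels.dtype, copy=True)
    window = out[top:top + STIM_SIZE, left:left + STIM_SIZE]
    out[top:top + STIM_SIZE, left:left + STIM_SIZE] = (
        s.pixels + (1.0 - s.alpha) * window)
    return out


def compose_canvas(s: Stimulus, condition: Condition,
                   rng: np.random.Generator, dtype=None) -> np.ndarray:
    """Full presentation: transform, background, composite; returns 340x340.

    ``dtype`` optionally casts the stimulus before transforming (single
    precision roughly halves interpolation cost; the random draws are
    identical either way).
    """
    if dtype is not None and s.pixels.dtype != np.dtype(dtype):
        s = replace(s, pixels=s.pixels.astype(dtype),
                    alpha=s.alpha.astype(dtype))
    t = transform_stim(s, condition.nuisance, rng)
    bg = make_background(condition.background, rng, stim=t)
    return place_on_canvas(t, bg, rng, condition.nuisance.jitter_max)
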