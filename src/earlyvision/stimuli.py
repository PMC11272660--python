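"""Synthetic face-like, non-face, and scene stimulus generation.

Real face/object photo sets are replaced by parametric grayscale foregrounds
with binary alpha masks on a 256x256 canvas.  The generators emulate the
low-level statistics a downstream encoder is sensitive to: matched mean
luminance and RMS contrast between the two classes, a narrow fraction-filled
and elongation distribution for faces (single high-fill oval with internal
eye/mouth structure) and broad distributions for non-faces (unions of random
blobs, plus a fraction of oval shapes).  The foreground's largest bounding-box
side is always 246 px, centered on the canvas, leaving the margin that the
downstream +/-42 px jitter exhausts exactly on a 340x340 background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

CANVAS = 256
LARGEST_SIDE = 246

__all__ = [
    "Stimulus", "StimStats", "GeneratorParams", "Pool",
    "gen_face", "gen_nonface", "gen_scene", "stim_stats",
    "match_luminance_sets", "generate_pool",
]


@dataclass
class Stimulus:
    """A grayscale foreground with alpha mask on a 256x256 canvas.

    pixels : float array, luminance on the 0-255 scale.
    alpha  : float array in [0, 1]; binary at generation time, fractional
             after geometric interpolation.
    label  : 'face' or 'nonface'.
    sublabel : optional 'male-like' / 'female-like' variant tag for faces.
    """

    pixels: np.ndarray
    alpha: np.ndarray
    label: str
    sublabel: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pixels.shape != self.alpha.shape:
            raise ValueError("pixels and alpha must have identical shapes")


@dataclass(frozen=True)
class StimStats:
    """Low-level statistics of a stimulus foreground."""

    mean_luminance: float
    rms_contrast: float
    fraction_filled: float
    elongation: float


@dataclass(frozen=True)
class GeneratorParams:
    """Targets and geometry ranges for the stimulus generators.

    Luminance/contrast targets are per-image draws on the 0-255 scale; shape
    targets control the per-class fraction-filled and elongation
    distributions.  Non-face luminance is generated darker by design (its
    mean is the face mean divided by ``nonface_dim_factor``) so that
    :func:`match_luminance_sets` recovers a brightening factor near that
    value when equalizing the two sets.
    """

    face_lum_mean: float = 103.0
    face_lum_sd: float = 15.0
    contrast_mean: float = 41.5
    contrast_sd: float = 7.0
    nonface_dim_factor: float = 1.15
    nonface_lum_sd: float = 14.0

    face_elong_mean: float = 1.60
    face_elong_sd: float = 0.16
    face_fill_exponent_range: tuple[float, float] = (4.0, 8.0)

    nonface_log_elong_mean: float = 0.85   # exp(0.85) ~ 2.34 median
    nonface_log_elong_sd: float = 0.38
    nonface_oval_fraction: float = 0.25
    nonface_blob_count: tuple[int, int] = (3, 6)

    # face feature geometry, as fractions of foreground width/height
    eye_y_range: tuple[float, float] = (0.32, 0.42)
    eye_sep_range: tuple[float, float] = (0.40, 0.52)
    eye_rx_range: tuple[float, float] = (0.08, 0.12)
    mouth_y_range: tuple[float, float] = (0.68, 0.78)
    mouth_w_range: tuple[float, float] = (0.34, 0.48)
    mouth_h_range: tuple[float, float] = (0.05, 0.09)

    def validate(self) -> None:
        sds = (self.face_lum_sd, self.contrast_sd, self.nonface_lum_sd,
               self.face_elong_sd, self.nonface_log_elong_sd)
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 < self.face_lum_mean < 255.0):
            raise ValueError("face_lum_mean must lie in (0, 255)")
        if self.contrast_mean < 0:
            raise ValueError("contrast_mean must be >= 0")
        if self.face_elong_mean < 1.0:
            raise ValueError("elongation targets must be >= 1")
        if not 0.0 <= self.nonface_oval_fraction <= 1.0:
            raise ValueError("nonface_oval_fraction must lie in [0, 1]")
        lo, hi = self.nonface_blob_count
        if lo < 1 or hi < lo:
            raise ValueError("nonface_blob_count must be a valid (lo, hi)")


@dataclass
class Pool:
    """A labeled two-class stimulus pool (positive class drives hit rate)."""

    pos: list
    neg: list
    pos_label: str = "face"
    neg_label: str = "nonface"

    def __post_init__(self) -> None:
        if not self.pos or not self.neg:
            raise ValueError("both classes must be nonempty")


# ---------------------------------------------------------------------------
# internal helpers

def _smooth_field(shape, rng, sigma):
    """Low-frequency Gaussian random field, zero mean, unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _shading(shape, rng):
    """Linear gradient + low-frequency blobs, zero mean, unit SD."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    grad = (xx - w / 2) * np.cos(theta) + (yy - h / 2) * np.sin(theta)
    grad = grad / max(h, w)
    fld = 0.8 * grad + 0.6 * _smooth_field(shape, rng, sigma=max(h, w) / 8)
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def _normalize_foreground(lum, mask, target_mean, target_sd):
    """Rescale masked luminance to target mean/SD on the clipped [0,255] scale.

    Clipping after a single affine rescale biases the realized moments
    (dark features saturate at 0), so the rescale+clip step is iterated a
    few times; the fixed point has the target moments up to residual
    saturation.
    """
    for _ in range(4):
        vals = lum[mask]
        m, s = vals.mean(), vals.std()
        if s > 0:
            lum = (lum - m) / s * target_sd + target_mean
        else:
            lum = lum - m + target_mean
        lum = np.clip(lum, 0.0, 255.0)
    return lum


def _place_centered(fg_lum, fg_mask, label, sublabel=None):
    h, w = fg_mask.shape
    pixels = np.zeros((CANVAS, CANVAS))
    alpha = np.zeros((CANVAS, CANVAS))
    top = (CANVAS - h) // 2
    left = (CANVAS - w) // 2
    pixels[top:top + h, left:left + w] = fg_lum * fg_mask
    alpha[top:top + h, left:left + w] = fg_mask
    return Stimulus(pixels=pixels, alpha=alpha, label=label, sublabel=sublabel)


def _fit_box(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Resize a mask so its bounding box is exactly h x w.

    Crops to the current bounding box, nearest-neighbour resizes to the
    target box, and guarantees every border row/column contains foreground
    (nearest resampling can leave a border empty by sub-pixel misalignment;
    the nearest populated row/column pattern is copied in, a <=1 px change).
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    m = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if m.shape != (h, w):
        m = transform.resize(m, (h, w), order=0, anti_aliasing=False,
                             preserve_range=True).astype(bool)
    for axis in (0, 1):
        filled = np.flatnonzero(m.any(axis=1 - axis))
        view = m if axis == 0 else m.T
        if filled[0] != 0:
            view[0] = view[filled[0]]
        if filled[-1] != view.shape[0] - 1:
            view[-1] = view[filled[-1]]
    return m


def _superellipse_mask(h, w, n):
    """|2y/h|^n + |2x/w|^n <= 1 on an h x w grid; touches all four edges."""
    yy = np.abs(np.linspace(-1.0, 1.0, h))[:, None]
    xx = np.abs(np.linspace(-1.0, 1.0, w))[None, :]
    return _fit_box((yy ** n + xx ** n) <= 1.0, h, w)


def _ellipse_patch(mask, cy, cx, ry, rx, angle=0.0, value=True):
    """Set an ellipse (optionally rotated) into a boolean mask, in place."""
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    sel = (u / max(rx, 1e-9)) ** 2 + (v / max(ry, 1e-9)) ** 2 <= 1.0
    mask[sel] = value
    return sel


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


# ---------------------------------------------------------------------------
# generators

def gen_face(params: GeneratorParams, rng: np.random.Generator,
             sublabel: Optional[str] = None) -> Stimulus:
    """Generate a face-like stimulus.

    A high-fill superellipse foreground (taller than wide) containing two
    bilateral dark eye blobs, a dark mouth bar, and smooth shading.  The
    foreground bounding box has largest side 246 px; elongation is drawn
    near the face-class target.  ``sublabel`` selects the 'male-like' /
    'female-like' geometry variant used by the gender task.
    """
    params.validate()
    if sublabel not in (None, "male-like", "female-like"):
        raise ValueError(f"unknown sublabel {sublabel!r}")

    elong_mean = params.face_elong_mean
    eye_scale, mouth_scale, jaw_shade = 1.0, 1.0, 0.0
    if sublabel == "male-like":
        elong_mean -= 0.08
        eye_scale, mouth_scale, jaw_shade = 0.85, 1.25, 1.0
    elif sublabel == "female-like":
        elong_mean += 0.08
        eye_scale, mouth_scale, jaw_shade = 1.15, 0.85, 0.0

    e = _truncnorm(rng, elong_mean, params.face_elong_sd, 1.15, 2.2)
    h = LARGEST_SIDE
    w = int(round(LARGEST_SIDE / e))
    n = rng.uniform(*params.face_fill_exponent_range)
    mask = _superellipse_mask(h, w, n)

    lum = 120.0 + 18.0 * _shading((h, w), rng)

    eye_y = rng.uniform(*params.eye_y_range) * h
    sep = rng.uniform(*params.eye_sep_range) * w
    rx = rng.uniform(*params.eye_rx_range) * w * eye_scale
    ry = rx * rng.uniform(0.55, 0.8)
    depth = rng.uniform(55, 90)
    for sx in (-1.0, 1.0):
        sel = np.zeros((h, w), dtype=bool)
        _ellipse_patch(sel, eye_y, w / 2 + sx * sep / 2, ry, rx)
        lum[sel] -= depth

    mouth_y = rng.uniform(*params.mouth_y_range) * h
    mw = rng.uniform(*params.mouth_w_range) * w
    mh = rng.uniform(*params.mouth_h_range) * h * mouth_scale
    sel = np.zeros((h, w), dtype=bool)
    _ellipse_patch(sel, mouth_y, w / 2, mh / 2, mw / 2)
    lum[sel] -= rng.uniform(35, 60)

    if jaw_shade > 0:
        yy = np.mgrid[0:h, 0:w][0]
        band = (yy > mouth_y - 0.06 * h) & mask
        lum[band] -= 12.0 * jaw_shade

    tm = _truncnorm(rng, params.face_lum_mean, params.face_lum_sd, 40, 210)
    ts = _truncnorm(rng, params.contrast_mean, params.contrast_sd, 8, 90)
    lum = _normalize_foreground(lum, mask, tm, ts)
    return _place_centered(lum, mask.astype(float), "face", sublabel)


def gen_nonface(params: GeneratorParams, rng: np.random.Generator) -> Stimulus:
    """Generate a non-face stimulus.

    Either a single oval/superellipse (a configurable fraction of draws,
    mirroring the deliberate inclusion of oval shapes in the reference
    object set) or a union of random ellipses, resized so the foreground
    bounding box is tight with largest side 246 px.  Elongation is drawn
    from a broad log-normal; luminance is generated dimmer than the face
    class by ``nonface_dim_factor`` prior to set-level matching.
    """
    params.validate()
    e = float(np.clip(np.exp(rng.normal(params.nonface_log_elong_mean,
                                        params.nonface_log_elong_sd)),
                      1.0, 6.0))
    long_side = LARGEST_SIDE
    short_side = int(round(LARGEST_SIDE / e))
    if rng.random() < 0.5:
        h, w = long_side, short_side
    else:
        h, w = short_side, long_side

    if rng.random() < params.nonface_oval_fraction:
        mask = _superellipse_mask(h, w, rng.uniform(1.6, 4.0))
    else:
        lo, hi = params.nonface_blob_count
        k = int(rng.integers(lo, hi + 1))
        mask = np.zeros((h, w), dtype=bool)
        for _ in range(k):
            cy = rng.uniform(0.2, 0.8) * h
            cx = rng.uniform(0.2, 0.8) * w
            ry = rng.uniform(0.15, 0.45) * h
            rx = rng.uniform(0.15, 0.45) * w
            _ellipse_patch(mask, cy, cx, ry, rx, angle=rng.uniform(0, np.pi))
        # crop to the union's bounding box, then stretch to the target box
        mask = _fit_box(mask, h, w)

    lum = 110.0 + 20.0 * _shading((h, w), rng)
    # occasional internal dark/light patches so textures are not all smooth
    for _ in range(int(rng.integers(0, 3))):
        sel = np.zeros((h, w), dtype=bool)
        _ellipse_patch(sel, rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w,
                       rng.uniform(0.05, 0.18) * h, rng.uniform(0.05, 0.18) * w)
        lum[sel] += rng.uniform(-60, 60)

    # pre-match targets: set-level luminance matching multiplies both the
    # mean and the SD by ~nonface_dim_factor, so divide both out here
    tm = _truncnorm(rng, params.face_lum_mean / params.nonface_dim_factor,
                    params.nonface_lum_sd, 30, 200)
    ts = _truncnorm(rng, params.contrast_mean / params.nonface_dim_factor,
                    params.contrast_sd, 8, 90)
    lum = _normalize_foreground(lum, mask, tm, ts)
    return _place_centered(lum, mask.astype(float), "nonface")


def gen_scene(size: int, rng: np.random.Generator) -> np.ndarray:
    """Generate a size x size scene-like texture, histogram equalized.

    Horizon split (brighter upper region), 1/f-spectrum texture, and a few
    oriented bars; final luminance histogram is equalized so the empirical
    CDF is approximately uniform on [0, 255].
    """
    if size < 64:
        raise ValueError("scene size must be >= 64")

    yy, xx = np.mgrid[0:size, 0:size]
    horizon = rng.uniform(0.3, 0.7) * size
    img = np.where(yy < horizon, 165.0, 90.0)

    # 1/f amplitude-spectrum texture
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    tex = np.real(np.fft.ifft2(np.fft.fft2(white) / f))
    tex = tex / tex.std()
    img = img + 28.0 * tex

    for _ in range(int(rng.integers(2, 6))):
        theta = rng.uniform(0, np.pi)
        c = rng.uniform(-0.4, 0.4) * size
        width = rng.uniform(2, 8)
        d = (xx - size / 2) * np.cos(theta) + (yy - size / 2) * np.sin(theta)
        img[np.abs(d - c) < width] += rng.uniform(-70, 70)

    eq = exposure.equalize_hist(img)
    return np.clip(eq * 255.0, 0.0, 255.0)


# ---------------------------------------------------------------------------
# statistics and set matching

def stim_stats(s: Stimulus) -> StimStats:
    """Foreground statistics: mean/RMS luminance, fraction filled, elongation.

    Luminance statistics use foreground (alpha > 0) pixels only; RMS contrast
    is the unnormalized SD of foreground luminance on the 0-255 scale.
    Fraction filled is relative to the full 256x256 canvas; elongation is
    max(w/h, h/w) of the foreground bounding box.
    """
    fg = s.alpha > 0
    if not fg.any():
        raise ValueError("empty alpha mask")
    vals = s.pixels[fg]
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    h = rows[-1] - rows[0] + 1
    w = cols[-1] - cols[0] + 1
    return StimStats(
        mean_luminance=float(vals.mean()),
        rms_contrast=float(vals.std()),
        fraction_filled=float(fg.sum()) / fg.size,
        elongation=float(max(w / h, h / w)),
    )


def match_luminance_sets(set_a, set_b):
    """Brighten set B so its average foreground luminance matches set A.

    Returns ``(factor, adjusted_b)`` where ``factor`` is the ratio of the
    two sets' average per-image foreground mean luminances and each B
    stimulus's foreground is multiplied by it (clipped to [0, 255]).
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be nonempty")
    mean_a = float(np.mean([s.pixels[s.alpha > 0].mean() for s in set_a]))
    mean_b = float(np.mean([s.pixels[s.alpha > 0].mean() for s in set_b]))
    factor = mean_a / mean_b
    adjusted = []
    for s in set_b:
        px = np.clip(s.pixels * factor, 0.0, 255.0) * (s.alpha > 0)
        adjusted.append(replace(s, pixels=px))
    return factor, adjusted


def generate_pool(n_per_class: int, params: Optional[GeneratorParams] = None,
                  seed: int = 0, match: bool = True,
                  task: str = "face") -> Pool:
    """Generate a matched two-class pool.

    ``task='face'``: faces vs non-faces, with non-faces luminance-matched to
    faces.  ``task='gender'``: male-like vs female-like face variants.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    if task == "face":
        pos = [gen_face(params, rng) for _ in range(n_per_class)]
        neg = [gen_nonface(params, rng) for _ in range(n_per_class)]
        if match:
            _, neg = match_luminance_sets(pos, neg)
        return Pool(pos=pos, neg=neg, pos_label="face", neg_label="nonface")
    if task == "gender":
        pos = [gen_face(params, rng, "male-like") for _ in range(n_per_class)]
        neg = [gen_face(params, rng, "female-like") for _ in range(n_per_class)]
        return Pool(pos=pos, neg=neg, pos_label="male-like",
                    neg_label="female-like")
    raise ValueError(f"unknown task {task!r}")
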