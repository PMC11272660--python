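"""Backgrounds, nuisance transforms, and alpha compositing."""

import numpy as np
import pytest

from earlyvision.compose import (
    BG_SIZE, JITTER_MAX, BackgroundSpec, Condition, NuisanceSpec,
    blur_scene, compose_canvas, make_background, place_on_canvas,
    transform_stim,
)
from earlyvision.stimuli import Stimulus, gen_face


def _disc_stimulus(radius=100, value=200.0):
    yy, xx = np.mgrid[0:256, 0:256]
    alpha = ((yy - 127.5) ** 2 + (xx - 127.5) ** 2 <= radius ** 2).astype(float)
    return Stimulus(pixels=value * alpha, alpha=alpha, label="nonface")


def test_background_kind_validation():
    with pytest.raises(ValueError):
        BackgroundSpec("plaid")
    with pytest.raises(ValueError):
        make_background(BackgroundSpec("image_mean_gray"),
                        np.random.default_rng(0), stim=None)


def test_mid_gray_is_exactly_128():
    bg = make_background(BackgroundSpec("mid_gray"), np.random.default_rng(0))
    assert bg.shape == (BG_SIZE, BG_SIZE)
    assert np.all(bg == 128.0)


def test_image_mean_gray_matches_foreground(params):
    s = gen_face(params, np.random.default_rng(1))
    bg = make_background(BackgroundSpec("image_mean_gray"),
                         np.random.default_rng(0), stim=s)
    assert np.all(bg == s.pixels[s.alpha > 0].mean())


@pytest.mark.parametrize("kind", ["pixelated_white", "pixelated_binary"])
def test_pixelated_blocks(kind):
    bg = make_background(BackgroundSpec(kind), np.random.default_rng(2))
    if kind == "pixelated_binary":
        assert set(np.unique(bg)) <= {0.0, 255.0}
    else:
        assert bg.min() >= 0 and bg.max() <= 255
    blocks = bg[:84 * 4, :84 * 4].reshape(84, 4, 84, 4)
    assert np.all(blocks == blocks[:, :1, :, :1])  # constant per 4x4 block


def test_pixelated_image_sampled_uses_foreground_values(params):
    s = gen_face(params, np.random.default_rng(3))
    bg = make_background(BackgroundSpec("pixelated_image_sampled"),
                         np.random.default_rng(4), stim=s)
    fg_vals = np.unique(s.pixels[s.alpha > 0])
    assert np.isin(np.unique(bg), fg_vals).all()


def test_pink_noise_moments():
    bg = make_background(BackgroundSpec("pink_noise"),
                         np.random.default_rng(5))
    assert abs(bg.mean() - 128.0) < 2.0
    assert abs(bg.std() - 40.0) < 4.0  # clipping eats a little variance


def test_background_determinism(params):
    s = gen_face(params, np.random.default_rng(6))
    for kind in ("pink_noise", "pixelated_white", "scene_high_contrast",
                 "scene_blurred", "pixelated_image_sampled"):
        a = make_background(BackgroundSpec(kind), np.random.default_rng(9), s)
        b = make_background(BackgroundSpec(kind), np.random.default_rng(9), s)
        assert np.array_equal(a, b), kind


def test_blur_scene_fixes_constants():
    const = np.full((64, 64), 77.0)
    out = blur_scene(const)
    assert np.allclose(out, 77.0)


def test_transform_identity_is_bit_exact(params):
    s = gen_face(params, np.random.default_rng(8))
    t = transform_stim(s, NuisanceSpec(scale_min=1.0, rot_max=0.0),
                       np.random.default_rng(0))
    assert t.pixels is s.pixels and t.alpha is s.alpha


def test_rotation_preserves_disc_area():
    s = _disc_stimulus()
    t = transform_stim(s, NuisanceSpec(scale_min=1.0, rot_max=180.0),
                       np.random.default_rng(10))
    assert abs(t.alpha.sum() - s.alpha.sum()) / s.alpha.sum() < 0.01


def test_scaling_area_law():
    s = _disc_stimulus()
    n = NuisanceSpec(scale_min=0.5, rot_max=0.0)
    rng = np.random.default_rng(11)
    u = np.random.default_rng(11).uniform(n.scale_min, 1.0)  # clone the draw
    t = transform_stim(s, n, rng)
    ratio = t.alpha.sum() / s.alpha.sum()
    assert ratio == pytest.approx(u ** 2, rel=0.05)


def test_place_fully_transparent_returns_background():
    s = Stimulus(pixels=np.zeros((256, 256)), alpha=np.zeros((256, 256)),
                 label="face")
    bg = np.random.default_rng(12).uniform(0, 255, (BG_SIZE, BG_SIZE))
    out = place_on_canvas(s, bg, np.random.default_rng(13))
    assert np.array_equal(out, bg)


def test_place_composites_and_conserves_background():
    s = _disc_stimulus(radius=60, value=250.0)
    bg = np.full((BG_SIZE, BG_SIZE), 10.0)
    rng = np.random.default_rng(14)
    jy, jx = np.random.default_rng(14).integers(-JITTER_MAX, JITTER_MAX + 1,
                                                size=2)
    out = place_on_canvas(s, bg, rng)
    top, left = 42 + jy, 42 + jx
    window = out[top:top + 256, left:left + 256]
    assert np.array_equal(window[s.alpha > 0], s.pixels[s.alpha > 0])
    mask = np.zeros_like(out, dtype=bool)
    mask[top:top + 256, left:left + 256] = s.alpha > 0
    assert np.all(out[~mask] == 10.0)


def test_jitter_bound_exhausts_margin():
    # the +/-42 px jitter is exactly the (340 - 256) / 2 margin
    assert JITTER_MAX == (340 - 256) // 2
    s = Stimulus(pixels=np.full((256, 256), 200.0),
                 alpha=np.ones((256, 256)), label="face")
    for seed in range(5):
        out = place_on_canvas(s, np.zeros((BG_SIZE, BG_SIZE)),
                              np.random.default_rng(seed))
        assert out.shape == (BG_SIZE, BG_SIZE)  # never raises / clips


def test_nuisance_validation():
    with pytest.raises(ValueError):
        NuisanceSpec(scale_min=0.0)
    with pytest.raises(ValueError):
        NuisanceSpec(rot_max=181.0)
    with pytest.raises(ValueError):
        NuisanceSpec(jitter_max=43)


def test_compose_canvas_shape_and_determinism(params):
    s = gen_face(params, np.random.default_rng(15))
    cond = Condition(BackgroundSpec("pixelated_binary"),
                     NuisanceSpec(scale_min=0.7, rot_max=45.0))
    a = compose_canvas(s, cond, np.random.default_rng(16))
    b = compose_canvas(s, cond, np.random.default_rng(16))
    assert a.shape == (BG_SIZE, BG_SIZE)
    assert np.array_equal(a, b)
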