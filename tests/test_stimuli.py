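"""Synthetic stimulus generator: geometry, statistics, determinism."""

import dataclasses

import numpy as np
import pytest

from earlyvision.stimuli import (
    CANVAS, LARGEST_SIDE, GeneratorParams, Stimulus,
    gen_face, gen_nonface, gen_scene, generate_pool,
    match_luminance_sets, stim_stats,
)


def _bbox_sides(alpha):
    rows = np.flatnonzero(alpha.any(axis=1))
    cols = np.flatnonzero(alpha.any(axis=0))
    return rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1


@pytest.mark.parametrize("gen", [gen_face, gen_nonface])
def test_generator_contracts(params, gen):
    rng = np.random.default_rng(5)
    for _ in range(10):
        s = gen(params, rng)
        assert s.pixels.shape == (CANVAS, CANVAS)
        assert s.alpha.shape == (CANVAS, CANVAS)
        assert set(np.unique(s.alpha)) <= {0.0, 1.0}  # binary at generation
        assert s.pixels.min() >= 0.0 and s.pixels.max() <= 255.0
        h, w = _bbox_sides(s.alpha)
        assert max(h, w) == LARGEST_SIDE


@pytest.mark.parametrize("gen", [gen_face, gen_nonface])
def test_generator_determinism(params, gen):
    a = gen(params, np.random.default_rng(77))
    b = gen(params, np.random.default_rng(77))
    assert np.array_equal(a.pixels, b.pixels)
    assert np.array_equal(a.alpha, b.alpha)


def test_face_class_statistics(large_sets):
    """Face foregrounds are high-fill, mildly elongated, narrowly spread."""
    faces, nonfaces, _ = large_sets
    fstats = [stim_stats(s) for s in faces]
    nstats = [stim_stats(s) for s in nonfaces]
    frac = np.mean([s.fraction_filled for s in fstats])
    elong = np.mean([s.elongation for s in fstats])
    assert 0.50 <= frac <= 0.62
    assert 1.4 <= elong <= 1.9
    # non-face shape variation is much larger than across the face set
    f_sd = np.std([s.elongation for s in fstats])
    n_sd = np.std([s.elongation for s in nstats])
    assert n_sd > f_sd


def test_class_luminance_contrast_matched(large_sets):
    """After set matching the class means agree to better than 2%."""
    faces, nonfaces, _ = large_sets
    fstats = [stim_stats(s) for s in faces]
    nstats = [stim_stats(s) for s in nonfaces]
    for attr in ("mean_luminance", "rms_contrast"):
        a = np.mean([getattr(s, attr) for s in fstats])
        b = np.mean([getattr(s, attr) for s in nstats])
        assert abs(a - b) / a < 0.02, attr


def test_invalid_params_rejected():
    bad = dataclasses.replace(GeneratorParams(), face_lum_sd=-1.0)
    with pytest.raises(ValueError):
        gen_face(bad, np.random.default_rng(0))
    with pytest.raises(ValueError):
        gen_face(GeneratorParams(), np.random.default_rng(0), sublabel="dog")


def test_scene_contract_and_equalization():
    with pytest.raises(ValueError):
        gen_scene(32, np.random.default_rng(0))
    a = gen_scene(340, np.random.default_rng(3))
    b = gen_scene(340, np.random.default_rng(3))
    assert a.shape == (340, 340)
    assert a.min() >= 0.0 and a.max() <= 255.0
    assert np.array_equal(a, b)
    # histogram equalization: the luminance CDF is approximately uniform
    frac_dark = np.mean(a < 127)
    assert 0.45 <= frac_dark <= 0.55


def test_stim_stats_constant_and_geometry():
    full = Stimulus(pixels=np.full((256, 256), 128.0),
                    alpha=np.ones((256, 256)), label="face")
    st = stim_stats(full)
    assert (st.mean_luminance, st.rms_contrast) == (128.0, 0.0)
    assert (st.fraction_filled, st.elongation) == (1.0, 1.0)

    rect = np.zeros((256, 256))
    alpha = np.zeros((256, 256))
    alpha[64:192, :] = 1.0  # 128 x 256 solid rectangle
    rect[alpha > 0] = 100.0
    st = stim_stats(Stimulus(pixels=rect, alpha=alpha, label="nonface"))
    assert st.fraction_filled == pytest.approx(0.5)
    assert st.elongation == pytest.approx(2.0)


def test_stim_stats_two_point_distribution():
    alpha = np.zeros((256, 256))
    alpha[:2, :] = 1.0
    pix = np.zeros((256, 256))
    pix[0, :] = 0.0
    pix[1, :] = 255.0
    st = stim_stats(Stimulus(pixels=pix, alpha=alpha, label="face"))
    assert st.mean_luminance == pytest.approx(127.5)
    assert st.rms_contrast == pytest.approx(127.5)


def test_stim_stats_empty_mask_errors():
    s = Stimulus(pixels=np.zeros((256, 256)), alpha=np.zeros((256, 256)),
                 label="face")
    with pytest.raises(ValueError):
        stim_stats(s)


def test_match_luminance_identity_and_inverse(params):
    rng = np.random.default_rng(11)
    a = [gen_face(params, rng) for _ in range(5)]
    factor, adj = match_luminance_sets(a, a)
    assert factor == pytest.approx(1.0)
    for s, t in zip(a, adj):
        assert np.allclose(s.pixels, t.pixels)

    dimmed = [dataclasses.replace(s, pixels=s.pixels / 1.15) for s in a]
    factor, adj = match_luminance_sets(a, dimmed)
    assert factor == pytest.approx(1.15, rel=1e-6)
    mean_a = np.mean([s.pixels[s.alpha > 0].mean() for s in a])
    mean_b = np.mean([s.pixels[s.alpha > 0].mean() for s in adj])
    assert abs(mean_a - mean_b) / mean_a < 0.01

    with pytest.raises(ValueError):
        match_luminance_sets([], a)


def test_gender_pool_variants():
    pool = generate_pool(3, seed=4, task="gender")
    assert {s.sublabel for s in pool.pos} == {"male-like"}
    assert {s.sublabel for s in pool.neg} == {"female-like"}
    assert all(s.label == "face" for s in pool.pos + pool.neg)
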