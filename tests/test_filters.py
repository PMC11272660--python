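"""Filter-bank construction and encoding identities.

The encoder's fast path (phase-{0,90} raw responses expanded through the
phase-negation identity) is checked against independent direct dot products
with explicitly constructed kernels at 1e-10 relative tolerance.
"""

import numpy as np
import pytest

from earlyvision.filters import (
    KernelSpec, RESPONSE_GAIN, build_bank, dog_kernel, encode, gabor_kernel,
    units_per_position, MODEL_KINDS, ORIENTATIONS,
)

EXPECTED_COUNTS = {
    "simple": (7088, (144, 144, 1024, 5776)),
    "lgn": (886, (18, 18, 128, 722)),
    "complex": (1772, (36, 36, 256, 1444)),
    "linear": (3544, (72, 72, 512, 2888)),
}


@pytest.fixture(scope="module")
def banks():
    return {k: build_bank(k) for k in MODEL_KINDS}


@pytest.fixture(scope="module")
def canvas():
    return np.random.default_rng(0).uniform(0, 255, (340, 340))


@pytest.mark.parametrize("kind", MODEL_KINDS)
def test_unit_counts(banks, kind):
    total, per_channel = EXPECTED_COUNTS[kind]
    assert banks[kind].unit_count == total
    assert banks[kind].channel_counts == per_channel


def test_channel_grids(banks):
    grids = [(ch.wavelength, ch.support, ch.n, ch.pad)
             for ch in banks["simple"].channels]
    assert grids[0][:3] == (256, 384, 3)   # zero-padded to host a 3x3 grid
    assert grids[0][3] > 0
    assert grids[1:] == [(128, 192, 3, 0), (64, 96, 8, 0), (32, 48, 19, 0)]


def test_gabor_support_and_normalization():
    k = gabor_kernel(KernelSpec(32, orientation=0.0, phase=0.0))
    assert k.shape == (48, 48)
    assert abs(k.mean()) < 1e-15          # zero DC
    assert np.linalg.norm(k) == pytest.approx(1.0)


def test_gabor_phase_negation():
    for theta in ORIENTATIONS:
        k0 = gabor_kernel(KernelSpec(64, orientation=theta, phase=0.0))
        k180 = gabor_kernel(KernelSpec(64, orientation=theta, phase=180.0))
        assert np.allclose(k180, -k0, atol=1e-12)
        k90 = gabor_kernel(KernelSpec(64, orientation=theta, phase=90.0))
        k270 = gabor_kernel(KernelSpec(64, orientation=theta, phase=270.0))
        assert np.allclose(k270, -k90, atol=1e-12)


def test_gabor_rotation_symmetry():
    k_v = gabor_kernel(KernelSpec(64, orientation=0.0, phase=0.0))
    k_h = gabor_kernel(KernelSpec(64, orientation=90.0, phase=0.0))
    assert np.allclose(k_h, np.rot90(k_v), atol=1e-12)


def test_dog_polarity_and_symmetry():
    on = dog_kernel(KernelSpec(64, polarity="on"))
    off = dog_kernel(KernelSpec(64, polarity="off"))
    assert np.array_equal(off, -on)
    assert np.allclose(on, np.rot90(on), atol=1e-12)    # radial symmetry
    assert np.allclose(on, on.T, atol=1e-12)


def test_dog_dc_balance():
    # unit-sum center minus 0.2 unit-sum surround: net DC 0.8 pre-scaling
    for lam in (32, 64, 128, 256):
        raw = dog_kernel(KernelSpec(lam, polarity="on"), normalized=False)
        assert raw.sum() == pytest.approx(0.8, rel=0.02)


def test_zero_canvas_gives_zero_features(banks):
    zero = np.zeros((340, 340))
    for kind, bank in banks.items():
        f = encode(zero, bank)
        assert np.all(f.values == 0.0), kind


def test_uniform_canvas_silences_v1(banks):
    uni = np.full((340, 340), 200.0)
    for kind in ("simple", "complex", "linear"):
        f = encode(uni, banks[kind])
        # DC-free kernels ignore uniform input on fully-contained supports;
        # the zero-padded lowest-SF channel sees the canvas edge, so check
        # the unpadded channels only
        sl = banks[kind].channel_slices
        inner = np.concatenate([f.values[s] for s in sl[1:]])
        assert np.max(np.abs(inner)) < 1e-10


def _direct_unit_responses(canvas, bank, channel, n_positions, rng):
    """Independent oracle: explicit kernels, explicit padded windows."""
    ch = bank.channels[channel]
    kernels = bank.kernels(channel)  # full explicit per-unit kernel stack
    scaled = canvas * (RESPONSE_GAIN / 255.0)
    padded = np.pad(scaled, ch.pad) if ch.pad else scaled
    upp = units_per_position(bank.model_kind)
    picks = rng.choice(ch.positions, size=min(n_positions, ch.positions),
                       replace=False)
    out = {}
    for p in picks:
        r, c = divmod(int(p), ch.n)
        win = padded[r * ch.stride:r * ch.stride + ch.support,
                     c * ch.stride:c * ch.stride + ch.support]
        if bank.model_kind == "simple":
            resp = [max(0.0, float(np.sum(k * win))) for k in kernels]
        elif bank.model_kind == "linear":
            resp = [float(np.sum(k * win)) for k in kernels]
        elif bank.model_kind == "lgn":
            resp = [max(0.0, float(np.sum(k * win))) for k in kernels]
        elif bank.model_kind == "complex":
            # energy pooling over the 4 phases of each orientation
            resp = []
            for oi in range(4):
                quad = kernels[4 * oi:4 * oi + 4]
                resp.append(sum(max(0.0, float(np.sum(k * win)))
                                for k in quad))
        out[p] = np.asarray(resp)
        assert len(resp) == upp
    return out


@pytest.mark.parametrize("kind", MODEL_KINDS)
def test_encode_matches_direct_dot_products(banks, canvas, kind):
    bank = banks[kind]
    f = encode(canvas, bank).values
    rng = np.random.default_rng(kind == "lgn")
    upp = units_per_position(kind)
    start = 0
    for ci, ch in enumerate(bank.channels):
        oracle = _direct_unit_responses(canvas, bank, ci, 6, rng)
        for p, resp in oracle.items():
            got = f[start + p * upp:start + (p + 1) * upp]
            assert np.allclose(got, resp, rtol=1e-10, atol=1e-12)
        start += ch.positions * upp


def test_simple_phase_sum_reproduces_complex(banks, canvas):
    fs = encode(canvas, banks["simple"]).values
    fc = encode(canvas, banks["complex"]).values
    pooled = fs.reshape(-1, 4).sum(axis=1)  # sum the 4 phases per (pos, ori)
    assert np.array_equal(pooled, fc)


def test_complex_equals_abs_of_quadrature_pair(banks, canvas):
    fl = encode(canvas, banks["linear"]).values.reshape(-1, 2)
    fc = encode(canvas, banks["complex"]).values
    assert np.allclose(np.abs(fl).sum(axis=1), fc, rtol=1e-10)


def test_linear_homogeneity(banks, canvas):
    f1 = encode(canvas, banks["linear"]).values
    f2 = encode(0.5 * canvas, banks["linear"]).values
    assert np.allclose(f2, 0.5 * f1, rtol=1e-10, atol=1e-12)


def test_lgn_on_off_complementarity(banks, canvas):
    f = encode(canvas, banks["lgn"]).values.reshape(-1, 2)
    on, off = f[:, 0], f[:, 1]
    assert np.all(on >= 0) and np.all(off >= 0)
    assert np.all((on == 0) | (off == 0))  # rectified complements


def test_rectified_kinds_nonnegative(banks, canvas):
    for kind in ("simple", "complex", "lgn"):
        assert encode(canvas, banks[kind]).values.min() >= 0.0


def test_float32_bank_consistency(canvas):
    b64 = build_bank("simple")
    b32 = build_bank("simple", dtype=np.float32)
    f64 = encode(canvas, b64).values
    f32 = encode(canvas, b32).values
    assert f32.dtype == np.float32
    assert np.allclose(f32, f64, rtol=1e-3, atol=1e-3)


def test_unknown_kind_rejected():
    with pytest.raises(ValueError):
        build_bank("pyramidal")


def test_subset_bank_selects_units(banks, canvas):
    bank = banks["lgn"]
    idx = np.arange(0, bank.unit_count, 7)
    sub = bank.subset(idx)
    assert sub.unit_count == len(idx)
    full = encode(canvas, bank).values
    assert np.array_equal(encode(canvas, sub).values, full[idx])
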