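import numpy as np
import pytest

from earlyvision.stimuli import GeneratorParams, gen_face, gen_nonface, \
    match_luminance_sets


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def large_sets(params):
    """500 faces and 500 non-faces, luminance-matched (shared across tests)."""
    rng = np.random.default_rng(1234)
    faces = [gen_face(params, rng) for _ in range(500)]
    nonfaces = [gen_nonface(params, rng) for _ in range(500)]
    factor, nonfaces = match_luminance_sets(faces, nonfaces)
    return faces, nonfaces, factor


@pytest.fixture(scope="session")
def small_pool():
    from earlyvision.stimuli import generate_pool

    return generate_pool(8, seed=99)
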