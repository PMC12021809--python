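import numpy as np
import pytest

from fibrotwin import maps


@pytest.fixture(scope="session")
def noise_ensemble():
    """100 seeded 96x96 noise maps (shared: generation is cheap, reuse is free)."""
    return [maps.generate_noise_map(seed=i) for i in range(100)]


@pytest.fixture(scope="session")
def fixture_ensemble():
    """100 seeded LGE-like fixture maps."""
    return [maps.generate_lge_like_fixture(seed=i) for i in range(100)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
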