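import warnings

import numpy as np
import pytest

from oenomet.simulate import GeneratorConfig, generate

# the generator's default study conditions, one canonical seed for the suite
BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size synthetic bundle under the default study conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(GeneratorConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def small_bundle():
    """Small, fast bundle for plumbing tests."""
    cfg = GeneratorConfig(
        seed=BUNDLE_SEED,
        n_metabolites=150,
        modules=[{"size": 40}, {"size": 30}],
        n_differential=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
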