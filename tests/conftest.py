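import numpy as np
import pytest

import honeypower as hp


@pytest.fixture(scope="session")
def published():
    return hp.load_published_weights()


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic study: 100 samples, 25 per floral type."""
    frame, latent = hp.generate_table(hp.GeneratorConfig())
    return frame, latent


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_weights(rng, n_in=3, n_hidden=5, scale=2.0):
    return hp.MLPWeights(
        rng.normal(0, scale, (n_in, n_hidden)),
        rng.normal(0, scale, n_hidden),
        rng.normal(0, scale, n_hidden),
        float(rng.normal(0, scale)),
    )
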