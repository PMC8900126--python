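import numpy as np
import pytest

from cmcnano.composition import (
    DEFAULT_AMIDE_FRACTION,
    fit_pattern_distribution,
    generate_chain,
)
from cmcnano.structure import ThetaPolicy, embed_chain


@pytest.fixture(scope="session")
def default_dist():
    return fit_pattern_distribution()


@pytest.fixture(scope="session")
def cmc8_chain_100(default_dist):
    """A 100-mer chain at default DS and amidation."""
    return generate_chain(
        default_dist, 100, amide_fraction=DEFAULT_AMIDE_FRACTION, seed=42
    )


@pytest.fixture(scope="session")
def cmc_chain_100(default_dist):
    """A 100-mer unmodified chain at default DS."""
    return generate_chain(default_dist, 100, amide_fraction=0.0, seed=42)


@pytest.fixture(scope="session")
def cmc8_conformer(cmc8_chain_100):
    return embed_chain(
        cmc8_chain_100, theta_policy=ThetaPolicy.target_lp(5.0), seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
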