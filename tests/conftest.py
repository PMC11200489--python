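import numpy as np
import pytest

import ecgleads as eg


@pytest.fixture(scope="session")
def small_dataset() -> eg.BeatSet:
    """9 classes × 12 beats, default informative leads, default noise."""
    return eg.generate_dataset(eg.SyntheticSpec(n_beats_per_class=12, seed=42))


@pytest.fixture(scope="session")
def tiny_model() -> eg.LeadWiseModel:
    return eg.build_leadwise(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
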