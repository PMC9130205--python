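import numpy as np
import pytest

from hgadmix.synthetic import (
    generate_populations,
    generate_profiles,
    sample_individuals,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """Small admixed dataset with planted truth, shared across tests."""
    profiles = generate_profiles(4, 12, concentration=0.5, seed=101)
    freq, truth = generate_populations(
        profiles, 15, mixture_mode="admixed", noise_sd=0.0, seed=102
    )
    table = sample_individuals(freq, 300, subclade_prob=0.4, seed=103)
    return {"profiles": profiles, "freq": freq, "truth": truth, "table": table}
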