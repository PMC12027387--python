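import warnings

import pytest

from phosphoprimer.simulate import GeneratorConfig, simulate_study

# the 3v3 design has only 9 distinct label permutations; the informational
# warning is expected throughout the suite
warnings.filterwarnings(
    "ignore", message="only .* distinct label permutations available"
)


@pytest.fixture(scope="session")
def small_config():
    """A fast study: enough substrates for recovery checks, small enough to
    keep each differential run well under a second."""
    return GeneratorConfig(
        n_proteins=80,
        n_substrates=15,
        mean_protein_length=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The generator's default study conditions (shared; treat as read-only)."""
    return simulate_study(seed=7)
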