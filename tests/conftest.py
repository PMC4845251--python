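import pytest

from swardlab.design import build_design, default_species_pool
from swardlab.synthetic import InteractionSpec, generate_dataset


@pytest.fixture(scope="session")
def pool():
    return default_species_pool()


@pytest.fixture(scope="session")
def design53(pool):
    return build_design(4, 3, pool)


@pytest.fixture(scope="session")
def neutral_dataset():
    """No interactions, no noise: mixtures behave exactly additively."""
    return generate_dataset(ix=InteractionSpec.neutral(seed=11))


@pytest.fixture(scope="session")
def comp_only_dataset():
    """Noise-free dataset with only a symmetric complementarity surplus."""
    ix = InteractionSpec(
        facilitation_ramp=(0.0,) * 6,
        legume_suppression_early=1.0,
        complementarity_amplitude=0.15,
        noise_cv=0.0,
        seed=11,
    )
    return generate_dataset(ix=ix)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions with noise (seeded)."""
    return generate_dataset(ix=InteractionSpec(seed=7))
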