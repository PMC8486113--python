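import numpy as np
import pytest

from carcmort import SyntheticConfig, NameNoise, generate_cohort
from carcmort.identity_resolution import deduplicate_movements, link_deaths


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise synthetic cohort: linkage ground truth is unambiguous."""
    return generate_cohort(SyntheticConfig(n_individuals=4000, seed=11))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with name corruption, missing mothers and duplicate IDs."""
    cfg = SyntheticConfig(
        n_individuals=3000, seed=12,
        name_noise=NameNoise(char_error_prob=0.02, token_drop_prob=0.03,
                             missing_mother_prob=0.10),
        duplicate_id_prob=0.10)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_linkage(clean_cohort):
    clusters = deduplicate_movements(clean_cohort.movement_log)
    matches = link_deaths(clusters, clean_cohort.mortality_registry)
    return clusters, matches


@pytest.fixture
def rng():
    return np.random.default_rng(0)
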