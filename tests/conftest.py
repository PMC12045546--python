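import numpy as np
import pytest

from reconpref import GeneratorConfig, LatentProfile, build_deck
from reconpref.config import default_base_utilities


@pytest.fixture(scope="session")
def deck9():
    return build_deck("normal", "unilateral")


@pytest.fixture(scope="session")
def deck10():
    return build_deck("normal", "unilateral", include_death=True)


@pytest.fixture
def clean_config():
    """Deterministic cohort: no noise, no covariate effects, no behavioural
    perturbations.  Every participant shares the default base utilities."""
    return GeneratorConfig(n_participants=8, rng_seed=3).replace(
        effects=[],
        latent_noise_sd=0.0,
        choice_noise=0.0,
        vas_noise_sd=0.0,
        unexpected_rank_fraction=0.0,
        equipoise_fraction=0.0,
    )


@pytest.fixture
def base_profile():
    """Noiseless respondent holding the default base utilities."""
    return LatentProfile("P0001", default_base_utilities())


def make_profile(utilities, **kw) -> LatentProfile:
    return LatentProfile("PTEST", dict(utilities), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
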