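import pytest

from triplescore import bundled_cohort, empirical_config, generate, score_cohort


@pytest.fixture(scope="session")
def cohort():
    return bundled_cohort()


@pytest.fixture(scope="session")
def scored(cohort):
    return score_cohort(cohort)


@pytest.fixture(scope="session")
def synthetic_cohort(cohort):
    """A medium synthetic cohort drawn from the reference distributions."""
    config = empirical_config(cohort, seed=20240813)
    config = type(config)(
        n_per_status={s: 50 for s in config.n_per_status},
        marker_distributions=config.marker_distributions,
        seed=20240813,
    )
    return generate(config)
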