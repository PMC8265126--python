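"""Shared synthetic-cohort fixtures (session-scoped; all data generated in-memory)."""

import pytest

from d2tra.synthetic_ehr import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort_500():
    """Noise-free, zero-missingness 500-patient cohort; negation rate 0.5."""
    return generate_cohort(
        GeneratorConfig(
            n_patients=500,
            d2t_prevalence=0.2,
            noise_sd=0.0,
            negation_rate=0.5,
            clinical_label_fraction=0.3,
            seed=20,
        )
    )


@pytest.fixture(scope="session")
def noise_free_30():
    """Small noise-free cohort with >2000 component-complete visits."""
    return generate_cohort(GeneratorConfig(n_patients=30, noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def default_cohort_60():
    """Default-noise cohort for feature/model plumbing tests."""
    return generate_cohort(
        GeneratorConfig(n_patients=60, clinical_label_fraction=0.6, seed=5)
    )
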