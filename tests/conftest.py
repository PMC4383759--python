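import numpy as np
import pytest
from hypothesis import settings

from radq.synthetic_cohort import GeneratorConfig, generate_cohort, \
    impose_missingness

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Complete SMART cohort, n=800."""
    cohort, _ = generate_cohort(GeneratorConfig(n=800, seed=101))
    return cohort


@pytest.fixture(scope="session")
def masked_cohort(small_cohort):
    """The same cohort with the default MAR masking."""
    return impose_missingness(small_cohort, seed=102)
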