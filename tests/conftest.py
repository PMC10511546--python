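import numpy as np
import pytest

from brainage_msn.preprocessing import apply_qc_filter, harmonize_table, zscore_qa_within_site
from brainage_msn.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject default-parameter cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_subjects=120, seed=11))


@pytest.fixture(scope="session")
def harmonised_cohort(small_cohort):
    morpho, qa, truth = small_cohort
    kept = apply_qc_filter(zscore_qa_within_site(qa))
    corrected, _ = harmonize_table(morpho.subset(kept))
    return corrected, qa, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
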