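import numpy as np
import pytest

from sendotype.io_model import impute_missing, qc_filter_proteins
from sendotype.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (80 patients, 10/200 informative proteins)."""
    return generate_cohort(CohortSpec())


@pytest.fixture(scope="session")
def complete_cohort(default_cohort):
    """Default cohort after QC and median imputation, ready for PCA/k-means."""
    npx, clinical, labels, truth = default_cohort
    complete = impute_missing(qc_filter_proteins(npx))
    return complete, clinical, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
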