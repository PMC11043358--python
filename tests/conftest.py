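import pytest

import screenwise as sw
from screenwise.dose_response import curves_to_matrix
from screenwise.io import curves_from_frame


def fit_ln_ic50_matrix(bundle, drug_id=None):
    """Fit every curve of a generated screen into an ln-IC50 matrix."""
    table = bundle.dose_response
    if drug_id is not None:
        table = table[table["drug_id"] == drug_id]
    return curves_to_matrix(curves_from_frame(table), sw.LN_IC50)


@pytest.fixture(scope="session")
def default_bundle():
    """The drug-dominated default screen (50 samples x 30 drugs)."""
    return sw.generate_screen(sw.SyntheticScreenConfig(seed=1))


@pytest.fixture(scope="session")
def ln_ic50_matrix(default_bundle):
    return fit_ln_ic50_matrix(default_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast, fully observed screen for model and IO tests."""
    return sw.generate_screen(
        sw.SyntheticScreenConfig(
            n_samples=16, n_drugs=8, n_genes=30, causal_genes_per_drug=3,
            coverage_fraction=1.0, seed=5,
        )
    )
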