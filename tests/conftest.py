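import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from veribayes import datasets

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    """Paired binary CT/MRI study, partial verification (116 subjects)."""
    return datasets.lung_ct_mri()


@pytest.fixture(scope="session")
def table4():
    """CT/MRI study with extreme verification bias (82 subjects)."""
    return datasets.lung_ct_mri_extreme()


@pytest.fixture(scope="session")
def table6():
    """Two-reader ordinal mammography study (1,768 subjects)."""
    return datasets.mammography_two_readers()


@pytest.fixture(scope="session")
def bugs4_vectors():
    """Dirichlet hyperparameters of the published combined-AUC run."""
    return datasets.mammography_auc_hyperparameters()


@pytest.fixture(scope="session")
def imputed_records(table6):
    """Per-subject records expanded from the IPW-imputed two-reader study."""
    from veribayes import expand_records, impute_ipw

    return expand_records(impute_ipw(table6, rounding="nearest"))


@pytest.fixture(scope="session")
def fitted_risk_model(imputed_records):
    """Logistic risk-score posterior on the imputed records (full-size run)."""
    from veribayes import fit_logistic

    return fit_logistic(imputed_records, 45_000, 5_000, seed=20_260_926)
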