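import pytest

from nearmiss_audit import fixtures as fx
from nearmiss_audit.criteria import builtin_profile, builtin_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def haydom_profile():
    return builtin_profile("Haydom")


@pytest.fixture(scope="session")
def who_profile():
    return builtin_profile("WHO")


@pytest.fixture(scope="session")
def who_clinical_profile():
    return builtin_profile("WHO-clinical")


@pytest.fixture(scope="session")
def audit_cohort():
    """Deterministic 248-case audit cohort plus denominators."""
    return fx.haydom_audit_cohort()


@pytest.fixture(scope="session")
def who_matrix():
    return fx.who_incidence_matrix()
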