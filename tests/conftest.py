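import pytest
from hypothesis import settings

from ichthyoscore import load_fixture

# Reproducible property tests: same example sequence on every run.
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 66-patient / 87-biopsy reference cohort."""
    return load_fixture()
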