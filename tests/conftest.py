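import warnings

import pytest

from danscreen import StudyConfig, gen_study, run_study_from_synthetic


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 1)."""
    return gen_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_study):
    """Ledger + report of the default study, computed once."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study_from_synthetic(default_study)
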