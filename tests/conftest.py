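import numpy as np
import pytest

from lipidsense import ContactSimSpec, LoadingSimSpec, simulate_contact_counts


@pytest.fixture(scope="session")
def fig4f_series():
    """50 000 iid counts from the four-component contact mixture."""
    return simulate_contact_counts(ContactSimSpec(seed=123))


@pytest.fixture()
def er_like_dict():
    return {"POPC": 60, "DOPE": 20, "DOPS": 10, "cholesterol": 10}


@pytest.fixture(scope="session")
def two_condition_dataset():
    """Noisy two-condition loading dataset with shared k3 (seeded)."""
    from lipidsense import simulate_loading_timecourse

    return simulate_loading_timecourse(LoadingSimSpec(replicates=10, seed=7))
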