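import numpy as np
import pytest

from gafscore.bank import ItemParameters, LatentDist, gafs8_bank
from gafscore.simulate import default_two_group_config, simulate_responses


@pytest.fixture(scope="session")
def bank():
    return gafs8_bank()


@pytest.fixture(scope="session")
def item1(bank):
    return bank[0]  # TAS-20 item 1


@pytest.fixture(scope="session")
def flat_item():
    """Zero-discrimination item: responses carry no trait information."""
    return ItemParameters("flat", 0.0, (2.0, 0.5, -0.5, -2.0))


@pytest.fixture(scope="session")
def two_group_sample():
    """Moderate two-group sample from the published bank (no DIF)."""
    cfg = default_two_group_config(n_norm=600, n_clin=600, seed=314)
    return simulate_responses(cfg)


@pytest.fixture(scope="session")
def normative_sample():
    """Single-group sample of 1200 from the published bank."""
    cfg = default_two_group_config(n_norm=1200, n_clin=1, seed=2718)
    rm = simulate_responses(cfg)
    from gafscore.data import ResponseMatrix

    keep = rm.group == "normative"
    return ResponseMatrix(rm.values[keep], rm.items, None)
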