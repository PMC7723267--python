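import numpy as np
import pytest

from evostab import DEFAULT_PARAMS
from evostab.equilibria import stable_target


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def two_species_target():
    """Exact T+/TP equilibrium at dose 0.4 (the main stabilization target)."""
    x_star, lam = stable_target("two-species")
    return np.asarray(x_star), lam
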