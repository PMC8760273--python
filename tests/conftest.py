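import numpy as np
import pytest

from cannet.inference import DirichletBank
from cannet.pomdp import FactorizedMapping, PriorVector


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


@pytest.fixture
def random_bank(rng):
    """Small random Dirichlet bank for a 3-state, 3-observation, 4-decision
    model (moderate concentrations)."""
    return DirichletBank(
        a=rng.uniform(1, 20, (3, 3, 2, 2)),
        b=rng.uniform(1, 20, (3, 3, 2, 2)),
        c=rng.uniform(1, 20, (4, 3, 2, 2)),
    )


@pytest.fixture
def one_factor_model(rng):
    """Single-state-factor model with exactly enumerable posteriors."""
    A = FactorizedMapping.random("A", 1, 1, rng)
    B = FactorizedMapping.random("B", 1, 1, rng)
    C = FactorizedMapping.random("C", 2, 1, rng)
    D = PriorVector.from_p1(rng.uniform(0.2, 0.8, size=1))
    E = PriorVector.from_p1(rng.uniform(0.2, 0.8, size=2))
    return A, B, C, D, E
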