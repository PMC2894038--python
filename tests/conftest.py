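import numpy as np
import pytest

from vbsa.network import ReactionNetwork, ReversibleReaction, parse_network

AB_MODEL = """\
species:
  - {name: A, initial: 2.0}
  - {name: B, initial: 0.0}
reactions:
  - {id: R1, reactants: "A", products: "B", kf: 1.0, kr: 1.0}
"""

DIMER_MODEL = """\
species:
  - {name: A, initial: 10.0}
  - {name: B, initial: 0.0}
reactions:
  - {id: R1, reactants: "2 A", products: "B", kf: 1.0, kr: 0.5}
"""


@pytest.fixture
def ab_network():
    """Symmetric isomerization A <-> B, kf = kr = 1, q0 = (2, 0)."""
    return parse_network(AB_MODEL)


@pytest.fixture
def dimer_network():
    """Dimerization 2A <-> B."""
    return parse_network(DIMER_MODEL)


@pytest.fixture
def decay_network():
    """First-order decay A -> 0 with unit rate."""
    return ReactionNetwork(
        ["A"], np.array([2.0]),
        [ReversibleReaction("R1", {"A": 1}, {}, 1.0, 0.0)],
    )


@pytest.fixture(scope="session")
def cascade():
    """Three-tier synthetic phosphorylation cascade (M=21, N=23)."""
    from vbsa.bench import synthetic_cascade_fixture

    return synthetic_cascade_fixture(tiers=3, seed=1)
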