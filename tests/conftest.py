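import numpy as np
import pandas as pd
import pytest

from p2k.alphabet import ALPHABET
from p2k.features import DeepKnowledge, build_deep_knowledge
from p2k.residuals import statistical_residuals
from p2k.synthetic import worked_example_matrix, interface_preferences, sample_contact_matrix


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_matrix()


@pytest.fixture(scope="session")
def random_srv():
    """Residual space of a seeded synthetic contact table."""
    cfm = sample_contact_matrix(interface_preferences(), 10_000, seed=1234)
    return statistical_residuals(cfm)


@pytest.fixture(scope="session")
def knowledge(random_srv) -> DeepKnowledge:
    """Deep knowledge (6 components) over the seeded synthetic residuals."""
    return build_deep_knowledge(random_srv, n_components=6)


@pytest.fixture()
def identity_knowledge():
    """Degenerate knowledge tables for layout tests: the projection of each
    residue on PC m is 100*m + alphabet index, and every re-projected matrix
    of PC m is constant m."""
    n_pcs = 6
    scores = np.array(
        [[100 * (m + 1) + i for m in range(n_pcs)] for i in range(20)], dtype=float
    )
    projections = pd.DataFrame(
        scores, index=list(ALPHABET), columns=[f"PC{m}" for m in range(1, n_pcs + 1)]
    )
    rsrvs = [np.full((20, 20), float(m + 1)) for m in range(n_pcs)]
    return projections, rsrvs
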