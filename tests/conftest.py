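import numpy as np
import pytest

from totalnoise import circuit_single_gene, make_network


@pytest.fixture()
def birth_death():
    """Zeroth-order production + first-order decay; stationary law Poisson(100)."""
    return make_network(
        species=["R"],
        stoichiometry=[[1, -1]],
        rate_laws=["k_R * D0", "gamma_R * R"],
        parameters={"k_R": 10.0, "gamma_R": 0.1},
        initial_conditions={"D0": 1.0, "R": 0.0},
    )


@pytest.fixture()
def single_gene():
    """Two-stage gene expression at repo defaults: steady state (10, 1000)."""
    return circuit_single_gene()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
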