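import numpy as np
import pytest
from hypothesis import settings

from graphdp import ConcentrationState, eight_group_dag

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig_dag():
    """The three-layer, eight-group experimental DAG used across the suite."""
    return eight_group_dag()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def unit_conc(fig_dag):
    """All concentrations fixed to 1 on the eight-group DAG."""
    return ConcentrationState(
        alpha0=1.0,
        alpha_root=1.0,
        alpha={j: 1.0 for j in fig_dag.node_ids if j != fig_dag.root},
    )
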