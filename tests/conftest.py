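import numpy as np
import pytest

import tcellnet as tc
from tcellnet.experiments import parameter_recovery


@pytest.fixture(scope="session")
def topo():
    return tc.default_topology()


@pytest.fixture(scope="session")
def params():
    return tc.reference_parameters()


@pytest.fixture(scope="session")
def ts(topo, params):
    return tc.build_type_space(topo, params.p)


@pytest.fixture(scope="session")
def fixture_data():
    """The canonical synthetic dataset and its generating truth."""
    return tc.default_fixture()


def source_state(ts, topo, counts_by_gen):
    vec = np.zeros(ts.size)
    for gen, z in counts_by_gen.items():
        vec[ts.index(topo.source, gen)] = z
    return tc.PopulationState(n=0, counts=vec, type_space=ts)


@pytest.fixture(scope="session")
def recovery_fits():
    """10-replicate parameter-recovery experiment at the study design
    (shared by the recovery and sensitivity-ranking acceptance checks)."""
    fits, truth = parameter_recovery(range(1, 11))
    return fits, truth
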