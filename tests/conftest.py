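import numpy as np
import pytest

from restdcm.features import subject_csd
from restdcm.model_space import ModelSpec, full_space
from restdcm.synthetic_data import (DCMParams, SimulationConfig,
                                    default_coupling, make_group_truth,
                                    simulate_bold, simulate_group)


@pytest.fixture(scope="session")
def two_node_chain():
    """2-node spec with a single free coupling R0 -> R1 of 0.25 Hz."""
    spec = ModelSpec(regions=("R0", "R1"), mask=np.array([[0, 0], [1, 0]]))
    params = DCMParams(A=np.array([[-0.5, 0.0], [0.25, -0.5]]))
    return spec, params


@pytest.fixture(scope="session")
def two_node_subject(two_node_chain):
    """One simulated subject (1000 scans, TR 2 s) and its MAR cross
    spectra on the resting-state band."""
    spec, params = two_node_chain
    cfg = SimulationConfig(n_scans=1000, tr=2.0, seed=3)
    ts = simulate_bold(params, cfg, regions=spec.regions)
    return spec, params, ts, subject_csd(ts)


@pytest.fixture(scope="session")
def a6_spec():
    return next(m for m in full_space("LHIP") if m.name == "a_6")


@pytest.fixture(scope="session")
def a6_group(a6_spec):
    """Small a_6 group (4 subjects, 1000 scans) with known jittered truth."""
    base = default_coupling(a6_spec, 0.2)
    cfg = SimulationConfig(n_scans=1000, tr=2.0, seed=11, subject_sd=0.05)
    truths = make_group_truth(a6_spec, base, cfg, 4)
    group = simulate_group(truths, cfg, regions=a6_spec.regions)
    return base, truths, group
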