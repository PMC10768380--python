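import numpy as np
import pytest

from ttgcn import HeteroNetwork, SynthConfig, generate


@pytest.fixture(scope="session")
def tiny_net():
    """Hand-built 4-drug / 3-target / 2-disease / 2-side-effect network."""
    dd = np.zeros((4, 4)); dd[0, 1] = dd[1, 0] = 1
    dt = np.array([[1, 0, 0],
                   [0, 1, 0],
                   [0, 0, 0],
                   [1, 0, 1]], dtype=float)
    ddis = np.array([[1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
    dse = np.array([[0, 1], [0, 0], [1, 0], [1, 1]], dtype=float)
    tt = np.zeros((3, 3)); tt[1, 2] = tt[2, 1] = 1
    tdis = np.array([[1, 0], [0, 1], [1, 1]], dtype=float)
    sim_d = np.clip((np.eye(4) * 0.6 + 0.4), 0, 1)
    np.fill_diagonal(sim_d, 1.0)
    sim_t = np.array([[1.0, 0.7, 0.2],
                      [0.7, 1.0, 0.6],
                      [0.2, 0.6, 1.0]])
    net = HeteroNetwork(4, 3, 2, 2,
                        relations={"drug-drug": dd, "drug-target": dt,
                                   "drug-disease": ddis, "drug-sideeffect": dse,
                                   "target-target": tt, "target-disease": tdis},
                        similarities={"drug-sim": sim_d, "target-sim": sim_t})
    net.validate()
    return net


@pytest.fixture(scope="session")
def synth_net():
    """The default synthetic fixture: 60 drugs x 90 targets, planted rank 4."""
    net, truth = generate(SynthConfig(seed=7))
    return net, truth
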