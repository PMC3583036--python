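import numpy as np
import pytest

from cortexmap.config import mini_preset, test_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mini_cfg():
    return mini_preset(master_seed=7)


@pytest.fixture
def mini_net(mini_cfg):
    from cortexmap.network_core import Network

    return Network(mini_cfg)


@pytest.fixture(scope="session")
def acceptance_cfg():
    """Shared desk-scale configuration for the quantitative runs."""
    return test_preset(master_seed=11)


@pytest.fixture(scope="session")
def phase1_balanced(acceptance_cfg):
    """One settled Phase-1 run with both plasticity rules active.

    Shared by the rate-band, stability and ocular-dominance checks; 18k
    steps is past the point where the population rate has settled.
    """
    from cortexmap.experiments import PhaseSchedule, run_phase
    from cortexmap.network_core import Network

    net = Network(acceptance_cfg.copy())
    art = run_phase(net, PhaseSchedule(1, "noise_only", 18_000))
    return net, art


def final_third_rate(net, counts):
    tail = counts[-len(counts) // 3:]
    return tail.sum() / (net.populations["E"].n * len(tail) / 1000.0)
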