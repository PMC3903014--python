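import pytest

from tkde.calling import CallingConfig
from tkde.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def basic_sim(tmp_path_factory):
    """Fifty constitutive loci, 10 cell lines x 2 replicates, sigma=20, no noise."""
    cfg = SimulationConfig(n_constitutive_loci=50, seed=11)
    out = tmp_path_factory.mktemp("sim_basic")
    truth, manifest = simulate(cfg, out)
    return cfg, truth, manifest


@pytest.fixture(scope="session")
def full_sim(tmp_path_factory):
    """basic_sim plus 30 cell-line-specific loci (presence prob 0.5) and
    100 background noise peaks per dataset."""
    cfg = SimulationConfig(
        n_constitutive_loci=50,
        n_specific_loci=30,
        specific_presence_prob=0.5,
        noise_peaks_per_dataset=100,
        seed=11,
    )
    out = tmp_path_factory.mktemp("sim_full")
    truth, manifest = simulate(cfg, out)
    return cfg, truth, manifest


@pytest.fixture
def default_config():
    return CallingConfig()
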