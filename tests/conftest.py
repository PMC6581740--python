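import pytest

from apmsdia.pipeline import PipelineConfig, run_pipeline
from apmsdia.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def spike_config():
    """Benchmark screen: 20 spiked interactors among 500 background proteins,
    10 sticky contaminants, default time course, 3 replicates, CV 0.2."""
    return SimConfig(
        n_background_proteins=500, n_true_interactors=20, n_contaminants=10, seed=7
    )


@pytest.fixture(scope="session")
def spike_experiment(spike_config):
    return simulate_experiment(spike_config)


@pytest.fixture(scope="session")
def spike_result(spike_config):
    return run_pipeline(PipelineConfig(sim=spike_config))


@pytest.fixture(scope="session")
def small_experiment():
    """A fast dataset with phospho forms for unit-level checks."""
    cfg = SimConfig(
        n_background_proteins=30,
        n_true_interactors=3,
        n_contaminants=2,
        simulate_phospho=True,
        seed=42,
    )
    return simulate_experiment(cfg)
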