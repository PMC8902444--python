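import pytest

from rxprev import PipelineConfig, SimulationConfig, generate_population_counts, generate_registry
from rxprev.pipeline import run_analysis


@pytest.fixture(scope="session")
def mid_registry():
    """A mid-size synthetic registry exercising every exclusion reason."""
    cfg = SimulationConfig(n_patients=3000, seed=7)
    patients, records = generate_registry(cfg)
    population = generate_population_counts(cfg)
    return cfg, patients, records, population


@pytest.fixture(scope="session")
def mid_analysis(mid_registry):
    """Full analysis of the mid-size registry with default parameters."""
    _, patients, records, population = mid_registry
    return run_analysis(patients, records, population, PipelineConfig())
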