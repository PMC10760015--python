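import numpy as np
import pytest

from rootcycle import pipeline as pl
from rootcycle import simulate as sim


@pytest.fixture
def small_sim_cfg():
    """Generator config scaled down for fast unit tests."""
    return sim.SimulationConfig(
        n_genes=300, n_phase_genes_per_phase=20, n_celltype_genes_per_type=10,
        n_mito_genes=5, seed=123,
    )


@pytest.fixture
def small_libraries(small_sim_cfg):
    cm, meta, program = sim.simulate_synchronized_libraries(small_sim_cfg, 150)
    return cm, meta, program


@pytest.fixture
def small_analysis_cfg():
    return pl.synthetic_analysis_config(123)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
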