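import numpy as np
import pandas as pd
import pytest

from concurgene.synthetic import SimulationConfig, simulate_cohort, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_chromosomes=2,
        markers_per_chromosome=100,
        n_genes=40,
        n_samples=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, probes_per_gene=2)


@pytest.fixture()
def flat_marker_map():
    """One chromosome, 100 evenly spaced markers."""
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(1, 101)],
            "chromosome": "1",
            "position": np.arange(1, 101) * 1000,
        }
    )
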