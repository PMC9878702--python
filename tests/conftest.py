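import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirweave import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One fully simulated study at the default cohort scale."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Reduced dimensions for fast end-to-end style tests."""
    return SimulationConfig(
        n_genes=400,
        n_mirnas=10,
        n_true_regulators=2,
        targets_per_mirna=20,
        corpus_size=60,
        n_pathways=40,
        n_target_enriched_pathways=8,
        n_hallmark_sets=50,
        seed=11,
    )
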