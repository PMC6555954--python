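import numpy as np
import pytest

from ribocodon import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(seed=11, n_genes=60, n_footprints=8000,
                                gene_length_range=(80, 160))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Transcriptome + expression + in-memory footprints shared across tests."""
    tx, truth = sim.simulate_transcriptome(small_config)
    expr = sim.simulate_expression(tx, small_config)
    emap = dict(zip(expr["gene_id"], expr["expr_a"]))
    reads, fp_truth = sim.simulate_footprints(tx, emap, small_config)
    return {
        "config": small_config,
        "tx": tx,
        "truth": truth,
        "expr": emap,
        "reads": reads,
        "footprints": sim.as_footprints(reads, tx),
        "cds": {t.gene_id: (t.cds_start, t.cds_end) for t in tx},
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
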