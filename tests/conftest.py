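import numpy as np
import pytest

from flcdna.alignment import ScoringScheme
from flcdna.simulate import (SimulationConfig, simulate_genome,
                             simulate_transcripts, simulate_study)


@pytest.fixture(scope="session")
def study12():
    """A small synthetic study shared across modules (12 genes, seed 1).

    Contaminant/chimera rates are raised so that every clone class is
    represented at this scale.
    """
    return simulate_study(SimulationConfig(seed=1, n_genes=12,
                                           chimera_rate=0.10,
                                           ncrna_rate=0.05,
                                           pathogen_rate=0.05))


@pytest.fixture(scope="session")
def big_truth():
    """Genome + transcript truth at generator calibration scale (n=2000)."""
    cfg = SimulationConfig(seed=11, n_genes=2000)
    genome, truth = simulate_genome(cfg)
    simulate_transcripts(truth, cfg.isoform_rates, seed=13, config=cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def nuc_scheme():
    return ScoringScheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
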