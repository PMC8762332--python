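from __future__ import annotations

import numpy as np
import pytest

from ribostruct import SimulationConfig, TranscriptModel, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_model(gene_id="g1", utr5_len=40, cds_len=300, covered_cds=90,
               fill=None, rng=None):
    """A transcript model with constant or random scores."""
    n = utr5_len + covered_cds
    if fill is not None:
        scores = np.full(n, float(fill))
    else:
        scores = (rng or np.random.default_rng(0)).normal(size=n)
    return TranscriptModel(gene_id=gene_id, utr5_len=utr5_len,
                           cds_len=cds_len, scores=scores)


@pytest.fixture
def random_models(rng):
    """200 transcripts with varied 5'UTR lengths, some below window sizes."""
    models = []
    for i in range(200):
        utr = int(rng.integers(0, 120))
        covered = int(rng.integers(0, 91))
        models.append(TranscriptModel(
            gene_id=f"g{i:03d}", utr5_len=utr, cds_len=300,
            scores=rng.normal(size=utr + covered)))
    return models


@pytest.fixture(scope="session")
def small_experiment():
    """A 500-gene simulated experiment shared across tests."""
    config = SimulationConfig(n_genes=500, library_size=200_000, seed=11)
    return simulate_experiment(config)
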