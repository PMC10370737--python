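import numpy as np
import pytest

from comolink import SimulationConfig, simulate_disease_pair


def ari_against_blocks(blocks, clusters):
    """Adjusted Rand index of recovered clusters vs planted blocks,
    restricted to the planted genes (unassigned genes become singletons)."""
    from sklearn.metrics import adjusted_rand_score

    truth = {g: i for i, b in enumerate(blocks) for g in b}
    pred = {g: i for i, c in enumerate(clusters) for g in c}
    genes = sorted(truth)
    return adjusted_rand_score(
        [truth[g] for g in genes],
        [pred.get(g, -1 - j) for j, g in enumerate(genes)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_disease_pair():
    """A small simulated disease pair shared across pipeline tests."""
    cfg_a = SimulationConfig(n_genes=400, de_fraction=0.1, seed=11)
    cfg_b = SimulationConfig(n_genes=400, de_fraction=0.1, seed=12)
    return simulate_disease_pair(cfg_a, cfg_b, shared_fraction=0.5)
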