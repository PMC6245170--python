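import numpy as np
import pytest

from netconsensus import PlantedEnsembleSpec, ThresholdedGraph, generate_ensemble


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles on 6 nodes."""
    adj = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        adj[a, b] = adj[b, a] = 1.0
    return ThresholdedGraph(adj, density=6 / 15)


@pytest.fixture
def two_cliques():
    """Two disjoint unit-weight 5-cliques on 10 nodes."""
    adj = np.zeros((10, 10))
    for block in (range(5), range(5, 10)):
        for a in block:
            for b in block:
                if a != b:
                    adj[a, b] = 1.0
    return ThresholdedGraph(adj, density=20 / 45)


@pytest.fixture(scope="session")
def small_planted():
    """Low-noise 60-node, 10-subject planted ensemble (6 communities)."""
    spec = PlantedEnsembleSpec(
        n_nodes=60,
        community_sizes=(10,) * 6,
        n_subjects=10,
        w_in=0.6,
        w_out=0.1,
        weight_sd=0.02,
        seed=7,
    )
    ensemble, truth = generate_ensemble(spec)
    return ensemble, truth.partition


@pytest.fixture(scope="session")
def identical_ensemble():
    """Ensemble of 20 copies of the same 60-node matrix."""
    from netconsensus import SubjectEnsemble

    spec = PlantedEnsembleSpec(
        n_nodes=60,
        community_sizes=(10,) * 6,
        n_subjects=1,
        w_in=0.6,
        w_out=0.1,
        weight_sd=0.02,
        seed=11,
    )
    single, _ = generate_ensemble(spec)
    return SubjectEnsemble(tuple(single.matrices) * 20)
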