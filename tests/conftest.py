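import numpy as np
import pytest
from hypothesis import settings

from netgene.bench import benchmark_cv
from netgene.network import GeneNetwork
from netgene.simulate import SimConfig, generate_planted_network

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def random_network(n_nodes: int, p: float, seed: int, weighted: bool = True) -> GeneNetwork:
    """Erdos-Renyi-style helper used across test modules."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_nodes)]
    triples = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                w = rng.uniform(0.1, 2.0) if weighted else 1.0
                triples.append((genes[i], genes[j], w))
    return GeneNetwork.from_edges(triples, extra_nodes=genes)


@pytest.fixture(scope="session")
def two_block_network() -> GeneNetwork:
    """Two 20-node dense blocks (p=0.5) with sparse cross edges (p=0.02)."""
    rng = np.random.default_rng(0)
    genes = [f"a{i:02d}" for i in range(20)] + [f"b{i:02d}" for i in range(20)]
    triples = []
    for block in (range(0, 20), range(20, 40)):
        for i in block:
            for j in block:
                if i < j and rng.random() < 0.5:
                    triples.append((genes[i], genes[j], 1.0))
    for i in range(20):
        for j in range(20, 40):
            if rng.random() < 0.02:
                triples.append((genes[i], genes[j], 1.0))
    return GeneNetwork.from_edges(triples, extra_nodes=genes)


@pytest.fixture(scope="session")
def planted_recovery_records():
    """Full 500-gene/10-module CV benchmark for seeds 1..3 (shared by the
    module-recovery and acceptance tests)."""
    out = {}
    for seed in (1, 2, 3):
        network, collection = generate_planted_network(SimConfig(seed=seed))
        out[seed] = benchmark_cv(network, collection, seed=seed)
    return out


@pytest.fixture(scope="session")
def density_sweep_points():
    """Per-module (edge density, SL-A auPRC) pairs across a p_within sweep,
    for seeds 1..3."""
    from netgene.evaluate import edge_density

    points = {}
    for seed in (1, 2, 3):
        xs, ys = [], []
        for k, p_within in enumerate((0.05, 0.1, 0.2, 0.4)):
            cfg = SimConfig(
                n_genes=200, n_modules=5, module_size_range=(30, 30),
                p_within=p_within, p_between=0.01, seed=1000 * seed + k,
            )
            network, collection = generate_planted_network(cfg)
            records = benchmark_cv(
                network, collection, methods=("SL-A",), seed=seed
            )
            auprc_by_set = {
                r.geneset_id: r.raw_value for r in records if r.metric == "auPRC"
            }
            for sid, genes in collection.sets.items():
                if sid in auprc_by_set:
                    xs.append(edge_density(network, genes))
                    ys.append(auprc_by_set[sid])
        points[seed] = (xs, ys)
    return points
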