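import numpy as np
import pytest

from neuromapper import MapperParams, compute_lens
from neuromapper.synthetic import SyntheticSpec, gen_blocks, gen_chain, gen_lens_cloud


@pytest.fixture(scope="session")
def blocks_dataset():
    """4 planted blocks x 40 samples, 400 genes, beta=2, sd=1, seed 0."""
    spec = SyntheticSpec(kind="blocks", n_rois=4, samples_per_roi=40, n_genes=400,
                         effect_size=2.0, noise_sd=1.0, seed=0)
    expr, truth = gen_blocks(spec)
    return expr, truth


@pytest.fixture(scope="session")
def blocks_lens(blocks_dataset):
    expr, _ = blocks_dataset
    return compute_lens(expr)


@pytest.fixture(scope="session")
def chain_dataset():
    """8-ROI planted gradient, 30 samples/ROI, beta=2, sd=0.5, seed 0."""
    spec = SyntheticSpec(kind="chain", n_rois=8, samples_per_roi=30,
                         effect_size=2.0, noise_sd=0.5, seed=0)
    expr, positions = gen_chain(spec)
    return expr, positions


@pytest.fixture(scope="session")
def chain_graph(chain_dataset):
    from neuromapper import build_graph

    expr, _ = chain_dataset
    lens = compute_lens(expr)
    return build_graph(expr, lens, MapperParams())


@pytest.fixture(scope="session")
def two_blobs_cloud():
    spec = SyntheticSpec(kind="lens_cloud", shape="two_blobs", n_points=200, seed=0)
    return gen_lens_cloud(spec)


def random_mapper_graph(rng: np.random.Generator, n_samples: int = 30, n_nodes: int = 10):
    """A structurally valid random MapperGraph for oracle-based tests.

    Nodes get random member sets drawn from a shared sample pool and random
    distinct bin indices; edges follow the nerve rule (distinct bins,
    nonempty intersection, weight = intersection size).
    """
    from neuromapper.mapper_core import MapperGraph, MapperNode

    sample_ids = [f"s{i}" for i in range(n_samples)]
    nodes = []
    for nid in range(n_nodes):
        size = int(rng.integers(1, max(2, n_samples // 3)))
        members = frozenset(rng.choice(sample_ids, size=size, replace=False))
        nodes.append(MapperNode(node_id=nid, bin_index=(nid, int(rng.integers(0, 3))), members=members))
    edges = {}
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if nodes[a].bin_index == nodes[b].bin_index:
                continue
            shared = len(nodes[a].members & nodes[b].members)
            if shared and rng.random() < 0.6:
                edges[(a, b)] = shared
    covered = set().union(*(n.members for n in nodes))
    noise = frozenset(s for s in sample_ids if s not in covered)
    return MapperGraph(nodes=nodes, edges=edges, noise_samples=noise,
                       params=MapperParams(), sample_ids=tuple(sample_ids))
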