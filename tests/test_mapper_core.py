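"""Cover construction, per-bin clustering, nerve graph, and metrics."""

import math

import networkx as nx
import numpy as np
import pytest

from neuromapper import MapperParams, build_cover, build_graph, graph_metrics
from neuromapper.lens import lens_from_coords
from neuromapper.mapper_core import (
    MapperGraph,
    MapperNode,
    cluster_bin,
    correlation_distances,
    percentile_windows,
)

from conftest import random_mapper_graph


def window_oracle(w, o):
    """Direct enumeration of the step rule for cross-checking."""
    if w >= 100:
        return [(0.0, 100.0)]
    s = w * (1 - o / 100.0)
    out = []
    k = 0
    while True:
        out.append((k * s, k * s + w))
        if k * s + w >= 100 - 1e-9:
            return out
        k += 1


class TestWindows:
    @pytest.mark.parametrize(
        "w,o,expected",
        [
            (50, 50, [(0, 50), (25, 75), (50, 100)]),
            (100, 0, [(0, 100)]),
            (100, 80, [(0, 100)]),
        ],
    )
    def test_examples(self, w, o, expected):
        got = percentile_windows(w, o)
        assert len(got) == len(expected)
        for (lo, hi), (elo, ehi) in zip(got, expected):
            assert lo == pytest.approx(elo) and hi == pytest.approx(ehi)

    def test_five_pct_quarter_overlap_gives_27(self):
        assert len(percentile_windows(5, 25)) == 27

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            w = float(rng.uniform(2, 100))
            o = float(rng.uniform(0, 99))
            got = percentile_windows(w, o)
            want = window_oracle(w, o)
            assert len(got) == len(want), (w, o)
            # union covers [0, 100]
            assert got[0][0] == 0.0 and got[-1][1] >= 100 - 1e-9


class TestCover:
    def lens(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return lens_from_coords(rng.normal(size=(n, 2)), [f"s{i}" for i in range(n)])

    def test_every_sample_covered(self):
        lens = self.lens()
        cover = build_cover(lens, MapperParams(window_pct=15, overlap_pct=30))
        covered = set().union(*cover.bins.values())
        assert covered == set(range(lens.n_samples))

    def test_zero_overlap_partitions(self):
        lens = self.lens()
        cover = build_cover(lens, MapperParams(window_pct=25, overlap_pct=0))
        counts = np.zeros(lens.n_samples, int)
        for members in cover.bins.values():
            counts[members] += 1
        assert (counts == 1).all()

    def test_low_overlap_bounds_bin_multiplicity(self):
        lens = self.lens(n=80, seed=1)
        for o in (10.0, 30.0, 49.0):
            cover = build_cover(lens, MapperParams(window_pct=20, overlap_pct=o))
            counts = np.zeros(lens.n_samples, int)
            for members in cover.bins.values():
                counts[members] += 1
            assert counts.max() <= 4

    def test_window_widening_grows_memberships(self):
        # for fixed w, raising the overlap only widens per-sample coverage
        lens = self.lens(n=60, seed=2)
        cover_lo = build_cover(lens, MapperParams(window_pct=20, overlap_pct=10))
        cover_hi = build_cover(lens, MapperParams(window_pct=20, overlap_pct=40))
        member_lo = {i: set() for i in range(60)}
        member_hi = {i: set() for i in range(60)}
        for b, mem in cover_lo.bins.items():
            for i in mem:
                member_lo[i].add(b)
        for b, mem in cover_hi.bins.items():
            for i in mem:
                member_hi[i].add(b)
        for i in range(60):
            assert len(member_lo[i]) <= len(member_hi[i])

    def test_constant_dimension_fatal(self):
        coords = np.column_stack([np.ones(10), np.arange(10.0)])
        lens = lens_from_coords(coords, [f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="constant"):
            build_cover(lens, MapperParams())


class TestClusterBin:
    def test_anticorrelated_blocks_split(self):
        # two groups with within-correlation ~1 and cross-correlation ~-1;
        # oracle: single-linkage cut at distance 1 separates them exactly
        rng = np.random.default_rng(4)
        base = rng.normal(size=20)
        values = np.vstack([base + rng.normal(0, 0.01, 20) for _ in range(4)]
                           + [-base + rng.normal(0, 0.01, 20) for _ in range(4)])
        dist = correlation_distances(values)
        clusters, noise = cluster_bin(dist, range(8), MapperParams(min_cluster_size=3))
        assert sorted(len(c) for c in clusters) == [4, 4]
        assert not noise
        assert {frozenset(c) for c in clusters} == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_small_bin_all_noise(self):
        dist = np.zeros((5, 5))
        clusters, noise = cluster_bin(dist, [1, 3], MapperParams(min_cluster_size=3))
        assert clusters == [] and noise == [1, 3]

    def test_identical_samples_one_cluster(self):
        dist = np.zeros((6, 6))
        clusters, noise = cluster_bin(dist, range(6), MapperParams())
        assert clusters == [list(range(6))] and noise == []

    def test_empty_bin(self):
        clusters, noise = cluster_bin(np.zeros((3, 3)), [], MapperParams())
        assert clusters == [] and noise == []


class TestGraph:
    def test_zero_overlap_graph_has_no_edges(self, blocks_dataset, blocks_lens):
        expr, _ = blocks_dataset
        for w in (20.0, 50.0):
            g = build_graph(expr, blocks_lens, MapperParams(window_pct=w, overlap_pct=0))
            assert g.edges == {}

    def test_nerve_consistency(self, chain_graph):
        members = {n.node_id: n.members for n in chain_graph.nodes}
        assert chain_graph.edges, "expected a connected chain graph"
        for (a, b), w in chain_graph.edges.items():
            assert w == len(members[a] & members[b]) > 0
            assert chain_graph.nodes[a].bin_index != chain_graph.nodes[b].bin_index

    def test_noise_disjoint_from_nodes(self, chain_graph):
        covered = set().union(*(n.members for n in chain_graph.nodes))
        assert not (chain_graph.noise_samples & covered)

    def test_planted_chain_component_is_elongated(self, chain_graph):
        # a 1-D gradient should produce one long, thin component: a 2-D
        # cover yields a thick path (overlap cliques push degrees above 2),
        # so elongation is measured by graph diameter instead of degrees
        gx = chain_graph.to_networkx()
        big = gx.subgraph(max(nx.connected_components(gx), key=len))
        assert big.number_of_nodes() >= 20
        assert nx.diameter(big) >= 8

    def test_two_blob_lens_cloud_gives_two_components(self, two_blobs_cloud):
        lens, labels = two_blobs_cloud
        g = build_graph(None, lens, MapperParams(window_pct=30, overlap_pct=50))
        gx = g.to_networkx()
        comps = [c for c in nx.connected_components(gx) if len(c) > 1]
        assert len(comps) == 2
        blobs = []
        for comp in comps:
            mem = set().union(*(g.nodes[n].members for n in comp))
            blobs.append({labels[s] for s in mem})
        assert sorted(map(tuple, blobs)) == [("blob_a",), ("blob_b",)]


class TestMetrics:
    def graph_from_edges(self, n_nodes, edges):
        nodes = [
            MapperNode(node_id=i, bin_index=(i, 0), members=frozenset({f"s{i}"}))
            for i in range(n_nodes)
        ]
        return MapperGraph(
            nodes=nodes,
            edges={(a, b): 1 for a, b in edges},
            noise_samples=frozenset(),
            params=MapperParams(),
            sample_ids=tuple(f"s{i}" for i in range(n_nodes)),
        )

    def test_two_triangles(self):
        g = self.graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert graph_metrics(g)["n_components"] == 2

    def test_edgeless_graph(self):
        g = self.graph_from_edges(5, [])
        m = graph_metrics(g)
        assert m["n_components"] == 5
        assert m["modularity"] == 0.0

    def test_empty_graph(self):
        g = MapperGraph(nodes=[], edges={}, noise_samples=frozenset(),
                        params=MapperParams(), sample_ids=())
        m = graph_metrics(g)
        assert m["n_nodes"] == 0 and m["n_components"] == 0

    def test_component_count_matches_union_find(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            g = random_mapper_graph(rng, n_samples=40, n_nodes=int(rng.integers(3, 20)))
            parent = list(range(len(g.nodes)))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in g.edges:
                parent[find(a)] = find(b)
            n_comp = len({find(i) for i in range(len(g.nodes))})
            assert graph_metrics(g)["n_components"] == n_comp
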