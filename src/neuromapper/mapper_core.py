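"""Equal-density cover, per-bin clustering, and the Mapper nerve graph.

The Mapper construction slices the samples into overlapping 2-D bins along
the lens, clusters each bin independently using the correlation distance
between full gene-expression vectors, and summarizes the result as a graph:
one node per (bin, cluster), one edge per pair of nodes sharing samples.

Windows are placed in *percentile* units of each lens dimension, so every
window holds roughly equal numbers of samples regardless of the lens
marginals (an equal-density cover).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import HDBSCAN

from .lens import Lens

ClusteringMethod = Literal["linkage-gap", "density", "single-linkage"]


@dataclass(frozen=True)
class MapperParams:
    """Free parameters of the Mapper construction.

    window_pct
        Window size ``w`` in percentile units of each lens dimension
        (0 < w <= 100).
    overlap_pct
        Overlap ``o`` between consecutive windows, as a percentage of the
        window (0 <= o < 100). ``o = 0`` tiles the axis disjointly and the
        resulting graph has no edges.
    min_cluster_size
        Minimum samples per cluster / node.
    clustering
        ``linkage-gap`` (default): average-linkage dendrogram cut at the
        first empty bin of the merge-height histogram (``gap_bins`` bins), a
        Mapper-style gap heuristic -- keeps unimodal or gradient bins whole
        while splitting bins that straddle genuinely separated groups.
        ``density``: HDBSCAN on the precomputed distance matrix.
        ``single-linkage``: fixed cut at ``linkage_cut``.
    """

    window_pct: float = 20.0
    overlap_pct: float = 40.0
    min_cluster_size: int = 3
    clustering: ClusteringMethod = "linkage-gap"
    linkage_cut: float = 1.0
    gap_bins: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.window_pct <= 100:
            raise ValueError("window_pct must be in (0, 100]")
        if not 0 <= self.overlap_pct < 100:
            raise ValueError("overlap_pct must be in [0, 100)")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")

    @property
    def sigma(self) -> tuple[float, float]:
        return (self.window_pct, self.overlap_pct)


@dataclass
class Cover:
    """Overlapping percentile windows per lens dimension and their bins."""

    windows: tuple[list[tuple[float, float]], list[tuple[float, float]]]
    bins: dict[tuple[int, int], list[int]]  # bin index pair -> sample indices
    percentiles: np.ndarray  # (n_samples, 2) rank-percentile coordinates


def percentile_windows(window_pct: float, overlap_pct: float) -> list[tuple[float, float]]:
    """Enumerate windows ``[k*s, k*s + w]`` with step ``s = w*(1 - o/100)``.

    The number of windows is ``K = 1 + ceil((100 - w)/s)`` (``K = 1`` for
    ``w = 100``), so the union always covers [0, 100]; the last window may
    extend past 100.
    """
    w, o = float(window_pct), float(overlap_pct)
    if w >= 100.0:
        return [(0.0, 100.0)]
    s = w * (1.0 - o / 100.0)
    # guard the exact-division case against float noise (e.g. 2.0000000003)
    k = math.ceil(round((100.0 - w) / s, 9))
    return [(i * s, i * s + w) for i in range(k + 1)]


def _rank_percentiles(values: np.ndarray) -> np.ndarray:
    """Map values to [0, 100] by average rank; requires >= 2 distinct values."""
    n = len(values)
    if np.ptp(values) < 1e-300 or n < 2:
        raise ValueError("constant lens dimension: cannot build an equal-density cover")
    ranks = rankdata(values, method="average")
    return (ranks - 1.0) / (n - 1.0) * 100.0


def build_cover(lens: Lens, params: MapperParams) -> Cover:
    """Assign every sample to the overlapping percentile bins it falls in.

    Window intervals are closed; for zero overlap they are half-open
    ``[lo, hi)`` with the final window closed, so the tiling is disjoint and
    every sample lands in exactly one bin.
    """
    pct = np.column_stack([_rank_percentiles(lens.coords[:, d]) for d in range(2)])
    wins = tuple(percentile_windows(params.window_pct, params.overlap_pct) for _ in range(2))
    disjoint = params.overlap_pct == 0

    member_windows: list[list[list[int]]] = []  # per dim, per sample, window indices
    for d in range(2):
        per_sample: list[list[int]] = []
        for x in pct[:, d]:
            hits = []
            for k, (lo, hi) in enumerate(wins[d]):
                last = k == len(wins[d]) - 1
                if disjoint and not last:
                    inside = lo <= x < hi
                else:
                    inside = lo <= x <= hi
                if inside:
                    hits.append(k)
            per_sample.append(hits)
        member_windows.append(per_sample)

    bins: dict[tuple[int, int], list[int]] = {}
    for i in range(lens.n_samples):
        for k1 in member_windows[0][i]:
            for k2 in member_windows[1][i]:
                bins.setdefault((k1, k2), []).append(i)
    return Cover(windows=(list(wins[0]), list(wins[1])), bins=bins, percentiles=pct)


@dataclass(frozen=True)
class MapperNode:
    node_id: int
    bin_index: tuple[int, int]
    members: frozenset[str]  # sample ids

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a Mapper node cannot be empty")


@dataclass
class MapperGraph:
    nodes: list[MapperNode]
    edges: dict[tuple[int, int], int]  # (node_id < node_id) -> shared-sample count
    noise_samples: frozenset[str]
    params: MapperParams
    sample_ids: tuple[str, ...] = ()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.node_id,
                bin=node.bin_index,
                n_members=len(node.members),
            )
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def nodes_of_sample(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for node in self.nodes:
            for sid in node.members:
                out.setdefault(sid, []).append(node.node_id)
        return out


def correlation_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - Pearson r`` between rows; constant rows get distance 1."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def cluster_bin(
    dist: np.ndarray, member_idx: Sequence[int], params: MapperParams
) -> tuple[list[list[int]], list[int]]:
    """Cluster one bin of the cover on a precomputed distance matrix.

    Returns ``(clusters, bin_noise)`` as lists of global sample indices.
    Bins smaller than ``min_cluster_size`` yield no clusters; samples the
    density clusterer marks as outliers become bin noise. Deterministic:
    members are processed in sorted order and clusters sorted by their
    smallest member index.
    """
    members = sorted(member_idx)
    if len(members) < params.min_cluster_size:
        return [], members
    sub = dist[np.ix_(members, members)]
    if sub.max() < 1e-12:
        return [list(members)], []
    if params.clustering == "linkage-gap":
        condensed = squareform(sub, checks=False)
        z = linkage(condensed, method="average")
        heights = z[:, 2]
        hist, edges = np.histogram(
            heights, bins=params.gap_bins, range=(0.0, float(heights.max()))
        )
        occupied = np.flatnonzero(hist > 0)
        gaps = [i for i in np.flatnonzero(hist == 0) if i > occupied[0]]
        if not gaps:
            labels = np.zeros(len(members), dtype=int)  # no gap: one cluster
        else:
            labels = fcluster(z, t=float(edges[gaps[0]]), criterion="distance")
    elif params.clustering == "density":
        # Excess-of-mass selection never returns the tree root, so a bin
        # holding one homogeneous cluster would come back all-noise; retry
        # allowing the single-cluster (root) solution in that case.
        labels = None
        for allow_single in (False, True):
            model = HDBSCAN(
                min_cluster_size=params.min_cluster_size,
                min_samples=2,
                metric="precomputed",
                allow_single_cluster=allow_single,
                copy=True,
            )
            labels = model.fit_predict(sub)
            if (labels != -1).any():
                break
    else:
        condensed = squareform(sub, checks=False)
        merged = fcluster(linkage(condensed, method="single"), t=params.linkage_cut,
                          criterion="distance")
        labels = np.asarray(merged)
    clusters: dict[int, list[int]] = {}
    noise: list[int] = []
    for local, lab in enumerate(labels):
        if lab == -1:
            noise.append(members[local])
        else:
            clusters.setdefault(int(lab), []).append(members[local])
    out: list[list[int]] = []
    for lab in sorted(clusters):
        group = clusters[lab]
        if len(group) >= params.min_cluster_size:
            out.append(sorted(group))
        else:
            noise.extend(group)
    out.sort(key=lambda c: c[0])
    return out, sorted(noise)


def build_graph(expr, lens: Lens, params: MapperParams) -> MapperGraph:
    """Run the full Mapper construction: cover -> per-bin clusters -> nerve.

    ``expr`` is an ExpressionMatrix whose rows align with ``lens``; pass
    ``expr=None`` to cluster on Euclidean distance in lens space instead
    (used for raw point-cloud geometries with no expression data).
    """
    if expr is not None and expr.n_samples != lens.n_samples:
        raise ValueError("expression matrix and lens disagree on sample count")
    cover = build_cover(lens, params)
    if expr is not None:
        dist = correlation_distances(np.asarray(expr.values, dtype=float))
        sample_ids = tuple(expr.sample_ids)
    else:
        diff = lens.coords[:, None, :] - lens.coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        sample_ids = tuple(lens.sample_ids)

    nodes: list[MapperNode] = []
    node_members_idx: list[set[int]] = []
    for bin_idx in sorted(cover.bins):
        clusters, _ = cluster_bin(dist, cover.bins[bin_idx], params)
        for cl in clusters:
            nodes.append(
                MapperNode(
                    node_id=len(nodes),
                    bin_index=bin_idx,
                    members=frozenset(sample_ids[i] for i in cl),
                )
            )
            node_members_idx.append(set(cl))

    edges: dict[tuple[int, int], int] = {}
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if nodes[a].bin_index == nodes[b].bin_index:
                continue
            shared = len(node_members_idx[a] & node_members_idx[b])
            if shared:
                edges[(a, b)] = shared

    covered: set[int] = set().union(*node_members_idx) if node_members_idx else set()
    noise = frozenset(sample_ids[i] for i in range(len(sample_ids)) if i not in covered)
    return MapperGraph(
        nodes=nodes, edges=edges, noise_samples=noise, params=params, sample_ids=sample_ids
    )


def component_sample_labels(graph: MapperGraph) -> dict[str, int]:
    """Majority connected-component index per covered sample.

    Components are numbered by their smallest node id, so labels are
    deterministic; a sample appearing in nodes of several components gets
    the component containing most of its nodes (ties to the lower index).
    """
    g = graph.to_networkx()
    comps = sorted(nx.connected_components(g), key=min)
    comp_of_node = {n: ci for ci, comp in enumerate(comps) for n in comp}
    votes: dict[str, list[int]] = {}
    for node in graph.nodes:
        for sid in node.members:
            votes.setdefault(sid, []).append(comp_of_node[node.node_id])
    return {
        sid: min(set(v), key=lambda c: (-v.count(c), c)) for sid, v in votes.items()
    }


# ---------------------------------------------------------------------------
# Metrics


def graph_metrics(graph: MapperGraph, modularity_seed: int = 0) -> dict[str, float]:
    """Basic network features used for parameter selection.

    Modularity is that of the best partition found by seeded Louvain; an
    edgeless graph has modularity 0 by convention.
    """
    n_total = len(graph.sample_ids) if graph.sample_ids else None
    if not graph.nodes:
        return {
            "n_nodes": 0, "n_edges": 0, "n_components": 0,
            "largest_component_samples": 0, "noise_fraction": 1.0 if n_total else 0.0,
            "modularity": 0.0,
        }
    g = graph.to_networkx()
    comps = list(nx.connected_components(g))
    members = {node.node_id: node.members for node in graph.nodes}
    largest = max(len(set().union(*(members[n] for n in comp))) for comp in comps)
    if g.number_of_edges() == 0:
        q = 0.0
    else:
        parts = nx.community.louvain_communities(g, weight="weight", seed=modularity_seed)
        q = nx.community.modularity(g, parts, weight="weight")
    if n_total:
        noise_fraction = len(graph.noise_samples) / n_total
    else:
        noise_fraction = 0.0
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_components": len(comps),
        "largest_component_samples": largest,
        "noise_fraction": noise_fraction,
        "modularity": float(q),
    }


# ---------------------------------------------------------------------------
# Export


def write_graph(
    graph: MapperGraph,
    annotations_by_id: Mapping[str, str] | None,
    graphml_path: str | Path | None = None,
    membership_tsv: str | Path | None = None,
    metrics_json: str | Path | None = None,
) -> None:
    """Write GraphML, a node-membership TSV, and a metrics JSON."""
    if graphml_path is not None:
        g = graph.to_networkx()
        for node in graph.nodes:
            comp: dict[str, int] = {}
            if annotations_by_id:
                for sid in node.members:
                    roi = annotations_by_id.get(sid, "?")
                    comp[roi] = comp.get(roi, 0) + 1
            g.nodes[node.node_id]["bin"] = f"{node.bin_index[0]},{node.bin_index[1]}"
            g.nodes[node.node_id]["roi_composition"] = json.dumps(comp, sort_keys=True)
        nx.write_graphml(g, graphml_path)
    if membership_tsv is not None:
        with open(membership_tsv, "w") as fh:
            fh.write("node_id\tsample_id\n")
            for node in graph.nodes:
                for sid in sorted(node.members):
                    fh.write(f"{node.node_id}\t{sid}\n")
    if metrics_json is not None:
        Path(metrics_json).write_text(json.dumps(graph_metrics(graph), indent=2))


def edge_list_lines(graph: MapperGraph) -> list[str]:
    """Canonical sorted edge list (for determinism checks and export)."""
    return [f"{a}\t{b}\t{w}" for (a, b), w in sorted(graph.edges.items())]
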