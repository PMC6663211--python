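"""Seeded shortest-path (hop) distances across the Mapper graph.

Given one or more seed ROIs (e.g. the ventral tegmental area or substantia
nigra, origin of the dopaminergic pathway), this module finds the nodes of
the main connected component containing seed-ROI samples, computes
unweighted hop distances from those seeds to every node in the component,
maps node distances to samples (mean over the nodes containing each
sample), and reports per-ROI distance distributions ranked from closest to
farthest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .mapper_core import MapperGraph


@dataclass
class PathDistanceResult:
    node_distance: dict[int, int]
    sample_distance: dict[str, float]
    roi_distributions: dict[str, list[float]]
    roi_ranking: list[str]
    excluded_samples: int  # samples with no main-component node


def main_component(graph: MapperGraph) -> set[int]:
    """Node ids of the main connected component.

    Largest by node count; ties broken by total member count, then by the
    lexicographically smallest node id, so the choice is deterministic.
    """
    if not graph.nodes:
        raise ValueError("empty graph has no main component")
    g = graph.to_networkx()
    members = {n.node_id: n.members for n in graph.nodes}
    comps = [set(c) for c in nx.connected_components(g)]
    return max(
        comps,
        key=lambda c: (len(c), sum(len(members[n]) for n in c), -min(c)),
    )


def seed_nodes(graph: MapperGraph, seed_rois: Iterable[str], roi_by_sample: Mapping[str, str]) -> set[int]:
    """Main-component nodes containing at least one sample from a seed ROI."""
    rois = set(seed_rois)
    if not rois:
        raise ValueError("seed_rois must be non-empty")
    comp = main_component(graph)
    seeds = {
        n.node_id
        for n in graph.nodes
        if n.node_id in comp and any(roi_by_sample.get(s) in rois for s in n.members)
    }
    if not seeds:
        raise ValueError(
            f"no node of the main component contains samples from seed ROIs {sorted(rois)}"
        )
    return seeds


def node_distances(graph: MapperGraph, seeds: set[int]) -> dict[int, int]:
    """Unweighted hop distance of every main-component node, min over seeds."""
    comp = main_component(graph)
    if not seeds <= comp:
        raise ValueError("seeds must lie in the main component")
    g = graph.to_networkx().subgraph(comp)
    dist: dict[int, int] = {}
    for s in sorted(seeds):
        for n, d in nx.single_source_shortest_path_length(g, s).items():
            if n not in dist or d < dist[n]:
                dist[n] = d
    return dist


def sample_distances(graph: MapperGraph, node_distance: Mapping[int, int]) -> tuple[dict[str, float], int]:
    """Mean node distance per sample; samples with no scored node excluded.

    Returns (sample_distance, n_excluded) where n_excluded counts samples
    that belong only to noise or to minor components.
    """
    per_sample: dict[str, list[int]] = {}
    for node in graph.nodes:
        if node.node_id in node_distance:
            for sid in node.members:
                per_sample.setdefault(sid, []).append(node_distance[node.node_id])
    out = {sid: float(np.mean(ds)) for sid, ds in per_sample.items()}
    total = len(graph.sample_ids) if graph.sample_ids else len(
        {s for n in graph.nodes for s in n.members} | set(graph.noise_samples)
    )
    return out, total - len(out)


def roi_distance_report(
    sample_distance: Mapping[str, float], roi_by_sample: Mapping[str, str]
) -> tuple[dict[str, list[float]], list[str]]:
    """Group sample distances by ROI and rank ROIs by mean, ascending."""
    if not sample_distance:
        raise ValueError("no sample distances to report")
    dists: dict[str, list[float]] = {}
    for sid, d in sample_distance.items():
        dists.setdefault(roi_by_sample[sid], []).append(d)
    for v in dists.values():
        v.sort()
    ranking = sorted(dists, key=lambda roi: (float(np.mean(dists[roi])), roi))
    return dists, ranking


def path_distance_analysis(
    graph: MapperGraph, seed_rois: Iterable[str], roi_by_sample: Mapping[str, str]
) -> PathDistanceResult:
    """Run the full seeded analysis: seeds -> node -> sample -> ROI report."""
    seeds = seed_nodes(graph, seed_rois, roi_by_sample)
    ndist = node_distances(graph, seeds)
    sdist, excluded = sample_distances(graph, ndist)
    distributions, ranking = roi_distance_report(sdist, roi_by_sample)
    return PathDistanceResult(
        node_distance=ndist,
        sample_distance=sdist,
        roi_distributions=distributions,
        roi_ranking=ranking,
        excluded_samples=excluded,
    )


def write_path_result(
    result: PathDistanceResult,
    roi_by_sample: Mapping[str, str],
    out_dir: str | Path,
    mni_by_sample: Mapping[str, tuple[float, float, float]] | None = None,
) -> None:
    """Export sample distances, per-ROI summaries, and the ROI ranking."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in sorted(result.sample_distance):
        row = {
            "sample_id": sid,
            "roi": roi_by_sample.get(sid, ""),
            "distance": result.sample_distance[sid],
        }
        if mni_by_sample and sid in mni_by_sample:
            row["mni_x"], row["mni_y"], row["mni_z"] = mni_by_sample[sid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "sample_distances.tsv", sep="\t", index=False)
    summary = [
        {
            "roi": roi,
            "n": len(result.roi_distributions[roi]),
            "mean": float(np.mean(result.roi_distributions[roi])),
            "median": float(np.median(result.roi_distributions[roi])),
        }
        for roi in result.roi_ranking
    ]
    pd.DataFrame(summary).to_csv(out / "roi_distances.tsv", sep="\t", index=False)
    (out / "roi_ranking.json").write_text(json.dumps(result.roi_ranking, indent=2))
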