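"""Parameter sweep over (window, overlap) grids and optimal-set selection.

Rather than committing to a single scale, the pipeline builds one Mapper
graph per parameter pair sigma = (window_pct, overlap_pct), scores each with
basic network features, and selects an optimal set by a transparent policy:
drop noisy or edgeless graphs, keep the Pareto front on (low noise fraction,
high modularity), cap at top_k by modularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import pandas as pd

from .lens import Lens
from .mapper_core import MapperGraph, MapperParams, build_graph, graph_metrics

logger = logging.getLogger(__name__)

Sigma = tuple[float, float]


@dataclass
class SelectionPolicy:
    """Filters and ranking used by :func:`select_optimal`."""

    max_noise_fraction: float = 0.2
    top_k: int = 4
    require_edges: bool = True


@dataclass
class SweepResult:
    """One scored row per grid point, with the built graphs cached."""

    table: pd.DataFrame  # indexed by sigma, metric columns + 'selected'/'failed'
    graphs: dict[Sigma, MapperGraph] = field(default_factory=dict)

    def selected_sigmas(self) -> list[Sigma]:
        return [s for s in self.table.index[self.table["selected"]]]

    def selected_graphs(self) -> dict[Sigma, MapperGraph]:
        return {s: self.graphs[s] for s in self.selected_sigmas()}


def default_grid(
    windows: Sequence[float] = (5.0, 6.0), overlaps: Sequence[float] = (20.0, 25.0, 30.0, 35.0)
) -> list[Sigma]:
    """Cartesian grid of (window, overlap) pairs, lexicographically ordered."""
    return sorted(product(map(float, windows), map(float, overlaps)))


def sweep(
    expr,
    lens: Lens,
    grid: Sequence[Sigma],
    base_params: MapperParams | None = None,
) -> SweepResult:
    """Build and score one Mapper graph per sigma in the grid.

    A fatal error at one sigma marks that row failed and the sweep
    continues. ``base_params`` carries the non-sigma settings
    (min_cluster_size, clustering method).
    """
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    base = base_params or MapperParams()
    rows: list[dict] = []
    graphs: dict[Sigma, MapperGraph] = {}
    for w, o in sorted(set((float(a), float(b)) for a, b in grid)):
        sigma: Sigma = (w, o)
        row: dict = {"window_pct": w, "overlap_pct": o, "failed": False}
        try:
            params = MapperParams(
                window_pct=w,
                overlap_pct=o,
                min_cluster_size=base.min_cluster_size,
                clustering=base.clustering,
                linkage_cut=base.linkage_cut,
            )
            graph = build_graph(expr, lens, params)
            graphs[sigma] = graph
            row.update(graph_metrics(graph))
        except (ValueError, RuntimeError) as exc:  # record, keep sweeping
            logger.warning("sweep: sigma=%s failed: %s", sigma, exc)
            row["failed"] = True
        rows.append(row)
    table = pd.DataFrame(rows).set_index(["window_pct", "overlap_pct"])
    table.index = [tuple(ix) for ix in table.index]
    table["selected"] = False
    return SweepResult(table=table, graphs=graphs)


def pareto_front(points: Sequence[tuple[float, float]]) -> list[int]:
    """Indices on the Pareto front of (minimize first, maximize second)."""
    front = []
    for i, (ni, qi) in enumerate(points):
        dominated = any(
            (nj <= ni and qj >= qi) and (nj < ni or qj > qi)
            for j, (nj, qj) in enumerate(points)
            if j != i
        )
        if not dominated:
            front.append(i)
    return front


def select_optimal(
    result: SweepResult, policy: SelectionPolicy | None = None
) -> list[Sigma]:
    """Pick the optimal sigma set; marks ``selected`` rows in the table.

    Policy: drop failed rows, rows with noise fraction above
    ``max_noise_fraction``, and (by default) edgeless graphs; keep the
    Pareto front on (minimize noise fraction, maximize modularity); if the
    front exceeds ``top_k``, keep the top_k by modularity. Ties broken by
    (window, overlap) lexicographic order, so the selection is deterministic
    and independent of row order.
    """
    policy = policy or SelectionPolicy()
    table = result.table
    ok = table.index[
        (~table["failed"])
        & (table["noise_fraction"] <= policy.max_noise_fraction)
        & ((table["n_edges"] > 0) if policy.require_edges else True)
    ]
    survivors = sorted(ok)  # lexicographic (window, overlap)
    if not survivors:
        raise ValueError(
            "no parameter set passed the noise/edge filters; expand the sweep grid "
            "or raise max_noise_fraction"
        )
    pts = [
        (float(table.loc[[s], "noise_fraction"].iloc[0]), float(table.loc[[s], "modularity"].iloc[0]))
        for s in survivors
    ]
    front = [survivors[i] for i in pareto_front(pts)]
    if len(front) > policy.top_k:
        front = sorted(front, key=lambda s: (-float(table.loc[[s], "modularity"].iloc[0]), s))
        front = sorted(front[: policy.top_k])
    table["selected"] = [s in set(front) for s in table.index]
    return sorted(front)


def write_sweep_table(result: SweepResult, path: str | Path) -> None:
    out = result.table.copy()
    out.insert(0, "window_pct", [s[0] for s in out.index])
    out.insert(1, "overlap_pct", [s[1] for s in out.index])
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
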