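"""ROI co-occurrence matrices per graph and the cross-sigma agreement matrix.

The co-occurrence matrix A[sigma] counts, for each pair of regions of
interest (i, j), how many times a sample from ROI i and a sample from ROI j
land in the same Mapper node; the diagonal holds the within-ROI unordered
pair counts m(m-1)/2. The agreement matrix averages the A[sigma] of the
selected parameter sets and keeps only the entries that are nonzero in
every contributing network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapper_core import MapperGraph, MapperParams


@dataclass
class CooccurrenceMatrix:
    roi_order: list[str]
    counts: np.ndarray
    sigma: tuple[float, float] | None = None
    subset_id: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.roi_order)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over roi_order")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("co-occurrence counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("co-occurrence counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.roi_order, columns=self.roi_order)


@dataclass
class AgreementMatrix:
    roi_order: list[str]
    values: np.ndarray
    sigmas: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_order, columns=self.roi_order)


def cooccurrence(
    graph: MapperGraph,
    roi_by_sample: Mapping[str, str],
    subset: Iterable[str] | None = None,
    roi_order: Sequence[str] | None = None,
) -> CooccurrenceMatrix:
    """Count per-node ROI pair co-occurrences over a Mapper graph.

    For a node whose members contain ``m_i`` samples of ROI i:
    ``counts[i, j] += m_i * m_j`` for i != j and
    ``counts[i, i] += m_i * (m_i - 1) / 2``; a sample pair sharing several
    nodes is counted once per node. If ``subset`` is given, only samples in
    it are counted (the graph itself is unchanged).
    """
    unlabeled = sorted(
        {sid for node in graph.nodes for sid in node.members if sid not in roi_by_sample}
    )
    if unlabeled:
        raise ValueError(f"samples without ROI label: {unlabeled[:10]}")
    subset_set = set(subset) if subset is not None else None
    if roi_order is None:
        roi_order = sorted(set(roi_by_sample.values()))
    index = {roi: k for k, roi in enumerate(roi_order)}
    counts = np.zeros((len(roi_order), len(roi_order)))
    for node in graph.nodes:
        members = node.members if subset_set is None else node.members & subset_set
        tallies: dict[str, int] = {}
        for sid in members:
            tallies[roi_by_sample[sid]] = tallies.get(roi_by_sample[sid], 0) + 1
        rois = [r for r in tallies if r in index]
        for a_pos, roi_a in enumerate(rois):
            ia, ma = index[roi_a], tallies[roi_a]
            counts[ia, ia] += ma * (ma - 1) / 2
            for roi_b in rois[a_pos + 1 :]:
                ib, mb = index[roi_b], tallies[roi_b]
                counts[ia, ib] += ma * mb
                counts[ib, ia] += ma * mb
    return CooccurrenceMatrix(
        roi_order=list(roi_order),
        counts=counts,
        sigma=graph.params.sigma if isinstance(graph.params, MapperParams) else None,
    )


def agreement(matrices: Sequence[CooccurrenceMatrix]) -> AgreementMatrix:
    """Average co-occurrence matrices, masking entries absent in any input.

    Inputs are re-indexed to the ROI order of the first matrix (labels must
    coincide as sets). The output value at (i, j) is the elementwise mean if
    every input has a nonzero entry there, else 0.
    """
    if not matrices:
        raise ValueError("agreement needs at least one co-occurrence matrix")
    order = list(matrices[0].roi_order)
    stacked = []
    for m in matrices:
        if list(m.roi_order) == order:
            stacked.append(m.counts)
        else:
            if set(m.roi_order) != set(order):
                raise ValueError("co-occurrence matrices cover different ROI sets")
            perm = [m.roi_order.index(r) for r in order]
            stacked.append(m.counts[np.ix_(perm, perm)])
    arr = np.stack(stacked)
    mean = arr.mean(axis=0)
    support = (arr > 0).all(axis=0)
    return AgreementMatrix(
        roi_order=order,
        values=np.where(support, mean, 0.0),
        sigmas=[m.sigma for m in matrices if m.sigma is not None],
    )


def write_matrix(
    matrix: CooccurrenceMatrix | AgreementMatrix, tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the ROI x ROI matrix as labelled TSV plus a JSON sidecar."""
    matrix.to_frame().to_csv(tsv_path, sep="\t", float_format="%.17g")
    if json_path is not None:
        meta: dict = {"diagonal": "within-ROI unordered pair counts m(m-1)/2"}
        if isinstance(matrix, AgreementMatrix):
            meta["sigmas"] = [list(s) for s in matrix.sigmas]
        else:
            meta["sigma"] = list(matrix.sigma) if matrix.sigma else None
            meta["subset_id"] = matrix.subset_id
        Path(json_path).write_text(json.dumps(meta, indent=2))


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labelled ROI x ROI TSV back as (roi_order, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return [str(r) for r in df.index], df.to_numpy(dtype=float)
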