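"""The 2-D filter (lens) guiding the Mapper cover.

The lens coordinates are the sample scores on the top-2 eigencomponents of
the sample x sample Pearson correlation matrix (default) or covariance
matrix of the z-scored expression data. Working on the sample-level matrix
keeps the embedding a function of between-sample similarity, which is also
what the per-bin clustering uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

LensMode = Literal["correlation", "covariance"]

# eigenvalues below this fraction of the trace are treated as null space
_NULL_EIGENVALUE_FRACTION = 1e-12


@dataclass(frozen=True)
class Lens:
    """Per-sample 2-D filter coordinates plus spectrum bookkeeping."""

    coords: np.ndarray  # (n_samples, 2)
    variance_explained: tuple[float, float]
    mode: LensMode
    sample_ids: tuple[str, ...]
    full_spectrum: np.ndarray | None = None  # eigenvalues / trace, descending

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("lens coordinates must be an (n, 2) array")
        if coords.shape[0] != len(self.sample_ids):
            raise ValueError("one coordinate pair per sample required")
        if any(v < -1e-12 for v in self.variance_explained):
            raise ValueError("variance_explained must be non-negative")
        object.__setattr__(self, "coords", coords)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]


def compute_lens(expr, mode: LensMode = "correlation") -> Lens:
    """Embed samples on the top-2 eigencomponents of their similarity matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Z-scored expression with >= 3 samples.
    mode
        ``correlation`` (default) uses the sample x sample Pearson
        correlation matrix; ``covariance`` the sample covariance matrix
        (over genes).

    Returns
    -------
    Lens
        Coordinates carry a deterministic sign convention: within each
        component the entry of largest magnitude is positive. Variance
        explained is eigenvalue / trace.
    """
    if mode not in ("correlation", "covariance"):
        raise ValueError(f"unknown lens mode {mode!r}")
    values = np.asarray(expr.values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("lens needs at least 3 samples")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if mode == "correlation":
        if np.any(norms < 1e-12):
            # constant sample rows have undefined correlation; treat as
            # uncorrelated with everything
            safe = np.where(norms < 1e-12, 1.0, norms)
            unit = centered / safe[:, None]
        else:
            unit = centered / norms[:, None]
        sim = unit @ unit.T
        np.fill_diagonal(sim, 1.0)
    else:
        sim = centered @ centered.T / (values.shape[1] - 1)
    sim = (sim + sim.T) / 2.0

    eigvals, eigvecs = np.linalg.eigh(sim)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    trace = float(np.trace(sim))
    if trace <= 0 or eigvals[1] < _NULL_EIGENVALUE_FRACTION * max(trace, 1.0):
        # rank < 2: no second filter dimension exists (e.g. all samples identical)
        raise ValueError("degenerate similarity matrix: samples are (nearly) identical")
    eigvals = np.clip(eigvals, 0.0, None)

    coords = np.empty((sim.shape[0], 2))
    for k in range(2):
        v = eigvecs[:, k]
        # deterministic sign: largest-magnitude loading positive
        pivot = int(np.argmax(np.abs(v)))
        if v[pivot] < 0:
            v = -v
        coords[:, k] = v * np.sqrt(eigvals[k])
    var = eigvals / trace
    return Lens(
        coords=coords,
        variance_explained=(float(var[0]), float(var[1])),
        mode=mode,
        sample_ids=tuple(expr.sample_ids),
        full_spectrum=var,
    )


def write_lens(lens: Lens, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Export lens coordinates as TSV plus a JSON sidecar with the spectrum."""
    pd.DataFrame(
        {"sample_id": lens.sample_ids, "pc1": lens.coords[:, 0], "pc2": lens.coords[:, 1]}
    ).to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {"variance_explained": list(lens.variance_explained), "mode": lens.mode},
                indent=2,
            )
        )


def lens_from_coords(
    coords: np.ndarray, sample_ids: Sequence[str], mode: LensMode = "correlation"
) -> Lens:
    """Wrap externally supplied 2-D coordinates (e.g. synthetic clouds) as a Lens."""
    coords = np.asarray(coords, dtype=float)
    return Lens(
        coords=coords,
        variance_explained=(0.0, 0.0),
        mode=mode,
        sample_ids=tuple(sample_ids),
    )
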