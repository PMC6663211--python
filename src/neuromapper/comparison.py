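"""Compare Mapper link structure against an external ROI x ROI matrix.

The agreement matrix defines which ROI pairs are linked ("present") in the
Mapper networks. Given an external symmetric matrix over the same ROIs --
differential-expression gene counts or fMRI functional connectivity -- this
module splits the external values into present/absent/all multisets,
measures the separation of their empirical distribution functions with the
two-sample Kolmogorov-Smirnov statistic D (used descriptively; no p-value),
locates the trade-off threshold tau at the maximum ECDF gap, and classifies
each linked pair into {dense, sparse} x {low, high} regimes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .aggregation import AgreementMatrix

ExternalKind = Literal["differential_expression", "functional_connectivity", "other"]
Regime = Literal["dense_low", "dense_high", "sparse_low", "sparse_high", "absent"]


@dataclass
class ExternalMatrix:
    """Symmetric external comparison matrix (e.g. DE counts, FC)."""

    roi_order: list[str]
    values: np.ndarray
    kind: ExternalKind = "other"
    transform: Literal["none", "log"] = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_order)
        if self.values.shape != (n, n):
            raise ValueError("external matrix must be square over roi_order")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("external matrix must be symmetric")


def ks_statistic(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic and the location of the maximum ECDF gap.

    ``D = max over pooled values of |ECDF_a(x) - ECDF_b(x)|``; the returned
    location is the smallest pooled value attaining the maximum. ECDFs are
    right-continuous (value counted at its own position).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic needs two non-empty samples")
    pooled = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    gaps = np.abs(cdf_a - cdf_b)
    # smallest pooled value attaining the maximum (ties within float noise)
    best = int(np.flatnonzero(gaps >= gaps.max() - 1e-12)[0])
    return float(gaps.max()), float(pooled[best])


def split_pairs(
    agreement: AgreementMatrix, external: ExternalMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Partition external values over common ROI pairs by Mapper link presence.

    Returns (present, absent, all, common_pairs) where a pair (i < j) is
    present iff the agreement entry is nonzero; the diagonal is excluded.
    ROI labels not shared by both matrices are dropped.
    """
    common = [r for r in agreement.roi_order if r in set(external.roi_order)]
    if len(common) < 2:
        raise ValueError("need at least 2 ROIs common to both matrices")
    ai = {r: agreement.roi_order.index(r) for r in common}
    ei = {r: external.roi_order.index(r) for r in common}
    present, absent, all_vals, pairs = [], [], [], []
    for p in range(len(common)):
        for q in range(p + 1, len(common)):
            r1, r2 = common[p], common[q]
            v = external.values[ei[r1], ei[r2]]
            all_vals.append(v)
            pairs.append((r1, r2))
            if agreement.values[ai[r1], ai[r2]] > 0:
                present.append(v)
            else:
                absent.append(v)
    return (np.asarray(present), np.asarray(absent), np.asarray(all_vals), pairs)


@dataclass
class ComparisonResult:
    present_values: np.ndarray
    absent_values: np.ndarray
    all_values: np.ndarray
    D_present_vs_all: float
    D_present_vs_absent: float
    tau: float | None
    direction: Literal["present_lower", "present_higher"]
    transform: Literal["none", "log"] = "none"
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def compare(agreement: AgreementMatrix, external: ExternalMatrix) -> ComparisonResult:
    """Full present-vs-absent comparison with KS distances and trade-off tau.

    When ``external.transform == 'log'`` the natural log is applied to the
    external values first (nonpositive values are a fatal error), so tau is
    on the log scale (exp(tau) gives the natural-scale threshold).
    """
    present, absent, all_vals, _ = split_pairs(agreement, external)
    if external.transform == "log":
        for arr in (present, absent, all_vals):
            if arr.size and arr.min() <= 0:
                raise ValueError("log transform requires strictly positive external values")
        present, absent, all_vals = np.log(present), np.log(absent), np.log(all_vals)
    if present.size == 0 or absent.size == 0:
        raise ValueError(
            "degenerate agreement matrix: links are "
            + ("all present" if absent.size == 0 else "all absent")
        )
    d_all, _ = ks_statistic(present, all_vals)
    d_abs, tau = ks_statistic(present, absent)

    pooled = np.unique(np.concatenate([present, absent]))
    cdf_p = np.searchsorted(np.sort(present), pooled, side="right") / present.size
    cdf_a = np.searchsorted(np.sort(absent), pooled, side="right") / absent.size
    diff = cdf_p - cdf_a
    direction = "present_lower" if diff.mean() >= 0 else "present_higher"
    if d_abs == 0.0:
        tau = None

    hist_bins = np.histogram_bin_edges(np.concatenate([present, absent]), bins=20)
    tables = {
        "cumulative": pd.DataFrame(
            {"value": pooled, "cdf_present": cdf_p, "cdf_absent": cdf_a, "difference": diff}
        ),
        "histogram": pd.DataFrame(
            {
                "bin_left": hist_bins[:-1],
                "bin_right": hist_bins[1:],
                "count_present": np.histogram(present, bins=hist_bins)[0],
                "count_absent": np.histogram(absent, bins=hist_bins)[0],
            }
        ),
    }
    return ComparisonResult(
        present_values=present,
        absent_values=absent,
        all_values=all_vals,
        D_present_vs_all=d_all,
        D_present_vs_absent=d_abs,
        tau=tau,
        direction=direction,
        transform=external.transform,
        tables=tables,
    )


@dataclass
class RegimeMatrix:
    roi_order: list[str]
    labels: dict[tuple[str, str], Regime]  # keyed by (roi_i, roi_j), i < j in roi_order
    dense_threshold: float
    value_threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"roi_a": a, "roi_b": b, "regime": lab}
            for (a, b), lab in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["roi_a", "roi_b", "regime"])

    def collapse_low(self) -> dict[tuple[str, str], str]:
        """Three-regime view: merge {sparse_low, dense_low} into 'low'."""
        return {
            k: ("low" if v in ("sparse_low", "dense_low") else v)
            for k, v in self.labels.items()
        }


def classify_regimes(
    agreement: AgreementMatrix,
    external: ExternalMatrix,
    dense_threshold: float = 2.0,
    tau: float | None = None,
) -> RegimeMatrix:
    """Label every common ROI pair with its connectivity/value regime.

    A present link is *dense* iff its agreement value is strictly greater
    than ``dense_threshold`` (default 2 average co-occurrences) and *low*
    iff its (transformed) external value is <= tau. Pairs with zero
    agreement are labelled ``absent``.
    """
    if tau is None:
        raise ValueError("tau undefined; run compare() or supply an explicit threshold")
    present, absent, all_vals, pairs = split_pairs(agreement, external)
    ai = {r: agreement.roi_order.index(r) for r in agreement.roi_order}
    ei = {r: external.roi_order.index(r) for r in external.roi_order}
    labels: dict[tuple[str, str], Regime] = {}
    for r1, r2 in pairs:
        a_val = agreement.values[ai[r1], ai[r2]]
        if a_val == 0:
            labels[(r1, r2)] = "absent"
            continue
        e_val = external.values[ei[r1], ei[r2]]
        if external.transform == "log":
            e_val = np.log(e_val)
        density = "dense" if a_val > dense_threshold else "sparse"
        level = "low" if e_val <= tau else "high"
        labels[(r1, r2)] = f"{density}_{level}"  # type: ignore[assignment]
    order = [r for r in agreement.roi_order if r in ei]
    return RegimeMatrix(
        roi_order=order, labels=labels, dense_threshold=dense_threshold, value_threshold=tau
    )


def regime_counts_per_roi(regimes: RegimeMatrix) -> pd.DataFrame:
    """Per-ROI counts of incident pairs in each regime (rows: ROI)."""
    cats = ["dense_low", "dense_high", "sparse_low", "sparse_high", "absent"]
    counts = {roi: {c: 0 for c in cats} for roi in regimes.roi_order}
    for (a, b), lab in regimes.labels.items():
        counts[a][lab] += 1
        counts[b][lab] += 1
    return pd.DataFrame.from_dict(counts, orient="index", columns=cats).loc[
        list(regimes.roi_order)
    ]


def read_external_tsv(
    path: str | Path,
    kind: ExternalKind = "other",
    transform: Literal["none", "log"] = "none",
) -> ExternalMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExternalMatrix(
        roi_order=[str(r) for r in df.index],
        values=df.to_numpy(dtype=float),
        kind=kind,
        transform=transform,
    )


def write_comparison(result: ComparisonResult, out_dir: str | Path, prefix: str = "comparison") -> None:
    """Write the JSON summary and the distribution tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{prefix}.json").write_text(
        json.dumps(
            {
                "D_present_vs_all": result.D_present_vs_all,
                "D_present_vs_absent": result.D_present_vs_absent,
                "tau": result.tau,
                "direction": result.direction,
                "transform": result.transform,
                "n_present": int(result.present_values.size),
                "n_absent": int(result.absent_values.size),
            },
            indent=2,
        )
    )
    for name, df in result.tables.items():
        df.to_csv(out / f"{prefix}_{name}.tsv", sep="\t", index=False, float_format="%.17g")
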