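"""Expression matrices, sample annotations, and gene lists.

The pipeline works on dense samples x genes matrices of z-scored log2
microarray expression, where every sample carries an anatomical annotation
(region-of-interest label and acronym, donor, MNI coordinates). This module
reads the Allen Human Brain Atlas per-donor directory layout and a generic
TSV layout, collapses probe-level values to gene level, z-scores, subsets
genes, and pools donors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Hemisphere = Literal["left", "right", "unknown"]


@dataclass(frozen=True)
class SampleAnnotation:
    """Anatomical metadata for one tissue sample."""

    sample_id: str
    roi_label: str
    roi_acronym: str = ""
    donor_id: str = ""
    mni_xyz: tuple[float, float, float] | None = None
    hemisphere: Hemisphere = "unknown"

    def __post_init__(self) -> None:
        if not self.roi_label:
            raise ValueError(f"sample {self.sample_id!r}: roi_label must be non-empty")


@dataclass
class ExpressionMatrix:
    """Dense samples x genes matrix with aligned annotations.

    ``values[i, j]`` is the (optionally z-scored) expression of gene
    ``genes[j]`` in sample ``samples[i]``. ``constant_genes`` records gene
    columns that had zero variance during z-scoring and were mapped to all
    zeros rather than dropped.
    """

    values: np.ndarray
    samples: list[SampleAnnotation]
    genes: list[str]
    is_zscored: bool = False
    constant_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.samples):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.samples)} sample annotations"
            )
        if self.values.shape[1] != len(self.genes):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.genes)} gene symbols"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values after ingestion")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def roi_labels(self, by: str = "roi_acronym") -> list[str]:
        """Per-sample ROI labels; ``by`` selects the annotation field."""
        out = []
        for s in self.samples:
            v = getattr(s, by)
            out.append(v if v else s.roi_label)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.genes)


@dataclass(frozen=True)
class GeneList:
    """A named, ordered set of gene symbols."""

    name: str
    symbols: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene list must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene symbols must be unique")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list, one symbol per line, '#' comments allowed."""
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym and sym not in seen:
            seen.add(sym)
            symbols.append(sym)
    return GeneList(name=name or path.stem, symbols=tuple(symbols), provenance=str(path))


# ---------------------------------------------------------------------------
# AHBA per-donor directory ingestion


def _hemisphere_from_mni(x: float | None) -> Hemisphere:
    if x is None or not np.isfinite(x):
        return "unknown"
    return "left" if x <= 0 else "right"


def read_ahba_donor(
    directory: str | Path, donor_id: str | None = None
) -> tuple[pd.DataFrame, list[SampleAnnotation], dict[str, str]]:
    """Read one Allen Human Brain Atlas donor directory.

    Expects ``MicroarrayExpression.csv`` (first column probe id, one column
    per sample, no header row -- a header row is auto-detected),
    ``SampleAnnot.csv`` (one row per sample) and ``Probes.csv`` (probe id ->
    gene symbol).

    Returns the probe x sample matrix (probes as rows), the sample
    annotations in column order, and the probe-to-gene-symbol map.
    """
    directory = Path(directory)
    donor_id = donor_id or directory.name
    paths = {
        "expression": directory / "MicroarrayExpression.csv",
        "annotation": directory / "SampleAnnot.csv",
        "probes": directory / "Probes.csv",
    }
    for kind, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing AHBA {kind} file: {p}")

    # header auto-detection: AHBA ships the expression file headerless
    first = pd.read_csv(paths["expression"], header=None, nrows=1)
    has_header = not pd.api.types.is_number(first.iloc[0, 1]) and not str(
        first.iloc[0, 1]
    ).replace(".", "", 1).replace("-", "", 1).isdigit()
    expr = pd.read_csv(paths["expression"], header=0 if has_header else None)
    expr = expr.set_index(expr.columns[0])
    expr.index = expr.index.astype(str)
    expr.index.name = "probe_id"

    annot = pd.read_csv(paths["annotation"])
    if len(annot) != expr.shape[1]:
        raise ValueError(
            f"annotation rows ({len(annot)}) do not match expression columns "
            f"({expr.shape[1]}) in {directory}"
        )

    probes = pd.read_csv(paths["probes"])
    probe_col = _pick_column(probes, ["probe_id", "probe_name", "id"])
    gene_col = _pick_column(probes, ["gene_symbol", "gene-symbol", "symbol"])
    probe_map = {
        str(pid): ("" if pd.isna(sym) else str(sym))
        for pid, sym in zip(probes[probe_col], probes[gene_col])
    }
    missing = [pid for pid in expr.index if pid not in probe_map]
    if missing:
        raise ValueError(
            f"{len(missing)} probe ids absent from probe table, e.g. {missing[:5]}"
        )

    name_col = _pick_column(annot, ["structure_name", "roi", "structure"])
    acro_col = _pick_column(annot, ["structure_acronym", "acronym"], required=False)
    annotations: list[SampleAnnotation] = []
    for i, row in annot.iterrows():
        xyz = None
        if {"mni_x", "mni_y", "mni_z"} <= set(annot.columns):
            xyz = (float(row["mni_x"]), float(row["mni_y"]), float(row["mni_z"]))
        sid = str(row["sample_id"]) if "sample_id" in annot.columns else f"{donor_id}_s{i}"
        annotations.append(
            SampleAnnotation(
                sample_id=sid,
                roi_label=str(row[name_col]),
                roi_acronym=str(row[acro_col]) if acro_col else "",
                donor_id=donor_id,
                mni_xyz=xyz,
                hemisphere=_hemisphere_from_mni(xyz[0] if xyz else None),
            )
        )
    expr.columns = [a.sample_id for a in annotations]
    return expr, annotations, probe_map


def _pick_column(df: pd.DataFrame, candidates: Sequence[str], required: bool = True) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    if required:
        raise ValueError(f"none of the columns {candidates} found in {list(df.columns)}")
    return None


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: dict[str, str],
    method: Literal["mean", "max-variance-probe"] = "mean",
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    ``mean`` averages all probes mapping to a gene; ``max-variance-probe``
    keeps the single most variable probe. Probes with a blank or absent gene
    symbol are dropped (counted in the log).
    """
    if method not in ("mean", "max-variance-probe"):
        raise ValueError(f"unknown collapse method {method!r}")
    genes = pd.Series(
        [probe_map.get(str(p), "") for p in probe_matrix.index], index=probe_matrix.index
    )
    dropped = int((genes == "").sum())
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    keep = probe_matrix.loc[genes != ""]
    if keep.empty:
        raise ValueError("all probes unmapped to gene symbols")
    keep_genes = genes[genes != ""]
    if method == "mean":
        out = keep.groupby(keep_genes.values).mean()
    else:
        variances = keep.var(axis=1, ddof=1)
        best = variances.groupby(keep_genes.values).idxmax()
        out = keep.loc[best.values]
        out.index = best.index
    out.index.name = "gene_symbol"
    return out.sort_index()


# ---------------------------------------------------------------------------
# Transformations


def zscore_transform(
    expr: ExpressionMatrix, scope: Literal["within-donor", "pooled"] = "within-donor"
) -> ExpressionMatrix:
    """Standardize each gene column to mean 0, sd 1 (sample sd, ddof=1).

    By default each gene is standardized across samples *within each donor*
    and the donors pooled afterwards, so that donor-level offsets cannot
    dominate the lens. Constant columns map to all zeros and are flagged in
    ``constant_genes`` rather than dropped.
    """
    if expr.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = expr.values.copy()
    constant: set[str] = set()
    if scope == "pooled":
        groups = [np.arange(expr.n_samples)]
    else:
        donors = np.asarray([s.donor_id for s in expr.samples])
        groups = [np.flatnonzero(donors == d) for d in pd.unique(donors)]
    for idx in groups:
        block = values[idx]
        if len(idx) < 2:
            raise ValueError("every donor needs at least 2 samples for z-scoring")
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd < 1e-12
        sd_safe = np.where(zero, 1.0, sd)
        values[idx] = (block - mu) / sd_safe
        values[np.ix_(idx, np.flatnonzero(zero))] = 0.0
        constant.update(np.asarray(expr.genes)[zero])
    return replace(
        expr,
        values=values,
        is_zscored=True,
        constant_genes=frozenset(constant) | expr.constant_genes,
    )


def subset_genes(expr: ExpressionMatrix, gene_list: GeneList) -> ExpressionMatrix:
    """Restrict columns to the symbols of ``gene_list`` (matrix order kept)."""
    wanted = set(gene_list.symbols)
    keep = [j for j, g in enumerate(expr.genes) if g in wanted]
    missing = wanted - set(expr.genes)
    if not keep:
        raise ValueError(
            f"gene list {gene_list.name!r} has zero overlap with the expression matrix"
        )
    if missing:
        logger.info(
            "subset_genes: %d/%d symbols of %s not in matrix",
            len(missing), len(wanted), gene_list.name,
        )
    return replace(
        expr,
        values=expr.values[:, keep],
        genes=[expr.genes[j] for j in keep],
        constant_genes=frozenset(g for g in expr.constant_genes if g in wanted),
    )


def pool_donors(
    matrices: Sequence[ExpressionMatrix],
    hemisphere: Hemisphere | None = "left",
) -> ExpressionMatrix:
    """Concatenate per-donor matrices over the shared gene set.

    Samples are filtered to ``hemisphere`` first (default left, matching the
    left-hemisphere coverage of the atlas; pass None to keep all). Genes not
    present in every donor are dropped with a logged count.
    """
    if not matrices:
        raise ValueError("no donor matrices to pool")
    shared = set(matrices[0].genes)
    for m in matrices[1:]:
        shared &= set(m.genes)
    if not shared:
        raise ValueError("empty gene intersection across donors")
    order = [g for g in matrices[0].genes if g in shared]
    dropped = sum(len(m.genes) for m in matrices) - len(order) * len(matrices)
    if dropped:
        logger.info("pool_donors: dropped %d non-shared gene columns in total", dropped)

    blocks: list[np.ndarray] = []
    samples: list[SampleAnnotation] = []
    constant: set[str] = set()
    for m in matrices:
        col_idx = [m.genes.index(g) for g in order]
        if hemisphere is None:
            row_idx = list(range(m.n_samples))
        else:
            row_idx = [i for i, s in enumerate(m.samples) if s.hemisphere == hemisphere]
            if not row_idx:
                logger.info(
                    "pool_donors: donor %s contributes 0 %s-hemisphere samples",
                    m.samples[0].donor_id if m.samples else "?", hemisphere,
                )
                continue
        blocks.append(m.values[np.ix_(row_idx, col_idx)])
        samples.extend(m.samples[i] for i in row_idx)
        constant.update(m.constant_genes)
    if not blocks:
        raise ValueError("no samples left after hemisphere filtering")
    return ExpressionMatrix(
        values=np.vstack(blocks),
        samples=samples,
        genes=order,
        is_zscored=all(m.is_zscored for m in matrices),
        constant_genes=frozenset(g for g in constant if g in shared),
    )


# ---------------------------------------------------------------------------
# Generic TSV layout


def write_expression_tsv(
    expr: ExpressionMatrix, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    """Write the generic two-file TSV layout (matrix + annotations)."""
    df = expr.to_frame()
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    rows = []
    for s in expr.samples:
        x, y, z = s.mni_xyz if s.mni_xyz else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "sample_id": s.sample_id,
                "roi_label": s.roi_label,
                "roi_acronym": s.roi_acronym,
                "donor_id": s.donor_id,
                "mni_x": x, "mni_y": y, "mni_z": z,
                "hemisphere": s.hemisphere,
            }
        )
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False, float_format="%.17g")


def read_expression_tsv(
    matrix_path: str | Path, annotation_path: str | Path, is_zscored: bool = False
) -> ExpressionMatrix:
    """Read the generic two-file TSV layout written by :func:`write_expression_tsv`.

    Rows or columns containing missing values are dropped with a logged
    count; no imputation is performed.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    n0_rows, n0_cols = df.shape
    df = df.dropna(axis=1, how="all").dropna(axis=0, how="any")
    df = df.dropna(axis=1, how="any")
    if df.shape != (n0_rows, n0_cols):
        logger.info(
            "read_expression_tsv: dropped %d rows / %d columns with missing values",
            n0_rows - df.shape[0], n0_cols - df.shape[1],
        )
    annot = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    annot = annot.set_index("sample_id")
    samples = []
    for sid in df.index:
        if sid not in annot.index:
            raise ValueError(f"sample {sid!r} missing from annotation file")
        row = annot.loc[sid]
        xyz = None
        if "mni_x" in annot.columns and np.isfinite(row.get("mni_x", np.nan)):
            xyz = (float(row["mni_x"]), float(row["mni_y"]), float(row["mni_z"]))
        samples.append(
            SampleAnnotation(
                sample_id=str(sid),
                roi_label=str(row["roi_label"]),
                roi_acronym=str(row.get("roi_acronym", "") or ""),
                donor_id=str(row.get("donor_id", "") or ""),
                mni_xyz=xyz,
                hemisphere=str(row.get("hemisphere", "unknown") or "unknown"),  # type: ignore[arg-type]
            )
        )
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        samples=samples,
        genes=[str(c) for c in df.columns],
        is_zscored=is_zscored,
    )
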