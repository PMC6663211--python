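"""End-to-end orchestration: ingest -> lens -> sweep -> agreement -> extras.

The :class:`RunConfig` captures every input path and parameter; a run
writes all artifacts plus a manifest (config, input hashes, version) into
the output directory, and identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .aggregation import agreement, cooccurrence, write_matrix
from .comparison import compare, read_external_tsv, write_comparison
from .data_model import read_expression_tsv, read_gene_list, subset_genes, zscore_transform
from .lens import compute_lens, write_lens
from .mapper_core import MapperParams, edge_list_lines, write_graph
from .param_select import SelectionPolicy, select_optimal, sweep, write_sweep_table
from .path_analysis import path_distance_analysis, write_path_result

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A RunConfig referenced missing inputs or inconsistent settings."""


@dataclass
class RunConfig:
    expression_tsv: str
    annotation_tsv: str
    out_dir: str
    gene_list: str | None = None
    external_matrix: str | None = None
    external_transform: str = "none"
    lens_mode: str = "correlation"
    zscore: bool = False  # set when the input matrix is not yet z-scored
    zscore_scope: str = "within-donor"
    window_grid: list[float] = field(default_factory=lambda: [20.0, 30.0])
    overlap_grid: list[float] = field(default_factory=lambda: [30.0, 50.0])
    min_cluster_size: int = 3
    clustering: str = "linkage-gap"
    max_noise_fraction: float = 0.2
    top_k: int = 4
    roi_field: str = "roi_acronym"
    seed_rois: list[str] = field(default_factory=list)
    modularity_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for label, p in [
            ("expression_tsv", self.expression_tsv),
            ("annotation_tsv", self.annotation_tsv),
            ("gene_list", self.gene_list),
            ("external_matrix", self.external_matrix),
        ]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} does not exist: {p}")
        if not self.window_grid or not self.overlap_grid:
            raise ConfigError("sweep grids must be non-empty")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        expr = read_expression_tsv(
            config.expression_tsv, config.annotation_tsv, is_zscored=not config.zscore
        )
        if config.zscore:
            expr = zscore_transform(expr, scope=config.zscore_scope)  # type: ignore[arg-type]
        if config.gene_list:
            expr = subset_genes(expr, read_gene_list(config.gene_list))
        roi_by_sample = dict(zip(expr.sample_ids, expr.roi_labels(by=config.roi_field)))

        stage = "lens"
        lens = compute_lens(expr, mode=config.lens_mode)  # type: ignore[arg-type]
        write_lens(lens, out / "lens.tsv", out / "lens.json")

        stage = "sweep"
        grid = [(w, o) for w in config.window_grid for o in config.overlap_grid]
        base = MapperParams(
            window_pct=config.window_grid[0],
            overlap_pct=config.overlap_grid[0],
            min_cluster_size=config.min_cluster_size,
            clustering=config.clustering,  # type: ignore[arg-type]
        )
        result = sweep(expr, lens, grid, base_params=base)

        stage = "select"
        policy = SelectionPolicy(
            max_noise_fraction=config.max_noise_fraction, top_k=config.top_k
        )
        sigmas = select_optimal(result, policy)
        write_sweep_table(result, out / "sweep.tsv")

        stage = "graphs"
        coocs = []
        for sigma in sigmas:
            graph = result.graphs[sigma]
            tag = f"w{sigma[0]:g}_o{sigma[1]:g}"
            write_graph(
                graph,
                roi_by_sample,
                graphml_path=out / f"graph_{tag}.graphml",
                membership_tsv=out / f"membership_{tag}.tsv",
                metrics_json=out / f"metrics_{tag}.json",
            )
            (out / f"edges_{tag}.tsv").write_text("\n".join(edge_list_lines(graph)) + "\n")
            coocs.append(cooccurrence(graph, roi_by_sample))

        stage = "agreement"
        agree = agreement(coocs)
        write_matrix(agree, out / "agreement.tsv", out / "agreement.json")

        if config.external_matrix:
            stage = "compare"
            external = read_external_tsv(
                config.external_matrix, transform=config.external_transform  # type: ignore[arg-type]
            )
            comp = compare(agree, external)
            write_comparison(comp, out)

        if config.seed_rois:
            stage = "pathdist"
            best = sigmas[0]
            pathres = path_distance_analysis(
                result.graphs[best], config.seed_rois, roi_by_sample
            )
            write_path_result(pathres, roi_by_sample, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "selected_sigmas": [list(s) for s in sigmas],
        "inputs": {
            p: _sha256(p)
            for p in [
                config.expression_tsv,
                config.annotation_tsv,
                config.gene_list,
                config.external_matrix,
            ]
            if p
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
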