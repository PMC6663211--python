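"""Synthetic expression datasets with planted, recoverable structure.

Three generators cover the geometries the pipeline must resolve:

``blocks``
    Discrete ROI blocks (emulating cortex / subcortex / cerebellum /
    brainstem separation): each block owns a set of marker genes boosted by
    the effect size beta, plus Gaussian noise. Same-block samples are
    positively correlated; the Mapper graph should split into one component
    per block.
``chain``
    A smooth 1-D gradient (emulating the dopaminergic pathway): ROIs sit at
    latent positions r/n_rois along a path and genes respond with random
    sigmoid profiles (half rising, half falling), so adjacent ROIs are most
    correlated and hop distance from one end should recover the ordering.
``lens_cloud``
    Raw 2-D point clouds fed straight to the cover/graph stage (no
    expression): two well-separated Gaussian blobs, or a noisy circle whose
    Mapper graph should contain a cycle.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_model import ExpressionMatrix, SampleAnnotation, zscore_transform
from .lens import Lens, lens_from_coords


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset; identical spec + seed => identical data."""

    kind: Literal["blocks", "chain", "lens_cloud"]
    n_rois: int = 4
    samples_per_roi: int = 40
    n_genes: int = 400
    markers_per_block: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    # lens_cloud only
    shape: Literal["two_blobs", "circle"] = "two_blobs"
    n_points: int = 500
    separation: float = 10.0
    radial_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_rois, self.samples_per_roi, self.n_genes, self.markers_per_block) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _annotations(spec: SyntheticSpec, roi_names: list[str]) -> list[SampleAnnotation]:
    out = []
    for r, roi in enumerate(roi_names):
        for s in range(spec.samples_per_roi):
            out.append(
                SampleAnnotation(
                    sample_id=f"{roi}_s{s:03d}",
                    roi_label=roi,
                    roi_acronym=roi,
                    donor_id="synthetic",
                    hemisphere="left",
                )
            )
    return out


def gen_blocks(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Planted-block expression; returns the matrix and sample -> block id."""
    if spec.kind != "blocks":
        raise ValueError("spec.kind must be 'blocks'")
    if spec.markers_per_block * spec.n_rois > spec.n_genes:
        raise ValueError("markers_per_block * n_rois exceeds n_genes")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rois * spec.samples_per_roi
    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    for r in range(spec.n_rois):
        rows = slice(r * spec.samples_per_roi, (r + 1) * spec.samples_per_roi)
        cols = slice(r * spec.markers_per_block, (r + 1) * spec.markers_per_block)
        values[rows, cols] += spec.effect_size
    roi_names = [f"block{r:02d}" for r in range(spec.n_rois)]
    samples = _annotations(spec, roi_names)
    expr = ExpressionMatrix(
        values=values,
        samples=samples,
        genes=[f"G{j:04d}" for j in range(spec.n_genes)],
    )
    expr = zscore_transform(expr, scope="pooled")
    truth = {s.sample_id: int(s.roi_label.removeprefix("block")) for s in samples}
    return expr, truth


def gen_chain(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Planted 1-D gradient; returns the matrix and ROI -> latent position.

    ROI r (1-based) sits at position p_r = r / n_rois. Gene g responds with
    a sigmoid f_g(p) = 1 / (1 + exp(-(p - c_g)/width)) of random center
    c_g ~ U(0, 1); half the genes use the falling mirror 1 - f_g.
    """
    if spec.kind != "chain":
        raise ValueError("spec.kind must be 'chain'")
    if spec.n_rois < 3:
        raise ValueError("a chain needs at least 3 ROIs")
    rng = np.random.default_rng(spec.seed)
    centers = rng.uniform(0.0, 1.0, size=spec.n_genes)
    rising = np.arange(spec.n_genes) % 2 == 0
    width = 0.15  # sigmoid steepness: transitions span a few adjacent ROIs

    positions = {f"roi{r:02d}": r / spec.n_rois for r in range(1, spec.n_rois + 1)}
    roi_names = list(positions)
    samples = _annotations(spec, roi_names)
    p = np.array([positions[s.roi_label] for s in samples])
    f = 1.0 / (1.0 + np.exp(-(p[:, None] - centers[None, :]) / width))
    f = np.where(rising[None, :], f, 1.0 - f)
    values = spec.effect_size * f + rng.normal(0.0, spec.noise_sd, size=f.shape)
    expr = ExpressionMatrix(
        values=values,
        samples=samples,
        genes=[f"G{j:04d}" for j in range(spec.n_genes)],
    )
    return zscore_transform(expr, scope="pooled"), positions


def gen_lens_cloud(spec: SyntheticSpec) -> tuple[Lens, dict[str, str]]:
    """2-D point cloud wrapped as a Lens, plus sample -> geometric label."""
    if spec.kind != "lens_cloud":
        raise ValueError("spec.kind must be 'lens_cloud'")
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "two_blobs":
        half = spec.n_points // 2
        a = rng.normal(0.0, 1.0, size=(half, 2))
        b = rng.normal(spec.separation, 1.0, size=(spec.n_points - half, 2))
        coords = np.vstack([a, b])
        labels = ["blob_a"] * half + ["blob_b"] * (spec.n_points - half)
    elif spec.shape == "circle":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_points)
        radius = 1.0 + rng.normal(0.0, spec.radial_sd, size=spec.n_points)
        coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        labels = ["circle"] * spec.n_points
    else:
        raise ValueError(f"unknown lens_cloud shape {spec.shape!r}")
    ids = [f"pt{i:04d}" for i in range(spec.n_points)]
    return lens_from_coords(coords, ids), dict(zip(ids, labels))
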