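"""Ingestion, probe collapse, z-scoring, gene subsetting, donor pooling."""

import numpy as np
import pandas as pd
import pytest

from neuromapper.data_model import (
    ExpressionMatrix,
    GeneList,
    SampleAnnotation,
    collapse_probes,
    pool_donors,
    read_ahba_donor,
    read_expression_tsv,
    read_gene_list,
    subset_genes,
    write_expression_tsv,
    zscore_transform,
)


def make_expr(values, donors=None, rois=None, genes=None, hemisphere="left"):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    donors = donors or ["d1"] * n
    rois = rois or [f"roi{i}" for i in range(n)]
    samples = [
        SampleAnnotation(sample_id=f"s{i}", roi_label=rois[i], roi_acronym=rois[i],
                         donor_id=donors[i], hemisphere=hemisphere)
        for i in range(n)
    ]
    return ExpressionMatrix(values=values, samples=samples,
                            genes=genes or [f"g{j}" for j in range(g)])


class TestZscore:
    def test_single_donor_column(self):
        expr = make_expr([[1.0], [2.0], [3.0]])
        out = zscore_transform(expr)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])
        assert out.is_zscored

    def test_constant_column_flagged_as_zeros(self):
        expr = make_expr([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        out = zscore_transform(expr)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert out.constant_genes == {"g0"}

    def test_within_donor_standardization(self):
        expr = make_expr([[1.0], [3.0], [10.0], [20.0]], donors=["a", "a", "b", "b"])
        out = zscore_transform(expr, scope="within-donor")
        # each donor block standardized separately (ddof=1)
        np.testing.assert_allclose(out.values[:2, 0].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values[2:, 0].std(ddof=1), 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(10, 5)))
        once = zscore_transform(expr)
        twice = zscore_transform(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            zscore_transform(make_expr([[1.0, 2.0]]))


class TestCollapseProbes:
    def probes(self):
        mat = pd.DataFrame([[1.0, 3.0], [3.0, 5.0], [7.0, 9.0]],
                           index=["p1", "p2", "p3"], columns=["s1", "s2"])
        return mat, {"p1": "X", "p2": "X", "p3": "Y"}

    def test_mean_collapse(self):
        mat, pmap = self.probes()
        out = collapse_probes(mat, pmap, method="mean")
        np.testing.assert_allclose(out.loc["X"], [2.0, 4.0])

    def test_single_probe_identity(self):
        mat, pmap = self.probes()
        out = collapse_probes(mat, pmap)
        np.testing.assert_allclose(out.loc["Y"], [7.0, 9.0])

    def test_blank_symbol_dropped(self):
        mat, pmap = self.probes()
        pmap["p3"] = ""
        out = collapse_probes(mat, pmap)
        assert list(out.index) == ["X"]

    def test_all_unmapped_fatal(self):
        mat, _ = self.probes()
        with pytest.raises(ValueError, match="unmapped"):
            collapse_probes(mat, {"p1": "", "p2": "", "p3": ""})

    def test_max_variance_probe(self):
        mat = pd.DataFrame([[1.0, 1.1], [0.0, 10.0]], index=["p1", "p2"],
                           columns=["s1", "s2"])
        out = collapse_probes(mat, {"p1": "X", "p2": "X"}, method="max-variance-probe")
        np.testing.assert_allclose(out.loc["X"], [0.0, 10.0])

    def test_mean_preserves_per_sample_mean(self):
        # brute force: uniform probe count per gene keeps sample means intact
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(6, 4)),
                           index=[f"p{i}" for i in range(6)])
        pmap = {f"p{i}": f"G{i // 2}" for i in range(6)}
        out = collapse_probes(mat, pmap)
        np.testing.assert_allclose(out.mean(axis=0), mat.mean(axis=0))


class TestSubsetGenes:
    def test_intersection_preserves_order(self):
        expr = make_expr(np.arange(6.0).reshape(2, 3), genes=["A", "B", "C"])
        out = subset_genes(expr, GeneList(name="l", symbols=("B", "C", "D")))
        assert out.genes == ["B", "C"]
        np.testing.assert_allclose(out.values, [[1.0, 2.0], [4.0, 5.0]])

    def test_identity(self):
        expr = make_expr(np.ones((2, 2)), genes=["A", "B"])
        out = subset_genes(expr, GeneList(name="l", symbols=("A", "B")))
        assert out.genes == expr.genes

    def test_disjoint_fatal(self):
        expr = make_expr(np.ones((2, 2)), genes=["A", "B"])
        with pytest.raises(ValueError, match="zero overlap"):
            subset_genes(expr, GeneList(name="l", symbols=("X",)))


class TestPoolDonors:
    def test_concatenates_left_hemisphere(self):
        a = make_expr(np.ones((3, 2)), donors=["a"] * 3)
        b = make_expr(np.zeros((4, 2)), donors=["b"] * 4)
        for i, s in enumerate(b.samples):
            b.samples[i] = SampleAnnotation(sample_id=f"b{i}", roi_label=s.roi_label,
                                            donor_id="b", hemisphere="left")
        pooled = pool_donors([a, b])
        assert pooled.n_samples == 7
        assert {s.donor_id for s in pooled.samples} == {"a", "b"}

    def test_right_only_donor_contributes_nothing(self):
        a = make_expr(np.ones((3, 2)), donors=["a"] * 3, hemisphere="left")
        b = make_expr(np.zeros((2, 2)), donors=["b"] * 2, hemisphere="right")
        for i, s in enumerate(b.samples):
            b.samples[i] = SampleAnnotation(sample_id=f"b{i}", roi_label=s.roi_label,
                                            donor_id="b", hemisphere="right")
        pooled = pool_donors([a, b])
        assert pooled.n_samples == 3

    def test_gene_intersection(self):
        a = make_expr(np.ones((2, 3)), genes=["A", "B", "C"])
        b = make_expr(np.zeros((2, 3)), genes=["B", "C", "D"])
        for i, s in enumerate(b.samples):
            b.samples[i] = SampleAnnotation(sample_id=f"b{i}", roi_label=s.roi_label,
                                            donor_id="d1", hemisphere="left")
        pooled = pool_donors([a, b])
        assert pooled.genes == ["B", "C"]

    def test_empty_intersection_fatal(self):
        a = make_expr(np.ones((2, 1)), genes=["A"])
        b = make_expr(np.ones((2, 1)), genes=["B"])
        with pytest.raises(ValueError, match="intersection"):
            pool_donors([a, b])


@pytest.fixture
def ahba_dir(tmp_path):
    d = tmp_path / "donor9861"
    d.mkdir()
    pd.DataFrame([["p1", 1.0, 2.0, 3.0], ["p2", 4.0, 5.0, 6.0]]).to_csv(
        d / "MicroarrayExpression.csv", header=False, index=False
    )
    pd.DataFrame(
        {
            "structure_name": ["frontal pole", "cerebellum", "thalamus"],
            "structure_acronym": ["fro", "Cb", "Th"],
            "mni_x": [-10.0, -20.0, -5.0],
            "mni_y": [0.0, 1.0, 2.0],
            "mni_z": [3.0, 4.0, 5.0],
        }
    ).to_csv(d / "SampleAnnot.csv", index=False)
    pd.DataFrame({"probe_id": ["p1", "p2"], "gene_symbol": ["GENE1", "GENE2"]}).to_csv(
        d / "Probes.csv", index=False
    )
    return d


class TestAhbaIngestion:
    def test_round_trip(self, ahba_dir):
        mat, annots, pmap = read_ahba_donor(ahba_dir)
        assert mat.shape == (2, 3)
        assert len(annots) == 3
        assert pmap == {"p1": "GENE1", "p2": "GENE2"}
        assert annots[0].roi_label == "frontal pole"
        assert annots[0].hemisphere == "left"

    def test_missing_annotation_file(self, ahba_dir):
        (ahba_dir / "SampleAnnot.csv").unlink()
        with pytest.raises(FileNotFoundError, match="SampleAnnot.csv"):
            read_ahba_donor(ahba_dir)

    def test_column_count_mismatch(self, ahba_dir):
        annot = pd.read_csv(ahba_dir / "SampleAnnot.csv")
        pd.concat([annot, annot.iloc[[0]]]).to_csv(ahba_dir / "SampleAnnot.csv", index=False)
        with pytest.raises(ValueError, match="match"):
            read_ahba_donor(ahba_dir)

    def test_unknown_probe_fatal(self, ahba_dir):
        pd.DataFrame({"probe_id": ["p1"], "gene_symbol": ["GENE1"]}).to_csv(
            ahba_dir / "Probes.csv", index=False
        )
        with pytest.raises(ValueError, match="p2"):
            read_ahba_donor(ahba_dir)


def test_expression_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    expr = make_expr(rng.normal(size=(5, 4)), rois=["a", "b", "c", "d", "e"])
    write_expression_tsv(expr, tmp_path / "m.tsv", tmp_path / "a.tsv")
    back = read_expression_tsv(tmp_path / "m.tsv", tmp_path / "a.tsv")
    np.testing.assert_array_equal(back.values, expr.values)
    assert back.genes == expr.genes
    assert [s.sample_id for s in back.samples] == [s.sample_id for s in expr.samples]
    assert [s.roi_label for s in back.samples] == [s.roi_label for s in expr.samples]


def test_gene_list_reader(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text("# dopamine receptors\nDRD1\nDRD2  # D2\n\nDRD1\n")
    gl = read_gene_list(p)
    assert gl.symbols == ("DRD1", "DRD2")
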