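import numpy as np
import pandas as pd
import pytest

from ntcmetab import (
    GeneSetCatalog,
    PipelineError,
    ScSimConfig,
    generate_sc_dataset,
    genotype_fold_change,
    log_normalize,
    normalize_to_min_population,
    population_pathway_mean,
    qc_filter,
    stage_change,
    subpathway_fold_change,
)

from conftest import make_annotation, make_matrix
from helpers_oracles import brute_pathway_mean


def scores_frame(rows):
    return pd.DataFrame(rows, columns=["population", "pathway", "mean_expression", "n_genes_used", "no_genes_matched"])


class TestPopulationPathwayMean:
    def test_single_gene_single_cell(self):
        matrix = make_matrix([[2.5]], genes=["g0"], scale="lognorm")
        annot = make_annotation(["c0"])
        catalog = GeneSetCatalog({"s": ["g0"]})
        out = population_pathway_mean(matrix, annot, catalog)
        assert out.loc[0, "mean_expression"] == 2.5
        assert out.loc[0, "n_genes_used"] == 1

    def test_matches_brute_force_double_mean(self, small_lognorm, two_set_catalog):
        annot = make_annotation(list(small_lognorm.cells), population=["p1"] * 25 + ["p2"] * 25)
        out = population_pathway_mean(small_lognorm, annot, two_set_catalog).set_index(["population", "pathway"])
        genes = list(small_lognorm.genes)
        for pop, cols in (("p1", slice(0, 25)), ("p2", slice(25, 50))):
            for name in two_set_catalog.names:
                expected = brute_pathway_mean(small_lognorm.values[:, cols], genes, two_set_catalog[name])
                assert out.loc[(pop, name), "mean_expression"] == pytest.approx(expected, rel=1e-9)

    def test_permutation_invariance(self, small_lognorm, two_set_catalog, rng):
        annot = make_annotation(list(small_lognorm.cells), population=["p1"] * 25 + ["p2"] * 25)
        order = rng.permutation(small_lognorm.n_cells)
        shuffled = small_lognorm.subset_cells(small_lognorm.cells[order])
        a = population_pathway_mean(small_lognorm, annot, two_set_catalog)
        b = population_pathway_mean(shuffled, annot, two_set_catalog)
        pd.testing.assert_frame_equal(a, b)

    def test_unmatched_genes_counted_and_flagged(self, small_lognorm):
        catalog = GeneSetCatalog({"partial": ["g0", "Missing1"], "absent": ["NoA", "NoB"]})
        annot = make_annotation(list(small_lognorm.cells))
        out = population_pathway_mean(small_lognorm, annot, catalog).set_index("pathway")
        assert out.loc["partial", "n_genes_used"] == 1
        assert out.loc["absent", "n_genes_used"] == 0
        assert bool(out.loc["absent", "no_genes_matched"])


class TestMinPopulationNormalization:
    @pytest.mark.parametrize(
        "means, expected",
        [([2.0, 2.4], [1.0, 1.2]), ([3.0, 3.0, 3.0], [1.0, 1.0, 1.0]), ([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])],
    )
    def test_relative_scores(self, means, expected):
        rows = [
            {"population": f"p{i}", "pathway": "s", "mean_expression": m, "n_genes_used": 3, "no_genes_matched": False}
            for i, m in enumerate(means)
        ]
        out = normalize_to_min_population(scores_frame(rows))
        np.testing.assert_allclose(out["relative_score"], expected, rtol=1e-12)
        assert out["relative_score"].min() == 1.0

    def test_zero_minimum_names_pathway(self):
        rows = [
            {"population": "p0", "pathway": "bad", "mean_expression": 0.0, "n_genes_used": 1, "no_genes_matched": False},
            {"population": "p1", "pathway": "bad", "mean_expression": 2.0, "n_genes_used": 1, "no_genes_matched": False},
        ]
        with pytest.raises(PipelineError, match="bad"):
            normalize_to_min_population(scores_frame(rows))


class TestStageChange:
    def test_elementwise_ratio_and_identity(self):
        early = scores_frame(
            [
                {"population": "nc", "pathway": "folate", "mean_expression": 1.0, "n_genes_used": 3, "no_genes_matched": False},
                {"population": "nt", "pathway": "folate", "mean_expression": 2.0, "n_genes_used": 3, "no_genes_matched": False},
            ]
        )
        late = early.copy()
        late.loc[0, "mean_expression"] = 1.3
        out = stage_change(early, late).set_index(["population", "pathway"])
        assert out.loc[("nc", "folate"), "fold_change"] == pytest.approx(1.3)
        assert out.loc[("nt", "folate"), "fold_change"] == pytest.approx(1.0)
        identity = stage_change(early, early)
        np.testing.assert_allclose(identity["fold_change"], 1.0)

    def test_missing_key_reported(self):
        early = scores_frame(
            [{"population": "nc", "pathway": "folate", "mean_expression": 1.0, "n_genes_used": 3, "no_genes_matched": False}]
        )
        late = scores_frame(
            [{"population": "nt", "pathway": "folate", "mean_expression": 1.3, "n_genes_used": 3, "no_genes_matched": False}]
        )
        out = stage_change(early, late)
        assert out["missing_stage"].all()
        assert out["fold_change"].isna().all()


def tiny_genotype_fixture(rng, ko_scale=1.0):
    """3-gene catalog, two populations, deterministic lognorm values."""
    genes = ["gA", "gB", "gC", "other"]
    cells = [f"c{i}" for i in range(8)]
    wt = np.abs(rng.normal(1.0, 0.3, (4, 8)))
    ko = wt * ko_scale
    matrix_wt = make_matrix(wt, genes=genes, cells=cells, scale="lognorm")
    matrix_ko = make_matrix(ko, genes=genes, cells=[f"k{i}" for i in range(8)], scale="lognorm")
    pops = ["p1"] * 4 + ["p2"] * 4
    annot_wt = make_annotation(cells, population=pops)
    annot_ko = make_annotation(list(matrix_ko.cells), population=pops, genotype="KO")
    catalog = GeneSetCatalog({"path": ["gA", "gB", "gC"]})
    return matrix_wt, matrix_ko, annot_wt, annot_ko, catalog


class TestGenotypeFoldChange:
    def test_identity_when_matrices_equal(self, rng):
        matrix_wt, _, annot_wt, _, catalog = tiny_genotype_fixture(rng)
        for level in ("gene", "pathway", "population", "ectoderm"):
            out = genotype_fold_change(matrix_wt, matrix_wt, annot_wt, annot_wt, catalog, level)
            np.testing.assert_allclose(out["fold_change"], 1.0, rtol=1e-9)

    def test_pathway_equals_mean_of_gene_level(self, rng):
        args = tiny_genotype_fixture(rng, ko_scale=1.7)
        gene_table = genotype_fold_change(*args, level="gene")
        path_table = genotype_fold_change(*args, level="pathway").set_index(["population", "pathway"])
        for (pop, pathway), sub in gene_table.groupby(["population", "pathway"]):
            assert path_table.loc[(pop, pathway), "fold_change"] == pytest.approx(
                sub["fold_change"].mean(), rel=1e-12
            )

    def test_geometric_aggregation_flag(self, rng):
        args = tiny_genotype_fixture(rng, ko_scale=2.0)
        gene_table = genotype_fold_change(*args, level="gene")
        geo = genotype_fold_change(*args, level="pathway", agg="geometric").set_index(["population", "pathway"])
        for (pop, pathway), sub in gene_table.groupby(["population", "pathway"]):
            expected = np.exp(np.log(sub["fold_change"]).mean())
            assert geo.loc[(pop, pathway), "fold_change"] == pytest.approx(expected, rel=1e-12)

    def test_orphan_population_excluded_with_warning(self, rng):
        matrix_wt, matrix_ko, annot_wt, annot_ko, catalog = tiny_genotype_fixture(rng)
        annot_ko = annot_ko.copy()
        annot_ko["population"] = ["p1"] * 4 + ["p3"] * 4
        with pytest.warns(UserWarning, match="only one genotype"):
            out = genotype_fold_change(matrix_wt, matrix_ko, annot_wt, annot_ko, catalog, "gene")
        assert set(out["population"]) == {"p1"}

    def test_single_gene_multiplier_recovered_from_generator(self):
        """A 4.5x knockout multiplier on one gene is recovered within +-15%
        at 300 cells/population through the full qc -> normalize -> fold
        change pipeline."""
        config = ScSimConfig(
            populations={"forebrain": 300, "hindbrain": 300},
            baseline_mean_range=(1.0, 3.0),  # a well-expressed target gene
            genotype_multipliers={"Pfkp": 4.5},
            stage_pathway_multipliers={},
            seed=11,
        )
        ds = generate_sc_dataset(config)
        wt, annot_wt, _ = qc_filter(ds.matrix_wt, ds.annot_wt)
        ko, annot_ko, _ = qc_filter(ds.matrix_ko, ds.annot_ko)
        table = genotype_fold_change(
            log_normalize(wt), log_normalize(ko), annot_wt, annot_ko, ds.catalog, "gene"
        )
        pfkp = table[table["gene"] == "Pfkp"]["fold_change"]
        assert len(pfkp) == 2
        for value in pfkp:
            assert value == pytest.approx(4.5, rel=0.15)

    def test_multiplier_monotonicity_in_expectation(self):
        """Raising a gene's injected KO multiplier raises its estimated
        gene-level fold change, averaged over 10 seeds."""
        catalog = GeneSetCatalog({"path": ["Pfkp", "Hk1", "Gpi1"]})
        estimates = {}
        for mult in (1.5, 2.5):
            values = []
            for seed in range(10):
                config = ScSimConfig(
                    populations={"hindbrain": 150},
                    catalog=catalog,
                    n_background_genes=80,
                    genotype_multipliers={"Pfkp": mult},
                    stage_pathway_multipliers={},
                    debris_rate=0.0,
                    doublet_rate=0.0,
                    seed=seed,
                )
                ds = generate_sc_dataset(config)
                table = genotype_fold_change(
                    log_normalize(ds.matrix_wt), log_normalize(ds.matrix_ko),
                    ds.annot_wt, ds.annot_ko, ds.catalog, "gene",
                )
                values.append(float(table[table["gene"] == "Pfkp"]["fold_change"].iloc[0]))
            estimates[mult] = np.mean(values)
        assert estimates[2.5] > estimates[1.5]


class TestSubpathwayFoldChange:
    def test_targeted_subpathway_stands_out(self):
        """With upper glycolysis injected at 2x, only that sub-pathway's
        fold change moves; the others stay near 1."""
        from ntcmetab.catalogs import UPPER_GLYCOLYSIS

        config = ScSimConfig(
            populations={"hindbrain": 400},
            genotype_multipliers={g: 2.0 for g in UPPER_GLYCOLYSIS},
            stage_pathway_multipliers={},
            debris_rate=0.0,
            doublet_rate=0.0,
            seed=5,
        )
        ds = generate_sc_dataset(config)
        out = subpathway_fold_change(
            log_normalize(ds.matrix_wt), log_normalize(ds.matrix_ko),
            ds.annot_wt, ds.annot_ko, ds.subpathways,
        ).set_index("subpathway")
        assert out.loc["upper_glycolysis", "fold_change"] == pytest.approx(2.0, rel=0.12)
        for name in out.index.drop("upper_glycolysis"):
            assert out.loc[name, "fold_change"] == pytest.approx(1.0, rel=0.12)

    def test_empty_subpathway_flagged(self, rng):
        matrix_wt, matrix_ko, annot_wt, annot_ko, _ = tiny_genotype_fixture(rng)
        subsets = {"present": ["gA"], "empty": ["NotThere"]}
        out = subpathway_fold_change(matrix_wt, matrix_ko, annot_wt, annot_ko, subsets)
        flagged = out[out["subpathway"] == "empty"]
        assert flagged["no_genes_matched"].all()
        assert flagged["fold_change"].isna().all()
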