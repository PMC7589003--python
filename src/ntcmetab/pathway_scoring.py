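"""Population-wise metabolic-pathway scores and genotype fold-change aggregation.

The central computation of the pipeline.  For each cell population and each
gene set ("pathway"), the pathway score is the unweighted mean over member
genes of each gene's mean log-normalized expression in that population.
Scores can then be normalized to the lowest-expressing population within
each pathway (so the minimum population scores exactly 1), compared across
developmental stages, or compared across genotypes.

Genotype comparison follows a fixed aggregation order: the knockout/wild-type
fold change is computed for each gene individually within each population,
and those per-gene fold changes are then averaged (arithmetically, by
default) up to pathway / population / ectoderm level.  Gene means for fold
changes are taken on the linear expression scale (counts per scale factor,
i.e. expm1 of the log-normalized values): ratios of log1p-compressed means
systematically understate true expression ratios, whereas linear-scale mean
ratios are consistent estimators of the underlying count-scale fold change.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    LOGNORM,
    NON_ECTODERM,
    ExpressionMatrix,
    GeneSetCatalog,
    PipelineError,
    validate_annotation,
)

EPS = 1e-9

LEVELS = ("gene", "pathway", "population", "ectoderm")


def _linear_values(matrix: ExpressionMatrix) -> np.ndarray:
    """Expression on the linear scale (de-logged when matrix is lognorm)."""
    if matrix.scale == LOGNORM:
        return np.expm1(matrix.values)
    return matrix.values


def population_pathway_mean(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame,
    catalog: GeneSetCatalog,
) -> pd.DataFrame:
    """Mean pathway expression per (population, pathway).

    For each pathway the score is ``mean over member genes of (mean over the
    population's cells of log-normalized expression)``.  Catalog genes absent
    from the matrix are excluded and reflected in ``n_genes_used``; a pathway
    with no matched genes is emitted with ``n_genes_used 0`` and a flag
    rather than silently dropped.
    """
    validate_annotation(annot, matrix)
    annot = annot.loc[matrix.cells]
    rows = []
    for population, cells in annot.groupby("population", sort=True).groups.items():
        sub = matrix.subset_cells(cells)
        gene_means = pd.Series(sub.values.mean(axis=1), index=sub.genes)
        for pathway in catalog.names:
            matched = [g for g in catalog[pathway] if g in gene_means.index]
            rows.append(
                {
                    "population": population,
                    "pathway": pathway,
                    "mean_expression": float(gene_means[matched].mean()) if matched else np.nan,
                    "n_genes_used": len(matched),
                    "no_genes_matched": not matched,
                }
            )
    return pd.DataFrame(rows)


def normalize_to_min_population(scores: pd.DataFrame) -> pd.DataFrame:
    """Divide each pathway's scores by the lowest-expressing population's score.

    Adds a ``relative_score`` column; the minimal population within each
    pathway gets exactly 1.
    """
    out = scores.copy()
    out["relative_score"] = np.nan
    for pathway, sub in out.groupby("pathway"):
        usable = sub[~sub["no_genes_matched"]] if "no_genes_matched" in sub else sub
        if usable.empty:
            continue
        floor = usable["mean_expression"].min()
        if not floor > 0:
            raise PipelineError(f"pathway {pathway!r} has a non-positive minimum population mean")
        out.loc[usable.index, "relative_score"] = usable["mean_expression"] / floor
    return out


def stage_change(scores_early: pd.DataFrame, scores_late: pd.DataFrame) -> pd.DataFrame:
    """Late/early ratio of pathway means per (population, pathway).

    Values above 1 denote upregulation over developmental time.  Keys present
    at only one stage are emitted with ``missing_stage`` set and no ratio.
    """
    keys = ["population", "pathway"]
    merged = scores_early.merge(
        scores_late, on=keys, how="outer", suffixes=("_early", "_late"), indicator=True
    )
    merged["fold_change"] = merged["mean_expression_late"] / merged["mean_expression_early"]
    merged["missing_stage"] = merged["_merge"] != "both"
    merged.loc[merged["missing_stage"], "fold_change"] = np.nan
    return merged[keys + ["mean_expression_early", "mean_expression_late", "fold_change", "missing_stage"]]


def _population_gene_means(matrix: ExpressionMatrix, annot: pd.DataFrame) -> dict[str, pd.Series]:
    values = _linear_values(matrix)
    annot = annot.loc[matrix.cells]
    means: dict[str, pd.Series] = {}
    for population, cells in annot.groupby("population", sort=True).groups.items():
        idx = matrix.cells.get_indexer(cells)
        means[str(population)] = pd.Series(values[:, idx].mean(axis=1), index=matrix.genes)
    return means


def genotype_fold_change(
    matrix_wt: ExpressionMatrix,
    matrix_ko: ExpressionMatrix,
    annot_wt: pd.DataFrame,
    annot_ko: pd.DataFrame,
    catalog: GeneSetCatalog,
    level: str = "pathway",
    *,
    agg: str = "arithmetic",
    eps: float = EPS,
) -> pd.DataFrame:
    """KO/WT fold change aggregated to the requested level.

    Per gene per population, ``FC = (mean KO expression + eps) / (mean WT
    expression + eps)`` with means on the linear scale.  ``level='gene'``
    returns that table; coarser levels average the per-gene fold changes —
    arithmetically unless ``agg='geometric'`` — over member genes
    (``'pathway'``), over all (pathway, gene) pairs of a population
    (``'population'``), or over genes and every ectoderm-derived population
    (``'ectoderm'``, one row per pathway).  Populations present in only one
    genotype are excluded with a warning.
    """
    if level not in LEVELS:
        raise PipelineError(f"level must be one of {LEVELS}")
    if agg not in ("arithmetic", "geometric"):
        raise PipelineError("agg must be 'arithmetic' or 'geometric'")
    validate_annotation(annot_wt, matrix_wt)
    validate_annotation(annot_ko, matrix_ko)
    shared_genes = matrix_wt.genes.intersection(matrix_ko.genes)
    means_wt = _population_gene_means(matrix_wt, annot_wt)
    means_ko = _population_gene_means(matrix_ko, annot_ko)
    shared_pops = sorted(set(means_wt) & set(means_ko))
    orphan = set(means_wt) ^ set(means_ko)
    if orphan:
        warnings.warn(f"populations present in only one genotype excluded: {sorted(orphan)}")

    rows = []
    for population in shared_pops:
        wt, ko = means_wt[population], means_ko[population]
        for pathway in catalog.names:
            for gene in catalog[pathway]:
                if gene not in shared_genes:
                    continue
                rows.append(
                    {
                        "population": population,
                        "pathway": pathway,
                        "gene": gene,
                        "fold_change": (ko[gene] + eps) / (wt[gene] + eps),
                    }
                )
    gene_table = pd.DataFrame(rows, columns=["population", "pathway", "gene", "fold_change"])
    if level == "gene":
        gene_table["n_genes_averaged"] = 1
        return gene_table

    def _mean(values: pd.Series) -> float:
        if agg == "geometric":
            return float(np.exp(np.log(values).mean()))
        return float(values.mean())

    if level == "pathway":
        grouped = gene_table.groupby(["population", "pathway"], sort=True)["fold_change"]
    elif level == "population":
        grouped = gene_table.groupby(["population"], sort=True)["fold_change"]
    else:  # ectoderm: all ectoderm-derived populations pooled, one row per pathway
        ecto = gene_table[gene_table["population"] != NON_ECTODERM]
        grouped = ecto.groupby(["pathway"], sort=True)["fold_change"]
    out = grouped.agg(fold_change=_mean, n_genes_averaged="size").reset_index()
    return out


def subpathway_fold_change(
    matrix_wt: ExpressionMatrix,
    matrix_ko: ExpressionMatrix,
    annot_wt: pd.DataFrame,
    annot_ko: pd.DataFrame,
    glycolysis_subsets: GeneSetCatalog | Mapping[str, list[str]],
    level: str = "pathway",
    **kwargs,
) -> pd.DataFrame:
    """``genotype_fold_change`` applied per glycolysis sub-pathway.

    Sub-pathway sets may overlap.  Sub-pathways with no genes in the shared
    matrix universe are emitted as flagged rows.
    """
    if not isinstance(glycolysis_subsets, GeneSetCatalog):
        glycolysis_subsets = GeneSetCatalog(dict(glycolysis_subsets))
    out = genotype_fold_change(matrix_wt, matrix_ko, annot_wt, annot_ko, glycolysis_subsets, level, **kwargs)
    out = out.rename(columns={"pathway": "subpathway"} if "pathway" in out.columns else {})
    shared = set(matrix_wt.genes.intersection(matrix_ko.genes))
    empty = [name for name in glycolysis_subsets.names if not set(glycolysis_subsets[name]) & shared]
    if empty and "subpathway" in out.columns:
        flags = pd.DataFrame(
            {"subpathway": empty, "fold_change": np.nan, "n_genes_averaged": 0}
        )
        out = pd.concat([out, flags], ignore_index=True)
    out["no_genes_matched"] = out.get("n_genes_averaged", 1) == 0
    return out
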