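"""Threshold co-expression statistics for gene pairs.

A cell "co-expresses" a pair when both log-normalized values are strictly
above a threshold (default 1).  Fractions of co-expressing cells proxy the
overlap of cell-cycle phases (G1/S x G2/M cyclins) or metabolic-cell-cycle
coupling (Pfkfb3 x Cdk1/Cdk4); genotype comparisons are reported both as
fraction ratios (robust to unequal cell totals) and raw count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PipelineError, validate_annotation


@dataclass
class CoexpressionResult:
    gene_a: str
    gene_b: str
    genotype: str
    threshold: float
    n_cells_total: int
    n_coexpressing: int
    mean_expr_a_within: float
    mean_expr_b_within: float

    @property
    def fraction(self) -> float:
        return self.n_coexpressing / self.n_cells_total


def coexpression_count(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    threshold: float = 1.0,
    genotype: str = "all",
) -> CoexpressionResult:
    """Count cells with both genes strictly above ``threshold``.

    Also reports each gene's mean expression within the co-expressing cells
    (NaN when no cell co-expresses).
    """
    a = matrix.gene_vector(gene_a)
    b = matrix.gene_vector(gene_b)
    both = (a > threshold) & (b > threshold)
    n = int(both.sum())
    return CoexpressionResult(
        gene_a=gene_a,
        gene_b=gene_b,
        genotype=genotype,
        threshold=threshold,
        n_cells_total=matrix.n_cells,
        n_coexpressing=n,
        mean_expr_a_within=float(a[both].mean()) if n else float("nan"),
        mean_expr_b_within=float(b[both].mean()) if n else float("nan"),
    )


def coexpression_genotype_ratio(
    result_wt: CoexpressionResult,
    result_ko: CoexpressionResult,
    basis: str = "fraction",
) -> dict:
    """KO/WT ratio of co-expression on the chosen basis; both bases reported.

    Fractions are the default because wild-type and knockout datasets rarely
    have equal cell totals; the raw-count ratio is co-reported.
    A zero wild-type quantity leaves the ratio undefined (NaN, flagged).
    """
    if basis not in ("fraction", "count"):
        raise PipelineError("basis must be 'fraction' or 'count'")
    if (result_wt.gene_a, result_wt.gene_b, result_wt.threshold) != (
        result_ko.gene_a,
        result_ko.gene_b,
        result_ko.threshold,
    ):
        raise PipelineError("WT and KO results must share gene pair and threshold")
    ratios = {}
    for name, wt_q, ko_q in (
        ("fraction", result_wt.fraction, result_ko.fraction),
        ("count", result_wt.n_coexpressing, result_ko.n_coexpressing),
    ):
        ratios[f"ratio_{name}"] = ko_q / wt_q if wt_q else float("nan")
    ratios["ratio"] = ratios[f"ratio_{basis}"]
    ratios["undefined"] = bool(np.isnan(ratios["ratio"]))
    ratios["basis"] = basis
    return ratios


def coexpression_panel(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame,
    pairs: list[tuple[str, str]],
    threshold: float = 1.0,
    basis: str = "fraction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair, per-genotype co-expression plus KO/WT ratios.

    Pairs with a gene missing from the matrix are emitted as flagged rows;
    the rest of the panel is still computed.  Row order is deterministic
    (pair order as given, genotypes sorted).
    """
    if not pairs:
        raise PipelineError("panel needs at least one gene pair")
    validate_annotation(annot, matrix)
    annot = annot.loc[matrix.cells]
    genotypes = sorted(annot["genotype"].unique())
    rows, ratio_rows = [], []
    for gene_a, gene_b in pairs:
        missing = [g for g in (gene_a, gene_b) if g not in matrix.genes]
        if missing:
            for genotype in genotypes:
                rows.append(
                    {
                        "gene_a": gene_a, "gene_b": gene_b, "genotype": genotype,
                        "n_cells_total": np.nan, "n_coexpressing": np.nan,
                        "fraction": np.nan, "mean_expr_a_within": np.nan,
                        "mean_expr_b_within": np.nan, "missing_gene": True,
                    }
                )
            ratio_rows.append(
                {"gene_a": gene_a, "gene_b": gene_b, "ratio": np.nan,
                 "ratio_fraction": np.nan, "ratio_count": np.nan, "missing_gene": True}
            )
            continue
        by_genotype = {}
        for genotype in genotypes:
            cells = annot.index[annot["genotype"] == genotype]
            res = coexpression_count(matrix.subset_cells(cells), gene_a, gene_b, threshold, genotype)
            by_genotype[genotype] = res
            rows.append(
                {
                    "gene_a": gene_a, "gene_b": gene_b, "genotype": genotype,
                    "n_cells_total": res.n_cells_total, "n_coexpressing": res.n_coexpressing,
                    "fraction": res.fraction, "mean_expr_a_within": res.mean_expr_a_within,
                    "mean_expr_b_within": res.mean_expr_b_within, "missing_gene": False,
                }
            )
        if {"WT", "KO"} <= set(by_genotype):
            ratios = coexpression_genotype_ratio(by_genotype["WT"], by_genotype["KO"], basis)
            ratio_rows.append(
                {"gene_a": gene_a, "gene_b": gene_b, "ratio": ratios["ratio"],
                 "ratio_fraction": ratios["ratio_fraction"], "ratio_count": ratios["ratio_count"],
                 "missing_gene": False}
            )
    return pd.DataFrame(rows), pd.DataFrame(ratio_rows)
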