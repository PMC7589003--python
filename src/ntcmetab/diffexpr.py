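"""Two-group differential expression on log-normalized values.

Per gene, a two-sided Wilcoxon rank-sum test (normal approximation with
tie and continuity correction) compares the two cell groups; fold changes
are ratios of group means with a small pseudocount; p-values are adjusted
across tested genes by Benjamini-Hochberg.  This is an explicitly
specified contract, not a bit-level clone of any particular toolkit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOGNORM, ExpressionMatrix, PipelineError

EPS = 1e-9
MIN_GROUP = 3


def differential_expression(
    matrix: ExpressionMatrix,
    cells_a,
    cells_b,
    *,
    min_frac: float = 0.0,
    min_abs_log2fc: float = 0.0,
) -> pd.DataFrame:
    """Compare cell groups A and B gene-by-gene.

    Returns a table with ``gene, log2_fold_change, p_value, adjusted_p,
    frac_expressing_a, frac_expressing_b`` sorted by adjusted p then
    descending |log2FC| then gene.  ``log2_fold_change`` is A over B on the
    group means of the provided values, pseudocounted with 1e-9; genes
    silent in both groups report log2FC 0 and p 1.
    """
    if matrix.scale != LOGNORM:
        raise PipelineError("differential_expression expects log-normalized values")
    cells_a, cells_b = pd.Index(cells_a), pd.Index(cells_b)
    if len(cells_a.intersection(cells_b)):
        raise PipelineError("cell groups must be disjoint")
    if len(cells_a) < MIN_GROUP or len(cells_b) < MIN_GROUP:
        raise PipelineError(f"each group needs at least {MIN_GROUP} cells")

    a = matrix.subset_cells(cells_a).values
    b = matrix.subset_cells(cells_b).values

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_a + EPS) / (mean_b + EPS))

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        pvals = np.asarray(res.pvalue, dtype=float)
    # degenerate genes: every value identical across both groups -> no evidence
    combined = np.concatenate([a, b], axis=1)
    degenerate = np.ptp(combined, axis=1) == 0
    pvals[degenerate] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "frac_expressing_a": (a > 0).mean(axis=1),
            "frac_expressing_b": (b > 0).mean(axis=1),
        }
    )
    if min_frac > 0:
        table = table[(table["frac_expressing_a"] >= min_frac) | (table["frac_expressing_b"] >= min_frac)]
    if min_abs_log2fc > 0:
        table = table[table["log2_fold_change"].abs() >= min_abs_log2fc]
    table = table.reset_index(drop=True)
    table["adjusted_p"] = stats.false_discovery_control(table["p_value"], method="bh")
    table["abs_lfc"] = table["log2_fold_change"].abs()
    table = (
        table.sort_values(["adjusted_p", "abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort")
        .drop(columns="abs_lfc")
        .reset_index(drop=True)
    )
    return table[
        ["gene", "log2_fold_change", "p_value", "adjusted_p", "frac_expressing_a", "frac_expressing_b"]
    ]


def subset_by_expression(matrix: ExpressionMatrix, gene: str, threshold: float = 1.0) -> pd.Index:
    """Cells whose normalized expression of ``gene`` is strictly above ``threshold``."""
    vector = matrix.gene_vector(gene)  # raises on absent gene
    return matrix.cells[vector > threshold]
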