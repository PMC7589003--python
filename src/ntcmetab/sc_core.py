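"""Single-cell QC filtering and log normalization.

Cells of low complexity (fewer than ``min_umi`` total UMIs) and putative
doublets/triplets (more than ``max_umi``) are removed with strict
inequalities, so boundary cells are retained; mitochondrial genes are
dropped by symbol prefix.  Normalization is counts-per-``scale_factor``
followed by log1p, the scale on which every downstream threshold operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    COUNTS,
    LOGNORM,
    EmptyMatrixError,
    ExpressionMatrix,
    PipelineError,
    validate_annotation,
)


@dataclass
class QcReport:
    n_input_cells: int
    n_low_complexity_removed: int
    n_doublet_removed: int
    n_mito_genes_removed: int
    n_output_cells: int

    def __post_init__(self) -> None:
        expected = self.n_input_cells - self.n_low_complexity_removed - self.n_doublet_removed
        if self.n_output_cells != expected or min(
            self.n_input_cells,
            self.n_low_complexity_removed,
            self.n_doublet_removed,
            self.n_mito_genes_removed,
            self.n_output_cells,
        ) < 0:
            raise PipelineError("QC report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def qc_filter(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame | None = None,
    *,
    min_umi: int = 200,
    max_umi: int = 2500,
    mito_prefix: str = "mt-",
) -> tuple[ExpressionMatrix, pd.DataFrame | None, QcReport]:
    """Remove low-complexity cells, UMI-rich doublets and mitochondrial genes.

    Per-cell totals are a property of the sequencing run: they are taken
    from the annotation's ``total_umi`` when one is provided (so they are
    not distorted by earlier gene filtering), otherwise computed as column
    sums of the input matrix before mitochondrial-gene removal.  Removal
    is strict (< min_umi or > max_umi); cells exactly at a threshold stay.
    """
    if matrix.scale != COUNTS:
        raise PipelineError("qc_filter expects a counts-scale matrix")
    if annot is not None:
        validate_annotation(annot, matrix)
        totals = annot.loc[matrix.cells, "total_umi"].to_numpy(float)
    else:
        totals = matrix.cell_totals()
    low = totals < min_umi
    high = totals > max_umi
    keep_cells = ~(low | high)
    mito = matrix.genes.str.startswith(mito_prefix)
    keep_genes = ~mito

    report = QcReport(
        n_input_cells=matrix.n_cells,
        n_low_complexity_removed=int(low.sum()),
        n_doublet_removed=int(high.sum()),
        n_mito_genes_removed=int(mito.sum()),
        n_output_cells=int(keep_cells.sum()),
    )
    if report.n_output_cells == 0:
        raise EmptyMatrixError("no cells survive UMI filtering")
    if not keep_genes.any():
        raise EmptyMatrixError("no genes survive mitochondrial filtering")

    filtered = ExpressionMatrix(
        matrix.values[np.ix_(keep_genes, keep_cells)],
        matrix.genes[keep_genes],
        matrix.cells[keep_cells],
        COUNTS,
    )
    kept_annot = annot.loc[filtered.cells] if annot is not None else None
    return filtered, kept_annot, report


def log_normalize(matrix: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """``value := ln(1 + count * scale_factor / cell_total)`` per cell."""
    if matrix.scale != COUNTS:
        raise PipelineError("log_normalize expects a counts-scale matrix")
    totals = matrix.cell_totals()
    if (totals <= 0).any():
        bad = matrix.cells[totals <= 0].tolist()
        raise PipelineError(f"cells with zero total counts cannot be normalized: {bad[:5]}")
    values = np.log1p(matrix.values * (scale_factor / totals[np.newaxis, :]))
    return ExpressionMatrix(values, matrix.genes, matrix.cells, LOGNORM)
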