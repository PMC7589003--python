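"""Core in-memory containers shared across the pipeline.

The pipeline operates on three data scales: a genes x cells expression
matrix with per-cell annotations, a metabolites x samples abundance table
with injection metadata, and per-embryo absorbance-vs-time kinetic traces.
Each container validates its own invariants on construction so that
downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

COUNTS = "counts"
LOGNORM = "lognorm"

#: annotation columns every cell table must carry
ANNOTATION_COLUMNS = ("population", "genotype", "stage", "total_umi", "mito_fraction")

#: the population label used for cells outside the ectoderm lineage
NON_ECTODERM = "non_ectoderm"


class PipelineError(ValueError):
    """Raised when an input violates a stage's contract."""


class EmptyMatrixError(PipelineError):
    """Raised when a filter leaves no cells (or no genes) behind."""


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with an explicit scale tag.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array, nonnegative, no NaN.
    genes, cells
        Unique, ordered gene symbols and cell barcodes.
    scale
        ``"counts"`` for raw UMI counts, ``"lognorm"`` for
        ``ln(1 + count * scale_factor / cell_total)`` values.
    """

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    scale: str = COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        if self.values.ndim != 2:
            raise PipelineError("expression values must be a 2-D array")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise PipelineError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.genes.has_duplicates:
            dupes = self.genes[self.genes.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate gene symbols: {dupes[:5]}")
        if self.cells.has_duplicates:
            dupes = self.cells[self.cells.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate cell barcodes: {dupes[:5]}")
        if np.isnan(self.values).any():
            raise PipelineError("expression values contain NaN")
        if (self.values < 0).any():
            raise PipelineError("expression values must be nonnegative")
        if self.scale not in (COUNTS, LOGNORM):
            raise PipelineError(f"unknown scale tag {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_totals(self) -> np.ndarray:
        """Per-cell column sums (total UMIs when scale == 'counts')."""
        return self.values.sum(axis=0)

    def gene_vector(self, gene: str) -> np.ndarray:
        if gene not in self.genes:
            raise PipelineError(f"gene {gene!r} not in matrix")
        return self.values[self.genes.get_loc(gene)]

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cells.get_indexer(pd.Index(cells))
        if (idx < 0).any():
            missing = [c for c, i in zip(cells, idx) if i < 0]
            raise PipelineError(f"unknown cell barcodes: {missing[:5]}")
        return ExpressionMatrix(self.values[:, idx], self.genes, pd.Index(cells), self.scale)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise PipelineError(f"unknown genes: {missing[:5]}")
        return ExpressionMatrix(self.values[idx, :], pd.Index(genes), self.cells, self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.genes.copy(), self.cells.copy(), self.scale)


def validate_annotation(annot: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check a cell annotation table (indexed by barcode) for required columns.

    When ``matrix`` is given, the annotation must cover all of its cells.
    """
    for col in ANNOTATION_COLUMNS:
        if col not in annot.columns:
            raise PipelineError(f"annotation missing column {col!r}")
    if annot.index.has_duplicates:
        raise PipelineError("annotation barcodes are not unique")
    if matrix is not None:
        missing = matrix.cells.difference(annot.index)
        if len(missing):
            raise PipelineError(f"annotation missing {len(missing)} cells, e.g. {list(missing[:3])}")
    return annot


@dataclass
class GeneSetCatalog:
    """Named, ordered gene sets; a gene may belong to several sets."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = dict.fromkeys(genes)  # ordered dedup
            if not seen:
                raise PipelineError(f"gene set {name!r} is empty")
            cleaned[name] = list(seen)
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}

    def all_genes(self) -> list[str]:
        out: dict[str, None] = {}
        for genes in self.sets.values():
            out.update(dict.fromkeys(genes))
        return list(out)


@dataclass
class MetaboliteTable:
    """Metabolites x samples abundances plus sample and metabolite metadata.

    ``samples`` is indexed by sample id with columns ``group`` (WT/KO/QC) and
    ``injection_order`` (unique integers); ``metabolites`` is indexed by
    metabolite name with a ``pathway`` column.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    metabolites: pd.DataFrame
    drift_flagged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.abundance.columns.equals(pd.Index(self.samples.index)):
            # allow same members in same order only
            raise PipelineError("abundance columns must equal sample metadata index")
        if "group" not in self.samples.columns or "injection_order" not in self.samples.columns:
            raise PipelineError("sample metadata needs 'group' and 'injection_order'")
        if self.samples["injection_order"].duplicated().any():
            raise PipelineError("injection orders must be unique")
        bad = set(self.samples["group"]) - {"WT", "KO", "QC"}
        if bad:
            raise PipelineError(f"unknown sample groups: {sorted(bad)}")
        if "pathway" not in self.metabolites.columns:
            raise PipelineError("metabolite metadata needs a 'pathway' column")
        if not self.abundance.index.equals(pd.Index(self.metabolites.index)):
            raise PipelineError("abundance rows must equal metabolite metadata index")
        if (self.abundance.values < 0).any():
            raise PipelineError("abundances must be nonnegative")

    def study_samples(self) -> pd.Index:
        return self.samples.index[self.samples["group"] != "QC"]

    def qc_samples(self) -> pd.Index:
        return self.samples.index[self.samples["group"] == "QC"]

    def group_samples(self, group: str) -> pd.Index:
        return self.samples.index[self.samples["group"] == group]


@dataclass
class KineticTrace:
    """A340 absorbance vs time for one embryo in the coupled PFK assay."""

    time_min: np.ndarray
    a340: np.ndarray
    embryo_id: str
    genotype: str

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.time_min.shape != self.a340.shape or self.time_min.ndim != 1:
            raise PipelineError("time and absorbance must be 1-D arrays of equal length")
        if len(self.time_min) < 3:
            raise PipelineError("trace too short")
        if not np.all(np.diff(self.time_min) > 0):
            raise PipelineError("time must be strictly increasing")
        if self.genotype not in ("WT", "KO"):
            raise PipelineError(f"unknown genotype {self.genotype!r}")
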