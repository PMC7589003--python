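"""Readers and writers for the pipeline's on-disk formats.

Expression matrices come in as MatrixMarket triplets (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv``) or as dense CSV with gene rows and cell
columns; gene sets as GMT; metabolite tables as CSV plus two metadata
sheets; kinetic traces as long-format CSV.  All tabular outputs are TSV
with a deterministic row order and fixed float precision so that repeated
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .containers import (
    COUNTS,
    ExpressionMatrix,
    GeneSetCatalog,
    KineticTrace,
    MetaboliteTable,
    PipelineError,
)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters for a pipeline run; all overridable by file or flag."""

    seed: int = 0
    qc_min_umi: int = 200
    qc_max_umi: int = 2500
    qc_mito_prefix: str = "mt-"
    norm_scale_factor: float = 10_000.0
    coexpr_threshold: float = 1.0
    metab_alpha: float = 0.05
    pfk_window_minutes: int = 10
    paths: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.qc_min_umi < self.qc_max_umi:
            raise PipelineError("qc.min_umi must be < qc.max_umi")
        if not 0 < self.metab_alpha < 1:
            raise PipelineError("metab.alpha must lie in (0, 1)")
        if self.coexpr_threshold < 0:
            raise PipelineError("coexpr.threshold must be >= 0")
        if self.norm_scale_factor <= 0:
            raise PipelineError("norm.scale_factor must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML/JSON; dotted keys (``qc.min_umi``) map to fields."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict) and key != "paths":
                for sub, v in value.items():
                    flat[f"{key}_{sub}"] = v
            else:
                flat[key] = value
        flat.update(overrides)
        return cls(**flat)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# expression matrices


def _read_names(path: str | Path, what: str) -> list[str]:
    names = [line.split("\t")[0].strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not names:
        raise PipelineError(f"no {what} found in {path}")
    return names


def read_expression(
    matrix_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    csv_path: str | Path | None = None,
    orientation: str = "genes-by-cells",
) -> ExpressionMatrix:
    """Read a raw-count matrix from MatrixMarket triplet or dense CSV.

    ``orientation`` describes the on-disk MTX layout; the in-memory matrix
    is always genes x cells.
    """
    if csv_path is not None:
        frame = pd.read_csv(csv_path, index_col=0)
        return ExpressionMatrix(frame.to_numpy(float), frame.index.astype(str), frame.columns.astype(str), COUNTS)
    if matrix_path is None or genes_path is None or barcodes_path is None:
        raise PipelineError("need either csv_path or matrix+genes+barcodes paths")
    mat = scipy.io.mmread(str(matrix_path))
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if orientation == "cells-by-genes":
        dense = dense.T
    elif orientation != "genes-by-cells":
        raise PipelineError(f"unknown orientation {orientation!r}")
    genes = _read_names(genes_path, "genes")
    cells = _read_names(barcodes_path, "barcodes")
    if dense.shape != (len(genes), len(cells)):
        raise PipelineError(
            f"matrix is {dense.shape} but name files list {len(genes)} genes "
            f"and {len(cells)} barcodes"
        )
    return ExpressionMatrix(dense, genes, cells, COUNTS)


def write_expression_csv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def write_expression_mtx(matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), scipy.sparse.coo_matrix(matrix.values))
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.genes))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cells))


def read_expression_dir(in_dir: str | Path, orientation: str = "genes-by-cells") -> ExpressionMatrix:
    d = Path(in_dir)
    return read_expression(d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", orientation=orientation)


# ---------------------------------------------------------------------------
# gene sets and target lists


def read_gene_sets(gmt_path: str | Path) -> GeneSetCatalog:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(gmt_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise PipelineError(f"{gmt_path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if not genes:
            raise PipelineError(f"{gmt_path}:{lineno}: gene set {name!r} is empty")
        sets[name] = genes
    return GeneSetCatalog(sets)


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in catalog.sets.items()]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_target_list(path: str | Path) -> list[str]:
    """One gene symbol per line; order preserved, duplicates dropped."""
    genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return list(dict.fromkeys(genes))


def write_target_list(targets: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in targets))


# ---------------------------------------------------------------------------
# annotation / metabolite / trace tables


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep=None, engine="python", index_col=0)
    annot.index = annot.index.astype(str)
    return annot


def read_metabolite_table(
    abundance_csv: str | Path, samples_csv: str | Path, metabolites_csv: str | Path
) -> MetaboliteTable:
    abundance = pd.read_csv(abundance_csv, index_col=0)
    samples = pd.read_csv(samples_csv, index_col=0)
    metabolites = pd.read_csv(metabolites_csv, index_col=0)
    return MetaboliteTable(abundance, samples.loc[abundance.columns], metabolites.loc[abundance.index])


def write_metabolite_table(table: MetaboliteTable, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.abundance.to_csv(out / "abundance.csv")
    table.samples.to_csv(out / "samples.csv")
    table.metabolites.to_csv(out / "metabolites.csv")


def read_traces(path: str | Path) -> list[KineticTrace]:
    """Long CSV with columns time_min, a340, embryo_id, genotype."""
    frame = pd.read_csv(path)
    traces = []
    for embryo, sub in frame.groupby("embryo_id", sort=True):
        sub = sub.sort_values("time_min")
        genotypes = sub["genotype"].unique()
        if len(genotypes) != 1:
            raise PipelineError(f"embryo {embryo} has conflicting genotypes")
        traces.append(KineticTrace(sub["time_min"].to_numpy(), sub["a340"].to_numpy(), str(embryo), genotypes[0]))
    return traces


def write_traces(traces: Sequence[KineticTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"time_min": t.time_min, "a340": t.a340, "embryo_id": t.embryo_id, "genotype": t.genotype}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result tables


def write_table(result: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with deterministic row order.

    Rows are sorted by ``sort_by`` (default: every non-float column, left to
    right) and floats rendered at fixed precision, so writing the same
    result twice yields byte-identical files.
    """
    frame = result.reset_index() if result.index.name else result.copy()
    if sort_by is None:
        sort_by = [c for c in frame.columns if not pd.api.types.is_float_dtype(frame[c])]
    if sort_by:
        frame = frame.sort_values(list(sort_by), kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
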