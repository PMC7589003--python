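"""Synthetic data generators with serialized ground truth.

Every pipeline input can be generated here at a known ground truth:

* population- and genotype-structured single-cell count matrices
  (negative-binomial counts, per-gene knockout multipliers, a latent
  "cycling" state that drives cell-cycle gene co-expression, and library
  sizes that straddle the QC thresholds);
* log-normal metabolite abundance tables with multiplicative
  injection-order drift and pooled-QC samples every six injections;
* lag/linear/plateau absorbance traces with Gaussian noise;
* predicted-target gene lists with controlled pathway nesting.

Injected knockout multipliers act on absolute per-cell expected counts.
Because per-cell normalization measures relative abundance, fold changes
estimated downstream carry a compositional factor ``1 + s (m - 1)`` where
``s`` is the perturbed genes' share of the library; keep that share small
(as the default configs do) when exact multiplier recovery matters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import catalogs
from .containers import (
    COUNTS,
    ExpressionMatrix,
    GeneSetCatalog,
    KineticTrace,
    MetaboliteTable,
    PipelineError,
)

DEFAULT_POPULATIONS = {
    "forebrain": 300,
    "midbrain": 300,
    "hindbrain": 300,
    "neural_crest": 300,
    "non_neural_ectoderm": 300,
    "non_ectoderm": 300,
}

# study-scale misregulation of the three upper-glycolysis targets,
# plus a mild knockdown of the folate pathway
DEFAULT_GENOTYPE_MULTIPLIERS = {"Pfkp": 4.5, "Pfkfb3": 2.5, "Hk1": 2.0}


@dataclass
class GroundTruth:
    """Injected effects serialized alongside every simulated dataset."""

    seed: int = 0
    gene_fold_changes: dict = field(default_factory=dict)
    pathway_fold_changes: dict = field(default_factory=dict)
    subpathway_fold_changes: dict = field(default_factory=dict)
    cycling_rates: dict = field(default_factory=dict)
    population_pathway_multipliers: dict = field(default_factory=dict)
    stage_pathway_multipliers: dict = field(default_factory=dict)
    qc_fail_cells: dict = field(default_factory=dict)
    metabolite_fold_changes: dict = field(default_factory=dict)
    drift_slope: float | None = None
    trace_slopes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass
class ScSimConfig:
    """Study conditions for the single-cell simulator.

    Defaults emulate the cranial dissociation scale used throughout the
    analysis: five ectoderm-derived populations plus a non-ectoderm pool,
    overdispersed counts (negative binomial, dispersion 0.5), libraries
    around 1100 UMIs with small debris and doublet fractions so the
    200/2500 UMI filters are exercised, and knockout multipliers on the
    three upper-glycolysis targets.
    """

    populations: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    catalog: GeneSetCatalog | None = None
    subpathways: GeneSetCatalog | None = None
    n_background_genes: int = 200
    baseline_mean_range: tuple[float, float] = (0.2, 3.0)
    dispersion: float = 0.5
    library_mean: float = 1100.0
    library_sigma: float = 0.25
    debris_rate: float = 0.03
    doublet_rate: float = 0.03
    genotype_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_MULTIPLIERS)
    )
    stage_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"E8.25": 0.5, "E9.5": 0.5}
    )
    stage_pathway_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"folic acid metabolism": 1.3, "antioxidant activity": 0.8}
    )
    population_effect_sigma: float = 0.10
    cycling_rate_wt: float = 0.10
    cycling_rate_ko: float = 0.16
    cycling_genes: tuple[str, ...] = tuple(catalogs.CELL_CYCLE_GENES)
    cycling_base_mean: float = 0.05
    cycling_boost: float = 60.0
    mito_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise PipelineError("negative binomial dispersion must be > 0")
        if any(n < 1 for n in self.populations.values()):
            raise PipelineError("every population needs at least one cell")
        if any(m <= 0 for m in self.genotype_multipliers.values()):
            raise PipelineError("genotype multipliers must be positive")


@dataclass
class ScDataset:
    matrix_wt: ExpressionMatrix
    matrix_ko: ExpressionMatrix
    annot_wt: pd.DataFrame
    annot_ko: pd.DataFrame
    catalog: GeneSetCatalog
    subpathways: GeneSetCatalog
    truth: GroundTruth


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def generate_sc_dataset(config: ScSimConfig | None = None) -> ScDataset:
    """Simulate wild-type and knockout count matrices with annotations.

    Counts follow ``NB(mean = baseline x population effect x stage effect x
    genotype multiplier x cycling boost x library factor, dispersion)``.
    The per-cell library factor scales baseline means so the expected
    wild-type library equals the drawn library size.  The ground truth
    records all injected multipliers, the cycling rates, and — computed on
    the realized counts — the cells that fall outside the UMI filters.
    """
    config = config or ScSimConfig()
    rng = np.random.default_rng(config.seed)
    catalog = config.catalog or catalogs.metabolic_catalog()
    subpathways = config.subpathways or catalogs.glycolysis_subpathways()

    background = [f"Bg{i:03d}" for i in range(1, config.n_background_genes + 1)]
    genes = list(
        dict.fromkeys(
            catalog.all_genes()
            + list(config.cycling_genes)
            + catalogs.MITO_GENES
            + background
        )
    )
    gene_idx = pd.Index(genes)
    n_genes = len(genes)

    lo, hi = config.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    is_mito = gene_idx.str.startswith("mt-")
    base[is_mito] = config.mito_mean
    for g in config.cycling_genes:
        base[gene_idx.get_loc(g)] = config.cycling_base_mean

    # structural multipliers drawn once per dataset
    pop_mult = {
        (pathway, population): float(rng.lognormal(0.0, config.population_effect_sigma))
        for pathway in catalog.names
        for population in config.populations
    }
    stage_names = list(config.stage_fractions)
    geno_vector = {
        "WT": np.ones(n_genes),
        "KO": np.array([config.genotype_multipliers.get(g, 1.0) for g in genes]),
    }
    cyc_idx = gene_idx.get_indexer([g for g in config.cycling_genes if g in gene_idx])
    cycling_rate = {"WT": config.cycling_rate_wt, "KO": config.cycling_rate_ko}

    matrices: dict[str, ExpressionMatrix] = {}
    annots: dict[str, pd.DataFrame] = {}
    qc_fail: dict[str, dict[str, list[str]]] = {}
    for genotype in ("WT", "KO"):
        cols, barcodes, pops, stages = [], [], [], []
        for population, n_cells in config.populations.items():
            # structural expectation per gene for this population (pre-genotype)
            rel = base.copy()
            for pathway in catalog.names:
                members = gene_idx.get_indexer([g for g in catalog[pathway] if g in gene_idx])
                rel[members] = rel[members] * pop_mult[(pathway, population)]
            stage_rel = {}
            for stage in stage_names:
                sr = rel.copy()
                if stage == "E9.5":
                    for pathway, mult in config.stage_pathway_multipliers.items():
                        if pathway in catalog:
                            members = gene_idx.get_indexer(
                                [g for g in catalog[pathway] if g in gene_idx]
                            )
                            sr[members] = sr[members] * mult
                stage_rel[stage] = sr

            cell_stages = rng.choice(
                stage_names, size=n_cells, p=np.array(list(config.stage_fractions.values()))
            )
            # library sizes: mostly lognormal, with debris and doublet tails
            kind = rng.choice(
                ["debris", "doublet", "normal"],
                size=n_cells,
                p=[config.debris_rate, config.doublet_rate, 1 - config.debris_rate - config.doublet_rate],
            )
            libs = np.exp(
                rng.normal(np.log(config.library_mean) - config.library_sigma**2 / 2,
                           config.library_sigma, n_cells)
            )
            libs[kind == "debris"] = rng.uniform(50, 250, (kind == "debris").sum())
            libs[kind == "doublet"] = rng.uniform(2300, 5000, (kind == "doublet").sum())
            cycling = rng.random(n_cells) < cycling_rate[genotype]

            means = np.empty((n_genes, n_cells))
            for stage in stage_names:
                mask = cell_stages == stage
                if not mask.any():
                    continue
                sr = stage_rel[stage]
                means[:, mask] = sr[:, None] * (libs[mask][None, :] / sr.sum())
            means = means * geno_vector[genotype][:, None]
            boost = np.ones((len(cyc_idx), n_cells))
            boost[:, cycling] = config.cycling_boost
            means[cyc_idx, :] *= boost

            counts = _nb_counts(rng, means, config.dispersion)
            cols.append(counts)
            barcodes.extend(f"{genotype}_{population}_{i:04d}" for i in range(n_cells))
            pops.extend([population] * n_cells)
            stages.extend(cell_stages.tolist())

        values = np.concatenate(cols, axis=1)
        matrix = ExpressionMatrix(values, gene_idx, pd.Index(barcodes), COUNTS)
        totals = matrix.cell_totals()
        mito_frac = values[is_mito].sum(axis=0) / np.maximum(totals, 1)
        annot = pd.DataFrame(
            {
                "population": pops,
                "genotype": genotype,
                "stage": stages,
                "total_umi": totals.astype(int),
                "mito_fraction": mito_frac,
            },
            index=matrix.cells,
        )
        matrices[genotype] = matrix
        annots[genotype] = annot
        qc_fail[genotype] = {
            "low": matrix.cells[totals < 200].tolist(),
            "high": matrix.cells[totals > 2500].tolist(),
        }

    multipliers = dict(config.genotype_multipliers)
    pathway_fc = {
        name: float(np.mean([multipliers.get(g, 1.0) for g in catalog[name]]))
        for name in catalog.names
    }
    subpathway_fc = {
        name: float(np.mean([multipliers.get(g, 1.0) for g in subpathways[name]]))
        for name in subpathways.names
    }
    truth = GroundTruth(
        seed=config.seed,
        gene_fold_changes=multipliers,
        pathway_fold_changes=pathway_fc,
        subpathway_fold_changes=subpathway_fc,
        cycling_rates=dict(cycling_rate),
        population_pathway_multipliers={f"{p}|{q}": v for (p, q), v in pop_mult.items()},
        stage_pathway_multipliers=dict(config.stage_pathway_multipliers),
        qc_fail_cells=qc_fail,
    )
    return ScDataset(
        matrices["WT"], matrices["KO"], annots["WT"], annots["KO"], catalog, subpathways, truth
    )


# ---------------------------------------------------------------------------
# metabolomics


def generate_metabolite_dataset(
    metabolite_fcs: Mapping[str, float] | None = None,
    pathways: Mapping[str, str] | None = None,
    *,
    n_per_group: int = 5,
    cv: float = 0.2,
    drift_slope: float = 0.0,
    qc_every: int = 6,
    qc_cv: float = 0.0,
    base_log_mean: float = np.log(1e4),
    base_log_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[MetaboliteTable, GroundTruth]:
    """Simulate an LC/MS abundance table with pooled-QC injections.

    Abundances are log-normal around a per-metabolite base level with the
    given coefficient of variation; knockout samples carry the injected
    fold changes.  A multiplicative drift ``1 + drift_slope * (order - 1)``
    acts on every injection; pooled QC samples — the equal-mix pool of both
    groups' expected levels — open the run, close it, and recur every
    ``qc_every`` study injections.
    """
    if n_per_group < 2:
        raise PipelineError("need at least 2 samples per group")
    if metabolite_fcs is None:
        metabolite_fcs = {name: fc for name, (pw, fc) in catalogs.DEFAULT_METABOLITES.items()}
        pathways = {name: pw for name, (pw, fc) in catalogs.DEFAULT_METABOLITES.items()}
    if pathways is None:
        pathways = {name: "other" for name in metabolite_fcs}
    rng = np.random.default_rng(seed)

    study_ids = [f"WT_{i+1}" for i in range(n_per_group)] + [f"KO_{i+1}" for i in range(n_per_group)]
    order = rng.permutation(len(study_ids))
    injected = [study_ids[i] for i in order]

    sequence: list[str] = []
    qc_counter = 0

    def _qc() -> str:
        nonlocal qc_counter
        qc_counter += 1
        return f"QC_{qc_counter}"

    sequence.append(_qc())
    for i, sid in enumerate(injected):
        sequence.append(sid)
        if (i + 1) % qc_every == 0 and i + 1 < len(injected):
            sequence.append(_qc())
    sequence.append(_qc())

    n_inj = len(sequence)
    if drift_slope <= -1.0 / max(n_inj - 1, 1):
        raise PipelineError("drift_slope would drive abundances non-positive")
    drift = 1.0 + drift_slope * np.arange(n_inj)

    names = list(metabolite_fcs)
    base = np.exp(rng.normal(base_log_mean, base_log_sigma, len(names)))
    fcs = np.array([metabolite_fcs[m] for m in names])
    sigma_ln = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    sigma_qc = np.sqrt(np.log1p(qc_cv**2)) if qc_cv > 0 else 0.0

    values = np.empty((len(names), n_inj))
    groups = []
    for j, sample in enumerate(sequence):
        if sample.startswith("QC"):
            pool = base * (1.0 + fcs) / 2.0
            noise = np.exp(rng.normal(0.0, sigma_qc, len(names))) if sigma_qc else 1.0
            values[:, j] = pool * noise * drift[j]
            groups.append("QC")
        else:
            group = "KO" if sample.startswith("KO") else "WT"
            level = base * (fcs if group == "KO" else 1.0)
            noise = np.exp(rng.normal(0.0, sigma_ln, len(names))) if sigma_ln else 1.0
            values[:, j] = level * noise * drift[j]
            groups.append(group)

    abundance = pd.DataFrame(values, index=pd.Index(names, name="metabolite"), columns=sequence)
    samples = pd.DataFrame(
        {"group": groups, "injection_order": np.arange(1, n_inj + 1)},
        index=pd.Index(sequence, name="sample"),
    )
    metabolites = pd.DataFrame(
        {"pathway": [pathways.get(m, "other") for m in names]},
        index=pd.Index(names, name="metabolite"),
    )
    table = MetaboliteTable(abundance, samples, metabolites)
    truth = GroundTruth(
        seed=seed, metabolite_fold_changes=dict(metabolite_fcs), drift_slope=drift_slope
    )
    return table, truth


# ---------------------------------------------------------------------------
# PFK traces


DEFAULT_TRACE_SLOPES = {
    "WT_1": ("WT", -0.02), "WT_2": ("WT", -0.02), "WT_3": ("WT", -0.02),
    "KO_1": ("KO", -0.03), "KO_2": ("KO", -0.03), "KO_3": ("KO", -0.03),
}


def generate_pfk_traces(
    slopes: Mapping[str, tuple[str, float]] | None = None,
    *,
    lag_min: float = 5.0,
    linear_min: float = 30.0,
    noise_sd: float = 0.002,
    a0: float = 1.0,
    total_min: float = 60.0,
    step_min: float = 1.0,
    seed: int = 0,
) -> tuple[list[KineticTrace], GroundTruth]:
    """Piecewise lag/linear/plateau absorbance traces with Gaussian noise.

    Absorbance sits at ``a0`` for ``lag_min``, changes at the embryo's slope
    for ``linear_min``, then plateaus; sampling is every ``step_min`` over
    ``total_min`` (the assay's 1-minute grid over an hour by default).
    """
    if lag_min + linear_min > total_min:
        raise PipelineError("lag + linear segments exceed the acquisition window")
    slopes = dict(slopes or DEFAULT_TRACE_SLOPES)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_min + step_min / 2, step_min)
    traces = []
    for embryo_id, (genotype, slope) in slopes.items():
        linear_part = np.clip(t - lag_min, 0.0, linear_min)
        y = a0 + slope * linear_part
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, len(t))
        traces.append(KineticTrace(t.copy(), y, embryo_id, genotype))
    truth = GroundTruth(
        seed=seed, trace_slopes={eid: s for eid, (_, s) in slopes.items()}
    )
    return traces, truth


# ---------------------------------------------------------------------------
# target lists


def generate_target_list(
    catalog: GeneSetCatalog,
    subpathways: GeneSetCatalog,
    *,
    n_in_pathway: int = 12,
    n_in_subpathway: int = 4,
    pathway: str = "glycolysis",
    subpathway: str = "upper_glycolysis",
    n_outside: int = 8,
    seed: int = 0,
) -> list[str]:
    """Sample a predicted-target list with controlled pathway nesting.

    Exactly ``n_in_pathway`` targets fall in ``pathway``, of which exactly
    ``n_in_subpathway`` fall in ``subpathway``; ``n_outside`` extra symbols
    lie outside the catalog entirely.
    """
    rng = np.random.default_rng(seed)
    pathway_genes = set(catalog[pathway])
    sub_genes = [g for g in subpathways[subpathway] if g in pathway_genes]
    rest = [g for g in catalog[pathway] if g not in set(sub_genes)]
    if n_in_subpathway > len(sub_genes) or n_in_pathway - n_in_subpathway > len(rest):
        raise PipelineError("requested target counts exceed available set sizes")
    if n_in_subpathway > n_in_pathway:
        raise PipelineError("nested count exceeds pathway count")
    picked = list(rng.choice(sub_genes, n_in_subpathway, replace=False)) + list(
        rng.choice(rest, n_in_pathway - n_in_subpathway, replace=False)
    )
    picked += [f"Offtgt{i:02d}" for i in range(1, n_outside + 1)]
    rng.shuffle(picked)
    return [str(g) for g in picked]
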