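"""Pooled-QC drift normalization and differential metabolite abundance.

Untargeted LC/MS runs drift over injection order; pooled quality-control
samples (a mixture of all study samples) injected at regular intervals
trace that drift.  Each measurement is divided by the injection-order
linear interpolation between flanking QC values and rescaled by the
metabolite's median QC value, which removes smooth drift while preserving
the abundance scale.  Differential abundance is a per-metabolite two-sided
Student t-test at a configurable alpha with no multiple-testing correction
(a Benjamini-Hochberg column is emitted for reference but does not drive
the significance call); pathway summaries and top-changed rankings sit on
top of the per-metabolite results.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MetaboliteTable, PipelineError


def qc_drift_normalize(table: MetaboliteTable) -> MetaboliteTable:
    """Remove injection-order drift using the pooled-QC samples.

    Per metabolite, every sample value (QC rows included) is divided by the
    linear interpolation of QC values at that sample's injection order —
    beyond the first/last QC the nearest QC value is reused — then rescaled
    by the metabolite's median QC value.  Metabolites with a zero in any QC
    are flagged and left unnormalized.
    """
    qc_ids = table.qc_samples()
    if len(qc_ids) < 2:
        raise PipelineError("drift normalization needs at least 2 QC samples")
    orders = table.samples["injection_order"].astype(float)
    qc_orders = orders[qc_ids].to_numpy()
    sort = np.argsort(qc_orders)
    qc_orders = qc_orders[sort]
    qc_cols = qc_ids[sort]

    out = table.abundance.copy()
    flagged: list[str] = []
    sample_orders = orders[table.abundance.columns].to_numpy()
    for metabolite in table.abundance.index:
        qc_vals = table.abundance.loc[metabolite, qc_cols].to_numpy(float)
        if (qc_vals == 0).any():
            flagged.append(metabolite)
            continue
        drift = np.interp(sample_orders, qc_orders, qc_vals)
        out.loc[metabolite] = table.abundance.loc[metabolite].to_numpy(float) / drift * np.median(qc_vals)
    return MetaboliteTable(out, table.samples.copy(), table.metabolites.copy(), tuple(flagged))


def differential_abundance(
    table: MetaboliteTable,
    alpha: float = 0.05,
    *,
    log_transform: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-metabolite KO-vs-WT two-sided t-test and fold change.

    Student's equal-variance t by default (Welch via ``equal_var=False``);
    the test runs on natural-scale values unless ``log_transform``.  Fold
    change is the ratio of raw group means (KO over WT).  ``significant``
    is exactly ``p < alpha``, uncorrected; ``adjusted_p`` (BH) is reported
    alongside for reference only.
    """
    if not 0 < alpha < 1:
        raise PipelineError("alpha must lie in (0, 1)")
    wt_ids, ko_ids = table.group_samples("WT"), table.group_samples("KO")
    if len(wt_ids) < 2 or len(ko_ids) < 2:
        raise PipelineError("need at least 2 samples per group")
    wt = table.abundance[wt_ids].to_numpy(float)
    ko = table.abundance[ko_ids].to_numpy(float)

    x_wt, x_ko = (np.log(wt), np.log(ko)) if log_transform else (wt, ko)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical rows trip scipy's precision-loss warning; those
        # rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x_ko, x_wt, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: identical values carry no evidence
    degenerate = (x_wt.std(axis=1) == 0) & (x_ko.std(axis=1) == 0)
    pvals[degenerate & (x_wt.mean(axis=1) == x_ko.mean(axis=1))] = 1.0
    pvals = np.where(np.isnan(pvals), 1.0, np.clip(pvals, 0.0, 1.0))

    frame = pd.DataFrame(
        {
            "metabolite": table.abundance.index,
            "fold_change": ko.mean(axis=1) / wt.mean(axis=1),
            "p_value": pvals,
            "adjusted_p": stats.false_discovery_control(pvals, method="bh"),
            "pathway": table.metabolites["pathway"].to_numpy(),
        }
    )
    frame["significant"] = frame["p_value"] < alpha
    return frame.reset_index(drop=True)


def pathway_metabolite_summary(results: pd.DataFrame, table: MetaboliteTable) -> pd.DataFrame:
    """Pathway-level rollup of differential-abundance results.

    ``cumulative_fold_change`` is the ratio of summed KO means to summed WT
    means over the pathway's metabolites ("total pathway pool"); the
    alternative ``mean_fold_change`` (mean of per-metabolite fold changes)
    is always co-reported since the two diverge whenever abundances differ
    in magnitude.  Empty pathways are skipped with a warning.
    """
    wt_ids, ko_ids = table.group_samples("WT"), table.group_samples("KO")
    wt_means = table.abundance[wt_ids].mean(axis=1)
    ko_means = table.abundance[ko_ids].mean(axis=1)
    rows = []
    for pathway, sub in results.groupby("pathway", sort=True):
        if sub.empty:
            warnings.warn(f"pathway {pathway!r} has no metabolites; skipped")
            continue
        members = sub["metabolite"]
        rows.append(
            {
                "pathway": pathway,
                "n_metabolites": len(sub),
                "n_significant": int(sub["significant"].sum()),
                "frac_significant": float(sub["significant"].mean()),
                "cumulative_fold_change": float(ko_means[members].sum() / wt_means[members].sum()),
                "mean_fold_change": float(sub["fold_change"].mean()),
            }
        )
    return pd.DataFrame(rows)


def rank_top_changed(results: pd.DataFrame, n_top: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top significantly up- and downregulated metabolites.

    Significant rows only; ``up`` sorted by fold change descending, ``down``
    ascending, ties broken by p-value then metabolite name.  Lists shorter
    than ``n_top`` are returned whole.
    """
    if results.empty:
        raise PipelineError("no differential-abundance results to rank")
    sig = results[results["significant"]]
    up = sig.sort_values(
        ["fold_change", "p_value", "metabolite"], ascending=[False, True, True], kind="mergesort"
    ).head(n_top)
    down = sig.sort_values(
        ["fold_change", "p_value", "metabolite"], ascending=[True, True, True], kind="mergesort"
    ).head(n_top)
    return up.reset_index(drop=True), down.reset_index(drop=True)
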