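"""Intersection of a predicted miRNA-target list with pathway gene sets.

Target prediction itself is an upstream input (one symbol per line);
this module only computes exact set intersections per pathway or
sub-pathway and can attach gene-level knockout/wild-type fold changes.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .containers import GeneSetCatalog, PipelineError


def intersect_targets(
    target_list: Sequence[str],
    catalog: GeneSetCatalog,
    fc_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per pathway: how many predicted targets fall inside the gene set.

    Returns one row per catalog set with ``n_pathway_genes``,
    ``n_targets_in_pathway`` and the semicolon-joined ``target_genes``
    (in catalog order).  When a gene-level fold-change table (columns
    ``gene``, ``fold_change``) is supplied, each row also carries the mean
    fold change over its in-pathway targets, and a ``per_target_fc`` column
    holds ``gene=fc`` entries.  Empty intersections are valid rows.
    """
    targets = list(dict.fromkeys(target_list))
    if not targets:
        raise PipelineError("target list is empty")
    target_set = set(targets)

    fc_by_gene: dict[str, float] = {}
    if fc_table is not None:
        fc_by_gene = fc_table.groupby("gene")["fold_change"].mean().to_dict()

    rows = []
    for pathway in catalog.names:
        members = catalog[pathway]
        hits = [g for g in members if g in target_set]
        row = {
            "pathway": pathway,
            "n_pathway_genes": len(members),
            "n_targets_in_pathway": len(hits),
            "target_genes": ";".join(hits),
        }
        if fc_table is not None:
            known = [g for g in hits if g in fc_by_gene]
            row["mean_target_fold_change"] = (
                sum(fc_by_gene[g] for g in known) / len(known) if known else float("nan")
            )
            row["per_target_fc"] = ";".join(f"{g}={fc_by_gene[g]:.6g}" for g in known)
        rows.append(row)
    return pd.DataFrame(rows)
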