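"""Pathway scores per population, stage changes, and knockout fold changes.

Computes (i) mean metabolic-pathway expression per ectoderm population with
min-population normalization, (ii) the E8.25 -> E9.5 change in wild type,
and (iii) KO/WT fold changes per pathway and per glycolysis sub-pathway at
E9.5, comparing the estimates against the injected ground truth.
"""

from ntcmetab import (
    genotype_fold_change,
    normalize_to_min_population,
    population_pathway_mean,
    stage_change,
    subpathway_fold_change,
)
from ntcmetab.io import write_table

from _shared import RESULTS, SCRATCH, get_sc_dataset, qc_and_normalize

ds = get_sc_dataset()
wt, annot_wt, _ = qc_and_normalize(ds.matrix_wt, ds.annot_wt)
ko, annot_ko, _ = qc_and_normalize(ds.matrix_ko, ds.annot_ko)

# per-population pathway scores in wild type, normalized to the lowest population
scores = normalize_to_min_population(population_pathway_mean(wt, annot_wt, ds.catalog))
write_table(scores, RESULTS / "pathway_scores_wt.tsv")

# developmental change: wild type E8.25 vs E9.5
early_cells = annot_wt.index[annot_wt["stage"] == "E8.25"]
late_cells = annot_wt.index[annot_wt["stage"] == "E9.5"]
early = population_pathway_mean(wt.subset_cells(early_cells), annot_wt.loc[early_cells], ds.catalog)
late = population_pathway_mean(wt.subset_cells(late_cells), annot_wt.loc[late_cells], ds.catalog)
stage_table = stage_change(early, late)
write_table(stage_table, RESULTS / "stage_change_wt.tsv")
folate = stage_table[stage_table["pathway"] == "folic acid metabolism"]["fold_change"]
print(f"folic acid pathway E8.25->E9.5 score ratio: {folate.mean():.3f} "
      f"(injected count-scale stage multiplier "
      f"{ds.truth.stage_pathway_multipliers['folic acid metabolism']}; "
      f"log-scale scores compress ratios)")

# knockout comparison at E9.5
wt95 = wt.subset_cells(annot_wt.index[annot_wt["stage"] == "E9.5"])
ko95 = ko.subset_cells(annot_ko.index[annot_ko["stage"] == "E9.5"])
args = (wt95, ko95, annot_wt.loc[wt95.cells], annot_ko.loc[ko95.cells])

gene_fc = genotype_fold_change(*args, ds.catalog, "gene")
write_table(gene_fc, SCRATCH / "genotype_fc_gene_full.tsv")  # bulky: all genes x populations
targets = gene_fc[gene_fc["gene"].isin(ds.truth.gene_fold_changes)]
write_table(targets, RESULTS / "genotype_fc_targets.tsv")
for gene, injected in ds.truth.gene_fold_changes.items():
    est = gene_fc[gene_fc["gene"] == gene]["fold_change"].mean()
    print(f"{gene}: estimated KO/WT fold change {est:.2f} (injected {injected})")

write_table(genotype_fold_change(*args, ds.catalog, "ectoderm"), RESULTS / "genotype_fc_ectoderm.tsv")
sub_fc = subpathway_fold_change(*args, ds.subpathways)
write_table(sub_fc, RESULTS / "genotype_fc_subpathway.tsv")
upper = sub_fc[sub_fc["subpathway"] == "upper_glycolysis"]["fold_change"].mean()
print(f"upper glycolysis mean fold change {upper:.2f} "
      f"(injected mean {ds.truth.subpathway_fold_changes['upper_glycolysis']:.2f}); "
      "other sub-pathways stay near 1")
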