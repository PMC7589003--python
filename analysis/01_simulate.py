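"""Simulate every input of the study at a known ground truth.

Writes the full single-cell matrices (bulky) under scratch/sim/, the
metabolite table, kinetic traces and target list alongside, and all
ground-truth JSONs under results/.
"""

from ntcmetab import (
    generate_metabolite_dataset,
    generate_pfk_traces,
    generate_target_list,
)
from ntcmetab.io import (
    write_expression_mtx,
    write_gene_sets,
    write_metabolite_table,
    write_target_list,
    write_traces,
)

from _shared import RESULTS, SCRATCH, SEED, get_sc_dataset

sim_dir = SCRATCH / "sim"
RESULTS.mkdir(exist_ok=True)

ds = get_sc_dataset()
for tag, matrix, annot in (("wt", ds.matrix_wt, ds.annot_wt), ("ko", ds.matrix_ko, ds.annot_ko)):
    write_expression_mtx(matrix, sim_dir / tag)
    annot.to_csv(sim_dir / tag / "annotation.csv")
write_gene_sets(ds.catalog, sim_dir / "catalog.gmt")
write_gene_sets(ds.subpathways, sim_dir / "subpathways.gmt")
ds.truth.to_json(RESULTS / "sc_truth.json")

metab_table, metab_truth = generate_metabolite_dataset(seed=SEED, drift_slope=0.02, qc_cv=0.02)
write_metabolite_table(metab_table, sim_dir / "metab")
metab_truth.to_json(RESULTS / "metab_truth.json")

traces, trace_truth = generate_pfk_traces(seed=SEED)
write_traces(traces, sim_dir / "traces.csv")
trace_truth.to_json(RESULTS / "pfk_truth.json")

targets = generate_target_list(ds.catalog, ds.subpathways, seed=SEED)
write_target_list(targets, sim_dir / "targets.txt")

print(f"single cell: {ds.matrix_wt.n_cells} WT + {ds.matrix_ko.n_cells} KO cells, "
      f"{ds.matrix_wt.n_genes} genes -> {sim_dir}")
print(f"injected knockout multipliers: {ds.truth.gene_fold_changes}")
print(f"metabolites: {metab_table.abundance.shape[0]} x {metab_table.abundance.shape[1]} injections "
      f"(drift slope {metab_truth.drift_slope})")
print(f"traces: {len(traces)} embryos; targets: {len(targets)} predicted")
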