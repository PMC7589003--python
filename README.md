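# ntcmetab

Downstream analyses linking **glycolysis to proliferation during neural
tube closure**: a tested, reusable implementation of the statistics behind
a single-cell + metabolomics + enzymology study of cranial neural tube
defects (NTDs) in mouse.

During neurulation the embryo is hypoxic and runs on glycolysis; a
knockout with a fully penetrant cranial NTD shows upregulated upper
glycolysis (*Pfkp*, *Pfkfb3*, *Hk1*), accumulated glycolytic metabolites,
increased PFK activity, and more cells co-expressing G1/S and G2/M
cell-cycle genes.  This package implements every quantitative step of that
argument as library code over standard formats, with a synthetic-data
module that regenerates all three data scales at known ground truth — so
every estimator has a recovery test.

## What it computes

| stage | statistic |
|---|---|
| `sc_core` | UMI/doublet/mito QC (strict < 200 / > 2500 bounds), counts-per-10⁴ log1p normalization |
| `diffexpr` | per-gene two-sided Wilcoxon rank-sum (tie/continuity corrected), BH adjustment, pseudocounted log2FC; expression-threshold cell subsetting |
| `pathway_scoring` | pathway score `mean_genes(mean_cells(x))` per population; min-population normalization (min ≡ 1); E8.25→E9.5 stage ratios; KO/WT fold change per gene then averaged to pathway/population/ectoderm — `FC_g,p = (mean KO + ε)/(mean WT + ε)` on the linear scale |
| `coexpression` | fraction of cells with both genes > 1 (log scale, strict), KO/WT ratios on fraction and count bases |
| `target_overlap` | exact intersection of a predicted-miRNA-target list with pathway/sub-pathway sets |
| `metabolomics` | pooled-QC injection-order drift normalization; Student t-tests at α = 0.05 (uncorrected, by design); pathway pools and top-changed ranking |
| `pfk_kinetics` | sliding-window OLS on A340 traces (|slope|-max among windows with r² ≥ 0.95), KO/WT activity ratio |
| `synthetic` | NB single-cell counts, log-normal LC/MS tables with drift + pooled QCs, lag/linear/plateau kinetic traces, nested target lists — all with serialized `GroundTruth` |

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```sh
cd analysis
python 01_simulate.py && python 03_pathway_scores.py && python 06_pfk_kinetics.py
```

prints (seed 1):

```
injected knockout multipliers: {'Pfkp': 4.5, 'Pfkfb3': 2.5, 'Hk1': 2.0}
...
Pfkp: estimated KO/WT fold change 4.47 (injected 4.5)
Pfkfb3: estimated KO/WT fold change 2.55 (injected 2.5)
Hk1: estimated KO/WT fold change 1.92 (injected 2.0)
upper glycolysis mean fold change 1.41 (injected mean 1.42); other sub-pathways stay near 1
...
KO/WT activity fold change 1.49 (injected 1.50), t-test p = 3.45e-09
```

i.e. the pipeline recovers the injected knockout multipliers on the three
upper-glycolysis targets through the full QC → normalize → fold-change
path, the sub-pathway rollup isolates upper glycolysis, and the kinetic
slope fit recovers the injected 1.5× activity ratio from 3-vs-3 noisy
traces.  Tables land in `results/` as deterministic TSVs.

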