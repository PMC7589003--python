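# Methods

`ntcmetab` implements the downstream statistics of a single-cell +
metabolomics + enzymology study of neural tube closure: how metabolic
pathway expression differs between ectoderm-derived cell populations, how
it changes from E8.25 to E9.5, how it is misregulated in a knockout with a
cranial neural tube defect, and how those transcriptional changes propagate
to metabolite pools and phosphofructokinase (PFK) activity.  This note
records the models, conventions and numerical choices; nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Single-cell QC and normalization

Cells with fewer than 200 or more than 2500 total UMIs are removed
(low-complexity debris and doublets/triplets respectively); the
inequalities are strict, so boundary cells are retained.  Genes whose
symbol starts with the mouse mitochondrial prefix `mt-` are dropped.
Per-cell totals are a property of the sequencing run: `qc_filter` takes
them from the annotation's `total_umi` when an annotation is supplied and
otherwise computes column sums of the input matrix, which makes the filter
idempotent and independent of gene-filtering order.  No statistical doublet
detection is attempted — the upper UMI bound is the doublet rule.

Normalization is counts-per-scale-factor log1p:
`x = ln(1 + c * 10^4 / total)`, the conventional single-cell scale on which
every expression threshold below (notably the co-expression cutoff `> 1`)
operates.  The scale factor 10,000 is configurable.

## Differential expression

`differential_expression` is a deliberately explicit contract: per gene, a
two-sided Wilcoxon rank-sum test (normal approximation with tie and
continuity correction, via `scipy.stats.mannwhitneyu`) on the
log-normalized values, Benjamini–Hochberg adjustment across tested genes,
and `log2FC = log2((mean_A + 1e-9) / (mean_B + 1e-9))` on the provided
values.  Genes identical across both groups report p = 1; genes silent in
both groups report log2FC 0.  No minimum-fraction or minimum-logFC
prefilters are applied by default (flags exist).  The intent is a
specified, testable re-statement of the conventional marker test, not a
bit-level clone of any toolkit; an independent hand-rolled rank statistic
in the test suite checks the p-values to 1e-9.

`subset_by_expression` selects cells with a gene's normalized expression
strictly above a cutoff.  The upstream description of "upregulated"
high-expressor cells is ambiguous between a fold-change and an expression
threshold; we implement the expression threshold with a configurable
cutoff (default 1.0 on the log scale) and keep the choice visible rather
than silently resolved.

## Pathway scoring and fold-change aggregation

The pathway score for (population, pathway) is the unweighted mean over
member genes of each gene's mean log-normalized expression over the
population's cells.  Genes equally weighted; genes missing from the matrix
are excluded and counted in `n_genes_used`; a pathway with no matched genes
is emitted flagged, never dropped.  `normalize_to_min_population` divides
each pathway's scores by the lowest-scoring population so the minimum is
exactly 1; `stage_change` is the late/early ratio of pathway means per key.

Genotype fold changes follow a fixed aggregation order: **per-gene first,
then arithmetic mean upward** (to pathway, population, or all ectoderm
populations pooled).  A geometric-mean alternative is available behind the
`agg` flag.  Two deliberate choices:

* **Linear-scale means.**  Per-gene means for fold changes are taken on
  `expm1` of the log-normalized values (i.e. counts per 10^4).  Ratios of
  log1p-compressed means systematically understate expression ratios —
  a 4.5× count change can appear as <2× on the log scale — whereas
  linear-scale mean ratios are consistent estimators of the underlying
  multiplier.  Only the differential-expression report keeps its log2FC on
  the log-scale means, where it is a ranking device rather than an
  estimator.
* **Compositional caveat.**  Normalized expression is relative abundance;
  if perturbed genes carry a share `s` of the library, every estimated fold
  change is divided by `1 + s(m − 1)`.  The simulator's defaults keep
  perturbed shares at the percent level, where the bias is ≤ ~3%; the
  recovery tests are designed under the same condition.

Sub-pathway fold changes apply the same machinery to the six glycolysis
subdivisions (glucose import/phosphorylation, upper glycolysis, lower
glycolysis, the shift into oxidative phosphorylation, gluconeogenesis,
pentose phosphate); overlapping sets are allowed, and each set contributes
independently.

## Co-expression

A cell co-expresses a pair when both log-normalized values are strictly
`> 1` (configurable).  Genotype comparisons default to the **fraction**
basis because wild-type and knockout datasets have unequal cell totals;
the raw-count ratio is always co-reported for comparability with
cell-count readouts.  Zero wild-type quantities leave the ratio flagged
undefined rather than infinite.

## Target–pathway intersection

Predicted miRNA targets are an input list (one symbol per line; prediction
is database-version-dependent and out of scope).  `intersect_targets`
computes exact, deduplicated set intersections per pathway/sub-pathway and
can join per-gene knockout fold changes.  Symbols are case-sensitive and
matched exactly; unmatched entries simply do not intersect.

## Metabolomics

**Drift normalization.**  Pooled-QC samples injected at the start, end and
every six study injections trace instrument drift.  Per metabolite, each
value is divided by the linear interpolation of QC values at its injection
order (nearest QC reused beyond the ends) and rescaled by the metabolite's
median QC value, preserving the abundance scale.  Exactly linear drift is
removed completely (post-normalization QC CV < 1e-9, asserted); the
procedure is idempotent to 1e-9.  A metabolite with a zero in any QC is
flagged and left untouched.

**Differential abundance.**  Per metabolite, a two-sided equal-variance
Student t-test (Welch behind a flag) on natural-scale values (log behind a
flag), KO-over-WT fold change on raw group means, significance at the
configured α = 0.05 with **no multiple-testing correction** — that is the
convention of the assay this reimplements; a BH column is emitted for
reference only and never drives the `significant` flag.  Identical
zero-variance groups report p = 1.

**Pathway summaries.**  "Cumulative" pathway fold change is under-defined
in common usage; we default to the sum ratio (total KO pool over total WT
pool, reading as the change in the total pathway pool) and always
co-report the mean of per-metabolite fold changes, since the two diverge
whenever abundances span magnitudes.  Top-changed rankings consider
significant metabolites only, ties broken by p then name.

## PFK kinetics

The coupled assay converts PFK flux into an A340 change, sampled every
minute for 60 minutes.  "Linear portion" is operationalized as a sliding
window: every minimal contiguous window spanning ≥ `window_minutes`
(default 10, ≥ 5 points) is fit by OLS; among windows with r² ≥ 0.95 the
largest |slope| wins (earliest start on ties), falling back to the best-r²
window with a flag when none qualifies.  Activity is |slope| — the module
is agnostic about whether the cascade consumes or produces NADH.  Molar
conversion (ε_NADH = 6220 M⁻¹cm⁻¹) is deliberately omitted from defaults:
only slopes and their genotype ratio are compared.  The genotype comparison
is the ratio of mean activities with a two-sided t-test.

## The simulator and what passing tests show

`ntcmetab.synthetic` generates every input with serialized ground truth.

*Single cell*: counts are Gamma–Poisson (negative binomial, dispersion 0.5,
`var = μ + 0.5 μ²` — standard scRNA-seq overdispersion).  Defaults: six
populations (five ectoderm-derived + a non-ectoderm pool) × 300 cells per
genotype; per-gene baselines log-uniform in [0.2, 3] expected counts;
per-(pathway, population) log-normal effects (σ = 0.1) giving each pathway
a genuine minimum population; stage effects on E9.5 (folate 1.3×,
antioxidant 0.8×); knockout multipliers on the three upper-glycolysis
targets (4.5 / 2.5 / 2); libraries log-normal around 1100 UMIs with 3%
debris (50–250 UMIs) and 3% doublet (2300–5000) tails so both QC filters
fire on truth-recorded cells.  Co-expression is induced by a latent
Bernoulli "cycling" state (rate 0.10 WT vs 0.16 KO, ratio 1.6) that boosts
the cyclin/Cdk genes' means 60-fold, so the realized co-expression
fraction tracks the cycling rate.

*Metabolomics*: log-normal abundances (base levels log-normal around 10⁴),
configurable CV (default 20%), multiplicative linear drift over injection
order, pooled-QC rows as described above; default injected effects:
fructose bisphosphate 1.9×, phosphoenolpyruvate 1.6×, pyruvate 1.4×,
ATP 1.8×, docosapentaenoic acid 2.2×, saturated fatty acids 0.7–0.8×.

*Kinetics*: flat lag (5 min), linear segment (30 min at the embryo's
slope), plateau; Gaussian noise σ = 0.002; defaults 3 WT at −0.02/min vs
3 KO at −0.03/min (ratio 1.5).

The simulator does **not** emulate ambient RNA, batch effects, UMI
saturation, cell-type misassignment, correlated gene programs beyond the
cycling state, heavy-tailed metabolite noise, or retention-time-dependent
LC/MS artifacts.  Passing recovery tests therefore demonstrate that the
estimators are correct and calibrated under their stated sampling models —
not that real datasets of this design would yield the same power or bias.

## Problem sizes and determinism

Recovery tests use 150–2000 cells/population, 10 seeds where a criterion is
"≥ 9/10 seeds", 600–1000 metabolites for calibration checks, and ≤ 20 × 50
fixtures for brute-force equivalence (exact for integer counts, 1e-9
relative for floats) — sizes chosen so the whole suite runs in well under a
minute of simulation time while keeping Monte-Carlo tolerances at ≥ 2–3
standard errors.  All randomness flows through `numpy.random.default_rng`
with explicit seeds; the same seed reproduces byte-identical generator
output, and `write_table` emits sorted rows at fixed float precision so
repeated runs are byte-identical.

## Known limitations

* Fold-change estimators are ratio-of-means; for very weakly expressed
  genes (< ~0.3 expected counts/cell) their sampling noise is large and the
  ±10–15% recovery bands hold only at the cell counts the tests state.
* The compositional bias described above is inherent to relative-abundance
  data and is not corrected, only kept small by design.
* The Wilcoxon implementation uses the asymptotic approximation throughout;
  at very small group sizes exact-test p-values would differ.
* Linear QC interpolation removes smooth drift only; abrupt instrument
  shifts between flanking QCs are attenuated, not eliminated.
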