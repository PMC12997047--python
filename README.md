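# lipocurve

A workflow for untargeted cell lipidomics that uses a **cell-count
calibration curve** to decide which LC-MS chemical signals actually come
from the cells.

## The problem

Untargeted LC-MS lipidomics of cultured or isolated cells produces a matrix
of thousands of chemical signals (deconvoluted *m/z* × retention-time
features) per injection. Many of those signals are not cellular at all:
extraction background, plasticware contaminants, culture-media carry-over.
When cell input is low — sorted T cells, endothelial monolayers — such
signals can dominate the matrix, mask biology and distort normalization
denominators such as the total useful signal (TUS).

`lipocurve` implements the curve-based remedy: a series of samples with
known, increasing cell counts (e.g. 50k, 100k, 250k, 500k, 750k, 1M cells)
is analyzed alongside the experimental samples. A signal is called
*cell-derived* when its abundance rises monotonically with cell count:

> keep signal *i* ⇔ Spearman ρ(counts, abundance_i) ≥ 0.7 and *p* < 0.05

computed over every contiguous window of at least three distinct cell counts
(for 6 counts: 10 windows), with selection done on the widest window by
default. The correlation p-values are deliberately not adjusted for
multiplicity — the step is a conservative filter, not inferential testing.

Around that core the package provides the full pipeline:

* **QA cascade** — blank exceedance, detection in ≥ 75 % of pooled-QC
  injections, k-NN imputation of missing values, and removal of signals with
  QC CV > 30 %;
* **QC-anchored corrections** — inter-batch rescaling from per-batch QC
  medians, and SVR-based injection-order drift correction with a per-signal
  revert guard;
* **normalizations** — by cell count, by TUS, by per-signal median, plus the
  log₁₀ + range-scaling transform used before PCA/HC;
* **differential testing** — per-signal Shapiro–Wilk/Levene gating into a
  two-way mixed ANOVA (time as a paired within-subject factor, group
  between-subjects) or an aligned-rank-transform (ART) ANOVA, with
  Benjamini–Hochberg adjustment per effect and the dual threshold
  *p* < 0.05 ∧ *p*<sub>adj</sub> < 0.2;
* **diagnostics** — PCA explained variance, hierarchical clustering
  (Euclidean, complete linkage), QC-dispersion checks;
* **a simulator** — synthetic feature matrices with known ground truth
  (cell/background/media origins, lognormal noise, MNAR censoring at the
  detection limit, injection-order drift, a mid-worklist batch break) for
  validating every stage.

## Worked example

```bash
lipocurve simulate --design cd3 --seed 3 --out demo
lipocurve run --feature-table demo/feature_table.csv \
              --metadata demo/metadata.csv --out demo/run
```

The `run` summary printed for this seed:

```json
{
  "interbatch_corrected": true,
  "interval": [50000, 1000000],
  "k_input": 1220,
  "k_qa": 1220,
  "k_selected": 79,
  "pc1_all": 0.365,
  "pc1_selected": 0.949,
  "qc_cluster_pass": true,
  "qc_dispersion_ratio": 0.063
}
```

Reading it: the simulated worklist contains 1220 signals (70 truly
cell-derived, the rest background or media). After batch correction and QA,
widest-interval Spearman selection keeps 79 signals. On all QA signals the
first principal component explains only 37 % of the variance — the samples
do not organize by cell count. Restricted to the selected signals, PC1
explains 95 % and the score plot orders the samples from 50k to 1M cells;
the pooled QCs sit in a tight cluster (dispersion ratio 0.06). The
`demo/run/` directory holds the per-stage tables: `qa_report.csv`,
`selection.csv`, the chord-diagram edge list `interval_edges.csv`, PCA
scores/loadings/variances, the HC linkage table and, for experimental
designs, the differential tables and the standard-vs-correlation Venn
partition.

The same operations are available as a library:

```python
import lipocurve as lc

cfg = lc.SimConfig.cd3_curve(seed=3)
matrix, samples, truth = lc.simulate_cell_curve(cfg)
corrected, _ = lc.interbatch_qc_median(matrix, samples)
qa_matrix, report = lc.run_qa(corrected, samples)
sel = lc.select_correlated(qa_matrix, samples, lc.widest_interval(samples))
```

## Layout

```
src/lipocurve/
  core.py         shared domain types (FeatureMatrix, SampleInfo, ...)
  io.py           CSV/YAML readers and writers, WorkflowConfig
  simulate.py     synthetic designs with ground truth
  qa.py           blank / QC-presence / k-NN imputation / CV cascade
  normalize.py    batch, drift, cell-count, TUS, median, log-range
  correlation.py  interval enumeration and Spearman selection
  stats.py        gated mixed / ART ANOVA, BH, approach comparison
  diagnostics.py  PCA, hierarchical clustering, TUS, QC dispersion
  cli.py          `lipocurve` subcommands and the end-to-end pipeline
```

See `docs/methods.md` for the statistical details and design choices.
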