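# Methods

This note documents the statistical model behind `lipocurve`, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical decisions a maintainer should know about.

## 1. The selection model

The working assumption is that a cell-derived chemical signal *i* is
proportional to cell input with multiplicative instrument noise,

    a_ij = β_i · c_j · ε_ij ,        ε lognormal, E[ε] = 1, sd/mean = CV,

while background and media signals are independent of *c*. Spearman rank
correlation is the natural test of this monotone relationship: it is
invariant to any strictly increasing per-signal transform (so selection
commutes with median normalization and log scaling), and it does not assume
linearity on the measured scale.

**Intervals.** Correlations are computed over every contiguous window of
the sorted distinct counts with at least three counts (`min_interval_counts
= 3`); non-contiguous subsets are not enumerated. Six counts yield 10
windows, four counts yield 3. All replicate samples inside the window are
used as correlation units (6 counts × 5 replicates → n = 30), with
tied x handled by mid-ranks. The widest window is the default working
interval; the per-interval selection counts are emitted as a chord-diagram
edge list so a user can judge whether an interior window (e.g. when the
extreme counts are noisy or censored) would serve better.

**Thresholds.** A signal is selected iff ρ ≥ 0.7 (boundary inclusive;
`rho_boundary_inclusive=False` gives the strict variant) and two-sided
p < 0.05, unadjusted. Positivity is enforced by the ρ threshold rather than
a one-sided test; `one_sided_corr=True` halves the p-values for users who
prefer the one-sided formulation.

**p-values.** ρ is the Pearson correlation of mid-ranks; p comes from
t = ρ·√((n−2)/(1−ρ²)) on n−2 df, with p = 0 at |ρ| = 1 and (ρ undefined,
p = 1) for constant abundances — undefined ρ is never selected. Two
numerical details: correlations within 10⁻¹² of ±1 are snapped to ±1 (the
nearest attainable non-unit rank correlation is O(1/n³) away, far above
float error), and for n ≤ 7 the t-approximation was checked against the
exact permutation null: because the permutation distribution is discrete,
the t-based p is compared to the [strict, inclusive] tail bracket and stays
within 0.05 of it (measured once over random tied-x fixtures and frozen as
the documented tolerance).

## 2. QA cascade

Order: blank filter → QC-presence filter → k-NN imputation → CV filter.
The CV filter deliberately sees imputed values, and imputation never alters
observed entries (property-tested).

* **Blank rule.** Conditions are the distinct curve counts plus the
  (timepoint × group) cells of the experiment; a signal passes when its
  condition mean exceeds the blank mean. The default is `any_condition`
  (at least one condition exceeds): requiring every condition to exceed the
  blank would delete genuine signals detectable only at high cell counts.
  `all_conditions` is available; under it a condition with no detections
  counts as failing. Signals absent from all blanks are kept.
* **QC presence.** Keep iff detected in ≥ 75 % of QC injections, boundary
  inclusive (3 of 4 passes).
* **k-NN imputation** (k = 5 by default). Distances between samples are
  Euclidean on per-signal standardized log₁₀ abundances over the signals
  observed in both samples; the neighbours of a missing (signal, sample)
  entry are the k nearest samples *in which that signal was observed*, and
  the imputed value is the median of their log₁₀ values, back-transformed.
  Median aggregation is robust to an outlying neighbour; restricting
  neighbours to samples observing the signal keeps the operation total for
  structurally absent signals (e.g. media signals in curve samples). The
  literal shared-signal Euclidean distance is not rescaled by the number of
  shared signals; with QA-typical missingness (< 15 %) the shared sets are
  nearly complete and the ordering is unaffected.
* **CV filter.** CV = sample sd / mean (ddof 1) over QC injections only —
  QCs are repeated injections of one pool, so their spread is instrument
  precision; computing CV over biological replicates would conflate biology
  with noise. Keep iff CV ≤ 0.30 ("higher than 30 %" is strict); zero mean
  → CV undefined → removed.

## 3. QC-anchored corrections

* **Inter-batch median correction** runs *before* QA whenever the worklist
  has ≥ 2 batches: x → x · m_i / m_{i,b} with m_{i,b} the batch-b QC median
  and m_i the global QC median. Signals with a zero or undefined batch
  median are left uncorrected and flagged. After correction the per-signal
  QC medians agree across batches by construction.
* **Drift correction** fits, per signal, a support-vector regression
  (RBF kernel, ε-insensitive loss; defaults ε = 0.05 on the QC-median
  scale, C = 1, γ = "scale") of QC abundance on injection order, and
  divides every sample by the fitted curve, which rescales each signal to
  its QC median. The hyperparameters are deliberately mild; the safety net
  is the per-signal guard: if the corrected QC CV exceeds the uncorrected
  one, or the fitted curve is non-positive anywhere, the signal reverts to
  its input values. Whether drift correction is needed at all is left to
  the user (`--drift-correct`); the default pipeline applies only the
  batch correction.

## 4. Normalizations and scaling

Cell-count (x/c_j), TUS (x/Σ_i x_ij over retained signals) and per-signal
median (x/median_i) normalizations are provided for the post-selection
comparison; median normalization is strictly increasing per signal and
therefore leaves the Spearman selection invariant (tested end-to-end).
Before PCA/HC the matrix is log₁₀-transformed and **range-scaled**:
z = (y − mean(y))/(max(y) − min(y)) per signal, the standard metabolomics
range scaling; constant signals map to zero. Zeros are replaced by half the
signal's minimum positive value before the log — zeros are rare after QA
and the substitution is the conventional left-censoring stand-in.

## 5. Differential testing

The experiment is a paired 2-level within factor (acute vs baseline, one
pair per subject) crossed with a between-subject group factor.

* **Gate.** Per signal, Shapiro–Wilk on the residuals of the group × time
  cell-means model and median-centred Levene across the six cells, both at
  α = 0.05. Both non-significant → two-way mixed ANOVA; otherwise ART
  ANOVA. `assumption_alpha = 0` disables the gate.
* **Mixed ANOVA.** With exactly two within levels the model reduces
  exactly to per-subject differences d_s and means m_s: the time effect is
  the F-test of the unweighted grand mean of d against the pooled
  within-group error (paired-t² in the one-group case, exact to 1e-10),
  the interaction is the one-way ANOVA of d across groups, the group effect
  the one-way ANOVA of m. The reduction is verified against an independent
  mixed-ANOVA implementation on balanced designs.
* **ART ANOVA.** For each effect, the data are aligned by keeping that
  effect's unweighted cell-means component plus the residual, mid-ranked,
  and pushed through the same reduced F-tests; only the aligned-for
  effect's statistic is kept. All-tied aligned values return F = 0, p = 1
  (not NaN), so BH downstream is total. Under a matched lognormal null both
  routes hold type-I error within [0.03, 0.07] at α = 0.05 (2000
  replicates, 3 × 8 subjects).
* **Multiplicity.** BH step-up per effect across signals (pooling across
  effects available via `bh_pooled`). Significance requires p < 0.05 and
  adjusted p < 0.2 — the exploratory dual threshold.

A property worth knowing: with the dual threshold, the BH step-up settles
at an effective raw-p cutoff t* ≈ sig_padj·R/m. When a fifth of the tested
signals carry strong effects (R ≈ 0.1·m + …), t* lands near 0.02–0.025, so
the *expected* number of null signals crossing it grows linearly with the
null count — about 4–5 for 180 nulls. The recovery test on the standard
experiment fixture observes exactly this behaviour: all 20 planted effects
recovered, with a handful (not ≤ 2) of null signals crossing the dual
threshold. Tightening `sig_padj` is the lever if stricter FDR control is
wanted.

## 6. The simulator

Defaults encode the two study designs: the T-cell curve (6 counts
50k–1M × 5 biological replicates, analyzed in increasing count order,
replicates shuffled within count) and the endothelial experiment (4 counts
25k–100k × 3 technical replicates injected at the beginning, middle and
end of the worklist, plus paired acute/baseline samples from three groups,
8 subjects per group, in randomized order). Shared machinery: pooled QCs
appended after every ~5 injections (pooling treats a missing value as zero,
as physical pooling of equal volumes would), 3 blanks carrying background
at half level, 3 media injections, lognormal noise with CV 0.10,
left-censoring below a detection limit (MNAR — missingness concentrates at
low counts), a mid-worklist batch break (×1.3 by default, removed by the
batch correction) and optional exponential injection-order drift
(`drift_slope`, default 0: the drift correction is exercised by dedicated
tests with planted drift, mirroring the observation that drift demanded
correction only in part of the acquisitions). The experiment can plant a
fold change (default 3) on a fraction (default 0.1) of cell signals at the
acute stage, a shared lognormal subject effect (CV 0.2), and optionally a
spurious acute-stage artifact on background signals to probe the
standard-vs-correlation comparison.

Not emulated: chromatographic peak shapes, adduct/isotope multiplicity,
retention-time drift, correlated noise between co-eluting signals,
intensity-dependent CV. Passing tests therefore demonstrate the logic and
calibration of the workflow under its own statistical assumptions, not
performance on raw vendor data.

**Problem sizes.** The test suite and the acceptance script run the curve
at 70 cell + 1000 background + 150 media signals × 43 injections and the
experiment at 200 + 300 + 60 signals × 79 injections — large enough for
stable rates, small enough that the whole suite runs in well under a
minute; the Monte-Carlo calibrations use 2000 replicates.

## 7. Known limitations

* The blank rule's `any_condition` default is the permissive reading of an
  ambiguous criterion; users wanting the strict reading set
  `blank_rule: all_conditions`.
* The shared-signal Euclidean distance in k-NN imputation can rank
  neighbours differently from a missing-fraction-rescaled distance when
  missingness is heavy; QA order (presence filters first) keeps that regime
  out of scope.
* The SVR drift model is per-signal and unpenalized across signals; with
  < 5 QCs it refuses to run, and the revert guard makes it at worst a
  no-op per signal.
* Polarities are independent matrices end to end; merging ESI+/ESI−
  features is out of scope, as is adduct grouping and any annotation.
* PCA "explained variance of the first component" is PC1 alone, computed
  on the log₁₀ range-scaled matrix with no further column standardization.
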