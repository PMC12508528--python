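# Methods

## Scope and data model

`sig2screen` implements two analysis arcs around a two-gene chemokine
signature (CXCL1/CXCL2) of MDSC infiltration: compound screening
(counts → normalization → batch correction → ranking) and single-cell /
outcome analysis (QC → classification → scoring → association and survival
statistics). All inputs are produced by the `simulate` module with ground
truth returned alongside the data, so every downstream claim in the test
suite is checked against known truth rather than reconstructed labels.

Screen data live in a well×probe count table with well metadata (plate,
compound, DMSO flag) and a probe panel (fixed-length sequences, gene
symbols, stable-gene flags). Single-cell data live in `AnnData` with raw
counts in `X` and log-normalized expression in `layers["lognorm"]`.

## Screen quantification

Reads are assigned to the unique probe at minimal Hamming distance within a
budget (default 3 mismatches on 30-nt probes). `N` bases never match; reads
tied between two probes at the minimal distance are discarded into a
per-well unassigned tally rather than split fractionally — splitting would
require weights the counting model does not define. Only substitutions are
considered: capture probes are short and fixed-length, so indel alignment
adds cost without benefit, and the read simulator is substitution-only to
match.

Normalization divides each well by (sum of stable-probe counts) / (across-
well median of those sums). Anchoring at the median keeps normalized values
on the count scale. A well with zero stable counts is an error naming the
well, since its size factor is undefined.

## Batch correction

Plate effects are modeled on log2(normalized value + 1) with the classical
parametric empirical-Bayes location/scale model: per-probe standardization
against the size-weighted grand mean and pooled residual variance, per-batch
per-probe location (γ̂) and scale (δ̂²) estimates, shrinkage of γ toward a
batch-level normal prior and δ² toward a moment-matched inverse-gamma prior
via the standard iterative estimates (absolute-change tolerance 1e-4, max
100 iterations), then back-transformation. Fitting (`combat_fit`) and
application (`combat_adjust`) are separate so a model can be audited (JSON
export) or applied to held-out wells.

Choices worth knowing:

* with a single batch the model is the identity — shrinkage targets equal
  the estimates and nothing is removed;
* zero-variance probes pass through uncorrected with a warning rather than
  failing the run;
* DMSO and compound wells are corrected jointly and compound identity is
  deliberately **not** a covariate: it would absorb the treatment effects
  the ranking is meant to measure;
* under a *pure uniform* shift the prior on γ concentrates, so per-probe
  sampling noise in the batch means is retained (the prior mean is removed
  exactly); this matches the reference implementations — the test suite
  cross-checks against scanpy's parametric variant at the 1e-2 level with
  correlation > 0.99999 — and the residual scales as 1/√n;
* the batch key defaults to the plate; any per-well label can be passed.

PCA diagnostics report, per principal component of the log-values, the
one-way-ANOVA R² of its scores on the batch label — a direct measure of how
much of that component is batch structure.

## Compound ranking

Per gene, the compound's wells are compared with same-plate DMSO controls:
log2FC is the mean over treated wells of (value − plate DMSO mean); the
test is a pooled-variance two-sample Student's *t* of plate-centered treated
versus plate-centered DMSO values, so plate offsets cancel and replicates
spanning plates pool cleanly. A variance floor of 1e-6 keeps *t* finite on
degenerate (zero-variance) replicates; single-replicate compounds are kept
with p = 1 (zero score contribution) so the ranked table always covers the
library.

The combined score is the mean over signature genes of
(−log₁₀ p)·(−log₂FC)·dir (dir = +1 for a down-regulation signature). It is
the simplest statistic monotone in both the volcano-plot axes; it lives in
one function (`score_compound`) so alternates (rank-sum, signed minimum)
can be swapped without touching the pipeline. Ranking sorts by score
descending with deterministic tie-breaks (smaller mean p, then compound
id); no multiple-testing correction enters the ranking (a BH-adjusted
column is emitted for reporting only).

## Single-cell analysis

QC keeps cells with ≥ 200 detected genes and ≤ 30% mitochondrial counts
(prefix rule `MT-`/`mt-`, configurable); the filter is idempotent and
returns a per-criterion report. Log-normalization is
ln(1 + 10⁴·count/total).

The module score bins all genes into 24 equal-size bins by mean expression
(rank-based, deterministic under ties) and samples 100 control genes per
signature gene from its bin with a fixed seed; the score is the per-cell
signature mean minus the pooled-control mean. On unstructured data the
score is centered at zero by construction.

Stratification splits at the median (> median → high; ties go low) or at a
supplied threshold. For the two-gene signature, patient grouping uses the
mean log-normalized expression of CXCL1 and CXCL2 in the patient's tumor
cells (the module score is reserved for larger gene sets). Composition is
tested by Pearson χ² without continuity correction (composition tables
typically have df > 1); group comparisons use Mann–Whitney with the exact
null for tie-free groups of ≤ 8 and the tie-corrected normal approximation
otherwise; correlations are Pearson or Spearman via scipy. Spatial
coexpression labels a spot "both" iff both transcripts have nonzero counts.

## MDSC classifier

The reference cohort is log-normalized, per-gene standardized (SD floored
at 1e-8) and decomposed by full-SVD PCA (default 30 components). For each
class, components whose scores separate the class from the rest
(two-sided Wilcoxon rank-sum, BH-adjusted p < 0.05) are selected; a
one-vs-rest logistic classifier is fit on them. The linear probabilistic
family was chosen over a kernel machine for determinism and transparency;
the model object isolates the classifier so a kernel variant can be slotted
in. Query cells are aligned by gene symbol, centered/scaled with the
*reference* parameters (genes missing from the query contribute 0 after
centering, i.e. the reference mean) and multiplied by the frozen loadings —
the space is never re-fit on the query, and projecting the reference
reproduces the training scores to 1e-8. A cell is labeled with its
argmax-probability class only when that probability reaches 0.55; otherwise
it is `unassigned`.

## Outcome statistics

* **z-scores**: per-gene center and scale (sample SD) before averaging over
  signature genes, so genes on different scales contribute equally;
  zero-variance genes are dropped with a warning.
* **ROC/AUC**: the AUC is computed from midranks, making the identity
  AUC = U/(n₁n₂) exact under ties; the curve comes from scikit-learn.
* **Kaplan–Meier** uses lifelines' product-limit estimator; subjects
  censored at an event time count as at risk for that time.
* **Log-rank** is the unweighted Mantel–Cox statistic with the standard
  hypergeometric variance under ties, implemented in-package (it is called
  thousands of times by the cutoff scan and calibration checks) and
  cross-checked in the tests against both lifelines and a term-by-term
  brute-force oracle.
* **Best cutoff** scans every unique score in the interquartile window
  (25th–75th percentile, the common auto-cutoff convention) and returns the
  log-rank-minimizing split. The minimized p is always flagged as optimized;
  an optional permutation-adjusted p (fraction of score permutations whose
  minimized p is at least as small, default 200 permutations when enabled)
  is the honest replacement.
* **H-score** = Σ intensity(0–3) × percent, range 0–300; percentages must
  sum to 100 ± 0.1. **Tumor volume** = width²×length/2 (mm³); width and
  length are swapped with a warning if given in the wrong order.

## Synthetic-data generators

All generators are deterministic given their seed.

* `gen_screen`: 384-well plates, 16 DMSO wells per plate, one probe per
  gene (2 signature + 33 stable + filler to 50 probes), negative-binomial
  (gamma-Poisson) counts with dispersion 0.05 around lognormal per-probe
  baselines (median ≈ 300 counts). Each plate draws per-probe additive
  log2-mean shifts N(0, 0.5) and a dispersion multiplier exp(N(0, 0.2)) —
  exactly the location/scale structure the EB correction targets. Hit
  compounds multiply signature-probe means by 2^log2FC (default −1.5);
  stable probes never carry compound effects. Replicates (default 3) are
  assigned in blocks so a compound's replicates land on different plates.
* `gen_scrna`: four cell-type programs (tumor, T, MDSC, other-myeloid)
  share a lognormal baseline over 1,500 genes with 40-gene marker blocks at
  +3 log2 units; tumor cells express CXCL1/CXCL2 scaled by a latent
  per-patient level u ~ N(0,1); the patient's MDSC fraction is
  logistic(logit(0.12) + slope·u) (slope default 2), coupling signature
  expression to MDSC infiltration. NB dispersion 0.3. Default cohort: 20
  patients × 200 cells.
* `gen_survival`: exponential event times (baseline hazard 0.1/unit), high
  group hazard multiplied by the hazard ratio; independent exponential
  censoring calibrated to the requested censor fraction; biomarker scores
  drawn around group centers ±gap/2 so cutoff scans have a recoverable
  split at 0.
* `gen_response`: P(response) = logistic(−slope·score) — high signature
  predicts non-response, the direction in which high chemokine expression
  predicts checkpoint-blockade failure.
* `gen_reads` emits exactly the tabulated number of reads per well/probe
  with independent per-base substitution errors; conservation (Σ counts
  reads, no probe gaining foreign reads at rate 0) is tested.

What the generators deliberately do **not** emulate: doublets and ambient
RNA, UMI duplication, dropout beyond NB sampling, batch structure between
the reference and query cohorts, non-proportional hazards, and dose–response
relationships. Passing tests therefore demonstrate correctness of the
estimators and the recoverability of the simulated effects — not robustness
to every artifact of real plates or real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run the full-scale screen recovery
(2,000 compounds × 3 replicates, ≈ 6,200 wells × 50 probes), classifier
evaluation on 1,500-cell cohorts, and 1,000-replicate log-rank calibration;
together they complete in well under five minutes on one CPU, so no check
is subsampled below its stated condition. Fixed tolerances: EB iteration
1e-4; pooled-variance floor 1e-6; standardization SD floor 1e-8;
probe-variance threshold for the constant-probe pass-through 1e-12.

## Known limitations

* The combined ranking score is a reasonable monotone composite, not a
  calibrated statistic; ranks, not score magnitudes, are the deliverable.
* The EB correction assumes roughly normal log-scale values; heavily
  zero-inflated probes violate this (the stable-gene normalization and
  pseudocount mitigate but do not remove it).
* The classifier assumes the query shares the reference's expression space;
  no cross-cohort alignment is attempted, and strong batch differences
  between cohorts would degrade the projection silently except for the
  `unassigned` fraction rising.
* `best_cutoff`'s nominal p is intentionally reported as optimized;
  only the permutation p should be quoted.
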