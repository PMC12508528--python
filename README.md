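# sig2screen

Gene-signature-based drug-screen scoring and chemokine-signature outcome
analysis for immuno-oncology transcriptomics.

Tumors recruit myeloid-derived suppressor cells (MDSCs) partly through the
chemokines CXCL1 and CXCL2, building an immunosuppressive microenvironment
that blunts checkpoint-blockade therapy. A two-gene CXCL1/CXCL2 signature of
MDSC infiltration can therefore serve two purposes at once: as a screening
readout for compounds that would reverse MDSC recruitment, and as a
biomarker of immunotherapy response and survival. `sig2screen` implements
both analysis arcs as a tested, reusable Python library, with synthetic-data
generators (known ground truth) standing in for the original screening
plates and patient cohorts.

## What it computes

**Screen arc** — from plate-based sequencing screens to ranked compounds:

* probe-level read counting by minimal Hamming distance (up to a mismatch
  budget; ambiguous ties discarded), `screen.count_reads`;
* per-well normalization to a stable (housekeeping-like) probe set,
  `screen.normalize_stable`;
* plate batch diagnosis by PCA (per-PC batch R²) and removal by a
  parametric empirical-Bayes location/scale model — per-batch per-probe
  effects γ, δ² shrunk toward normal / inverse-gamma priors —
  `batch.pca_batch_diag`, `batch.combat_fit`, `batch.combat_adjust`;
* compound ranking against same-plate DMSO controls: per gene
  log2FC and pooled Student's *t*, combined per compound as
  mean over signature genes of (−log₁₀ p)·(−log₂FC)·dir,
  `ranking.rank_compounds`.

**Cell/outcome arc** — from single cells to biomarker statistics:

* QC (detected genes ≥ 200, mitochondrial fraction ≤ 30%), library-size
  log-normalization, and binned-control module scores
  (signature mean minus expression-matched control mean), `sc`;
* a reference-projection MDSC classifier: PCA space frozen on an annotated
  reference, informative PCs per class by BH-adjusted Wilcoxon, one-vs-rest
  logistic probabilities with an `unassigned` rejection class, `classify`;
* high/low stratification, cell-type composition χ², Mann–Whitney
  comparisons, Pearson/Spearman correlations, spatial spot coexpression,
  `sc`;
* outcomes: per-sample signature z-scores, ROC/AUC (equal to the
  Mann–Whitney U/(n₁n₂) identity), Kaplan–Meier curves, Mantel–Cox
  log-rank, an optimized-cutoff scan with a permutation-adjusted p, the
  IHC H-score and the caliper tumor-volume formula, `outcomes`.

Module `simulate` generates every input with ground truth: negative-binomial
screen counts with per-plate location/scale batch effects and spiked
signature-down-regulating hits; patient scRNA cohorts whose per-patient MDSC
fraction is logistically coupled to tumor-cell CXCL1/CXCL2; survival tables
with a configurable hazard ratio; response labels with logistic
score-response coupling.

## Worked example

```bash
python examples/01_screen_ranking.py
```

simulates a 500-compound screen with 5 spiked hits (log2FC −1.5, 3
replicates, plate batch effects on) and prints:

```
compound_id     score  log2fc_CXCL1  log2fc_CXCL2  rank  true_hit
   CPD00005 19.399313     -1.669840     -1.736433     1      True
   CPD00409 16.807714     -1.657740     -1.483965     2      True
   CPD00364 16.572490     -1.534982     -1.639351     3      True
   CPD00237 14.557292     -1.346217     -1.588613     4      True
   CPD00281 13.565703     -1.548954     -1.435645     5      True
   CPD00464  1.548550     -0.366911     -0.707672     6     False
   ...
5 of 5 spiked hits in the top 10.
```

All five spiked compounds rank first, their estimated log2 fold changes
recover the simulated −1.5 within sampling error, and non-hit scores sit
an order of magnitude lower. The other examples
(`02_batch_correction.py` … `05_outcomes.py`) walk through batch
diagnostics, MDSC classification, signature-association tests and the
outcome statistics the same way, each printing what the numbers mean.

A thin CLI wraps the two orchestrated arcs:

```bash
sig2screen run --arc screen --seed 1 --out screen_run
sig2screen run --arc cell --seed 1 --out cell_run
```

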