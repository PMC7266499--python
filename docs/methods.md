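# Methods

This note documents the statistical procedures, the synthetic-study
generator, the numerical choices, and the known limitations of `csfpanel`.

## Biochemical classification

The primary rule labels a sample AD iff t-tau > 400 ng/l AND
(Aβ1–42 < 550 ng/l OR Aβ1–42/Aβ1–40 < 0.065). All inequalities are strict
exactly as the cutoffs are worded ("above", "below"); a value sitting on a
cutoff classifies as non-AD. This boundary behavior is a documented choice,
not an inferred intent. A missing Aβ1–40 disables only the ratio branch
(cohorts without Aβ1–40 measurements are still classifiable on the Aβ1–42
criterion). Samples missing t-tau or Aβ1–42 are excluded, unless
`control_override` marks them as known non-AD controls enrolled without
clinical chemistry. Units are fixed to ng/l; no unit inference is
attempted. The Hulstaert index Aβ1–42/(240 + 1.18·t-tau) classifies AD
strictly below 1.

## QC conventions

* Standard deviations use the n−1 (sample) convention throughout.
* Z-scores are computed per protein within a sample stratum (cohort or
  global) over present values; a protein with fewer than two present values
  or zero variance in a stratum becomes all-missing there rather than 0 —
  a fake certainty of 0 would contaminate clustering and classifiers.
* CVs are computed on linear intensities (CV is defined on the original
  scale). Intra-plate candidates are all 3-subsets of replicates within a
  plate; inter-plate candidates take one replicate from each of three
  distinct plates (the one-per-plate reading of the replicate design).
  A candidate's CV is sample sd / mean over its present values; candidates
  with fewer than two present values are excluded, candidates with exactly
  two are retained. The per-protein CV is the median over candidates.
  Biological CVs are computed within each cohort and the median across
  cohorts reported.

## Differential abundance and permutation FDR

Per protein, present values only (pairwise deletion). The test statistic
is the pooled-variance Student t (two-sided, unpaired); Welch was not used
because the SAM shrinkage below is defined on the classical pooled
denominator. The SAM statistic is

    d = (mean₁ − mean₂) / (se_pooled + s₀),   s₀ = 0.001

on log10 intensities (the scale on which s₀ is assumed to apply). Proteins
with fewer than two present values in either group, or zero variance in
both groups, are untestable: p and q are missing and they are excluded
from the FDR ranking (with s₀ > 0 a zero-variance d would be finite but
meaningless).

q-values use a SAM-style permutation estimator. Group labels are permuted
B times (default 250; when the number of distinct assignments C(n, n₁) ≤ B
the assignment set is enumerated exhaustively instead). Permuted |d|
values are pooled over proteins; for each observed threshold |dᵢ| of rank
rᵢ (1 = largest |d|),

    q_raw(i) = (pooled #{|d_perm| ≥ |dᵢ|} / B) / rᵢ ,  clipped to [0, 1]

and monotonized BH-style, q(i) = min over ranks ≥ rᵢ of q_raw, so q never
decreases as |d| decreases. The estimator is a documented reconstruction:
the upstream tooling does not print its exact q-value algorithm or
permutation count. B = 250 keeps small-cohort problems near-exhaustive and
tests fast; every randomized stage takes an explicit seed.

## Cross-cohort signature and contingency statistics

A protein enters the signature when it is significant (p or q below alpha,
mode selectable) in *every* cohort and its fold-change direction agrees
across all cohorts; a delta of exactly 0 is inconsistent with any sign.
Fold-change concordance is the Pearson r of log10 fold changes over
co-significant, direction-consistent proteins.

Fisher exact tests are two-sided by the "tables at most as probable as
observed" rule; the reported odds ratio is the sample OR (a·d)/(b·c), with
a Haldane 0.5 correction (flagged) when a cell is zero. Confidence
intervals (the Baptista–Pike companion of the published analysis) are out
of scope; only the point OR and p are consumed downstream. External-study
overlap matches by protein ID first, then by gene name, mirroring how
cross-study tables index their proteins.

Heat-map clustering is agglomerative with average linkage (the upstream
default is unstated; average linkage is the package's choice and is
configurable in principle via scipy): Euclidean distance for proteins,
1 − Pearson r for sample groups, deterministic leaf order with ties broken
by input order.

## Covariate association

Correlation p-values are analytic (t = r·√((n−2)/(1−r²))) rather than
permutation-based, with Benjamini–Hochberg q-values within cohort —
the BH step-up is also used elsewhere in the pipeline, so the same
adjustment is used here. "Correlates across cohorts" means p < 0.05 in
every cohort with a consistent sign. The MMSE stratification uses
low = score < cutoff (strict). The global correlation map computes
pairwise-complete Pearson r with a minimum overlap of 10 samples per pair
(stability of r under missingness) and clusters the correlation pattern
(1 − r, average linkage) into 8 groups by default. Covariate-adjusted
regression is OLS with listwise deletion; continuous covariates'
estimates are additionally reported multiplied by their interquartile
range so they are comparable to binary contrasts.

## 1D enrichment

All n dataset proteins are ranked ascending with average ranks on ties;
a term's score is s = 2·(meanRank_in − (n+1)/2)/n, so |s| ≤ (n − n_in)/n
and positive s means enrichment at high values. Significance is the
two-sided Mann–Whitney U test (tie-corrected normal approximation; exact
enumeration when n ≤ 25 without ties), BH-adjusted across tested terms.
Terms with fewer than 10 or more than 100 dataset members are excluded.
The cross-cohort consistency cutoff defaults to p < 0.05; a stricter 0.5%
preset is available because the two conventions coexist in practice.

## Classification

Feature selection fits an axis-aligned Gini decision tree whose maximum
depth grows until training accuracy 1.0; the features used, in traversal
order (root, then level by level ordered by impurity decrease), are the
candidate panel. "Random initial states" are realized as randomized split
tie-breaking (the learner's random state) plus sample-order shuffling;
rank-1 is the root feature, ranks 2–3 the second level. Evaluation uses
*stratified* shuffled k-fold (k = 6): stratification is the package's
resolution of an ambiguity between a plain shuffled splitter and a
stratified one in the source material, and is switchable
(`MLConfig.stratified`). The per-fold learner is scikit-learn's
`GradientBoostingClassifier` (logistic loss) with early stopping after 10
rounds without improvement on a held-out 20% slice of the training fold;
an XGBoost backend with the same early-stopping contract is pluggable
(`backend="xgboost"`). Default hyperparameters otherwise; no tuning. The
pooled test folds (each sample predicted exactly once) give the combined
confusion matrix at a probability cutoff of 0.5 (the cutoff is a package
choice). AUC follows the Mann–Whitney identity with 0.5 credit for ties.

## Synthetic-study generator

The generator defines the study conditions the tests and the acceptance
script measure against:

* **Design**: 3 cohorts with group sizes 29/31 (Sweden-like, no Aβ1–40),
  26/12/16 (Magdeburg/Kiel-like; the 16 Kiel-like controls are young —
  age 32 ± 12 vs 70 ± 8 elsewhere — lack clinical chemistry and carry
  `control_override`), and 33/26/24 (Berlin-like, with MMSE). 197 samples;
  88 AD, 109 non-AD.
* **Abundance**: per-protein median log10 intensity ~ Normal(6, 1.2),
  giving ≈ 6 orders of magnitude of dynamic range. Signature proteins draw
  from Normal(6.5, 0.8) truncated at 5.0 — biomarker candidates must be
  quantifiable, and published panels consist of well-quantified proteins.
* **Effects**: additive in log10 space (fold change 1.3 ⇔ 0.1139 log10),
  identical across cohorts (the shared-effect premise that the observed
  cross-cohort fold-change correlations motivate); cohorts differ only by
  small global offsets (±0.05 log10) and demographics. The 40-protein
  signature has 35 up / 5 down effects on a narrow ladder
  (0.095…log10(1.3)…0.16) whose median is exactly log10(1.3) — narrow so
  that the median is ≈ 1.3-fold *also after* significance selection, which
  is how the anchor value is observed — plus one dominant tau-like protein
  at 0.50 (~3.2-fold) with a pinned base abundance of 6.0 log10.
* **Missingness**: abundance-driven (left-censoring-like), P(missing) =
  logistic((m − log10 I)/s) with m = 4.756 (the 15th percentile of the
  abundance distribution) and s = 0.5, giving ≈ 15–20% overall
  missingness concentrated in low-abundance proteins. The logistic form is
  a modeling choice; no quantitative missingness model is published.
* **Correlation structure**: per-sample latent factors with loadings on a
  neuronal block (part of the up-signature plus bystanders, loading 0.06)
  and a blood-contamination block (40 non-signature proteins, loading
  0.15). Residual noise sd 0.1 log10.
* **Clinical coupling**: simulated ELISA t-tau is proportional to the
  tau-like protein's linear intensity plus Gaussian noise sized for a
  target Pearson r of 0.8; Aβ1–42 ~ N(450, 100) in AD vs N(800, 150) in
  controls; Aβ1–40 ~ N(9000, 1500); MMSE ~ N(22.7, 4.5) in AD vs
  N(27.7, 1.9) in controls (Berlin-like cohort only), rounded and clipped
  to [0, 30]. Because the biochemical rule *defines* the study groups,
  clinical values are redrawn (bounded rejection sampling) until a sample
  satisfies its group's rule — emulating enrollment, under which group
  sizes count rule-satisfying patients. With all noise at zero the rule
  reproduces the planted status exactly.

What the generator does **not** emulate: peptide-level structure,
retention-time or spectral effects, batch/plate effects in the main study
matrices, non-Gaussian heavy-tailed biological variation, realistic
protein identities beyond the designated tau-like index, and
between-protein correlation beyond the two latent blocks. Passing recovery
tests therefore demonstrates the pipeline's correctness under its own
assumptions, not performance on real CSF data; the published per-cohort
counts (e.g. 540/453/168 significant proteins) depend on the deposited
data and are out of scope.

## Problem sizes and runtimes

Tests and the acceptance script run the full pipeline at the study's
native scale (1,500 proteins × 197 samples, 250 permutations per cohort),
which completes in seconds thanks to vectorized permutation statistics.
Stability resampling uses 200 repeats (the procedure is defined up to
10,000; frequencies at 200 repeats have binomial SE ≤ 0.035, ample for the
≥ 95% root-frequency check). The null FDR calibration uses 1,000 proteins
at 30 vs 30. Exhaustive oracle comparisons in the test suite cover all
2×2 tables with totals ≤ 25 plus random larger tables up to 50, and all
C(6,3) = 20 label assignments for the permutation oracle.

## Known limitations

* The permutation q-value estimator is a reconstruction (see above); other
  implementations may differ in pooling and monotonization details.
* Fisher p-values follow the probability-ordering two-sided rule; software
  using central or mid-p conventions will differ on asymmetric tables.
* The classifier stage assumes within-cohort Z-scores as input and imputes
  missing Z-scores as 0 for backends without native missing-value support.
* Boundary behavior of the clinical cutoffs (values exactly at a cutoff)
  is strict by declaration; data re-analyses with non-strict conventions
  will differ on knife-edge samples.
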