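# Methods

## The modeling problem

V_ss (volume of distribution at steady state, L/kg) measures how extensively
a drug leaves plasma and binds in tissue; f_u is the fraction of drug in
plasma not bound to protein.  Both are driven by overlapping physicochemical
axes — lipophilicity pushes drugs into tissue (high V_ss) and onto plasma
proteins (low f_u), while solubility/charge does the opposite — so the
package models the two endpoints simultaneously: a two-response linear PLS
regression of (log₁₀ V_ss, f_u) and, for a coarser but more robust readout,
a classification of compounds into V_ss classes (and V_ss × f_u classes)
with a balanced forest of recursive-partitioning trees.

V_ss spans orders of magnitude and fold error is the pharmacologically
meaningful error measure, so it is always modeled as log₁₀ V_ss.  f_u is
modeled on its raw (0, 1] scale; a logit/log transform is available as a
configuration switch for sensitivity analysis but is not the default.

## Data model and class schemes

A `CompoundSet` aligns compound records (id, V_ss > 0, f_u ∈ (0, 1] or
missing, optional RDKit molecule) with an n×p descriptor matrix.  I/O covers
SDF with data tags (tag names are configuration, not hard-coded) and
CSV/TSV descriptor tables joined by id.

Class scheme: class 1 is V_ss ≤ 0.3 L/kg (roughly the extracellular fluid
volume), class 2 is 0.3–1 L/kg, class 3 is above 1 L/kg.  Two conventions for
exactly 1 L/kg circulate (strictly above vs at-or-above); `ClassScheme`
carries an explicit `vss_upper_inclusive` flag because the choice moves
compounds sitting exactly at the boundary between classes 2 and 3.  The
six-class scheme suffixes "a" (f_u > 0.7) or "b" (f_u ≤ 0.7); a value exactly
at the cutoff goes to the low ("b") side.

Missing f_u (about 16% of compounds in the motivating application) is
mean-imputed before classification, with the imputed ids retained so the
cluster-stratified splitter can distribute them approximately evenly across
training and test sets.  Rows with imputed f_u feed only the classification
stage; the PLS regression uses measured f_u rows exclusively, since imputing
a response would leak the training mean into the regression target.

Splitting clusters compounds first (Tanimoto distance on hashed path
fingerprints when structures exist, else Euclidean distance on standardized
descriptors; average-linkage hierarchy with a configurable cut) and samples
within each cluster, so the test set stays inside the training chemical
space.  The contract tested is that every cluster of size ≥ 2 contributes to
both sets and the split is deterministic under its seed.

## Descriptor conditioning

Duplicate columns (the same descriptor from two software packages) are
removed by exact match within 1e−12, keeping the earlier column.  Columns
with |sample skewness| > 2 (a configurable threshold; no principled universal
value exists) are log₁₀(x + c)-transformed with c = 0 for positive columns
and c = 1 − min(x) otherwise, then all columns are autoscaled (mean 0,
unit variance; ddof = 1).  Constant columns are a named error.  Boundary
rule sets (`MW < 940`, ranges, etc.) ship as three named built-in
configurations and are applied declaratively; a NaN descriptor value counts
as violating any rule that references it, and exclusions are logged with the
violated rules.

## NIPALS latent models

PCA and PLS components are extracted one at a time by NIPALS iteration with
deflation.  Numerical choices: convergence is declared when the relative
change of the score vector falls below 1e−10; the iteration cap is 5000
because power iteration stalls geometrically when leading eigenvalues are
nearly tied (gap ratio 0.99 needs ≈2300 iterations), and a component is still
accepted at the cap if the relative change is below 1e−7 — beyond that the
component is declared non-convergent and an error raised (this happens, by
design, for some permuted-response fits during Y-randomization, which are
then skipped and logged).  Orthogonality of scores and orthonormality of PCA
loadings hold to 1e−8 under these settings, and the standard oracle
identities are tested: PCA component 1 equals the dominant right singular
vector; PLS with A = rank(X) equals ordinary least squares; PLS1 with one
component equals the w ∝ Xᵀy formula.

Diagnostics: Hotelling T² uses per-component score variances with the
A(n−1)(n+1)/(n(n−A)) · F(A, n−A) critical value at α = 0.05.  DModX is the
row residual SD scaled by the pooled model residual SD (degrees of freedom
(n−A−1)(p−A)); in-plane observations are clamped to exactly 0.  Q²X uses
Wold-style element-wise deletion in 7 diagonal groups with a
missing-value-aware NIPALS refit per group.  Q² for regression leaves out
1/7 of the compounds per fold (deterministic under seed), with
Q² = 1 − PRESS/SS on the scaled responses, per response and pooled.

VIP is the standard projection importance weighted by per-component
explained Y-variance, normalized so mean(VIP²) = 1.  Variable reduction
iteratively drops variables with VIP < 0.8 (configurable), refits, and stops
when cross-validated Q² stops improving — an automated analogue of manual
weight-plot-driven pruning, which is not reproducible mechanically.  The
number of components is grown while pooled Q² improves by more than 0.01,
capped at 10.

The weight-plot export gives each variable's rotated weights (w\*c) on
components 1–2 and its signed orthogonal projection onto each response
direction in that plane; a positive projection reads as a positive influence
on that response.

## Balanced recursive-partitioning forest

Each of the (default) 10 trees is grown on a balanced bootstrap: exactly k
draws with replacement from every class, k = size of the smallest class.
At each node, mtry = ⌊√p⌋ candidate descriptors are drawn without
replacement; the split minimizing weighted Gini impurity over all midpoint
thresholds is chosen, with ties broken by lowest descriptor index then
lowest threshold (determinism).  Nodes stop at purity or below 5 in-bag
members (configurable; no pruning).  Every realized split records the
eligible candidates and the winner, giving the percent-selection-frequency
importance (100 × selections / chances; descriptors never eligible are
"not assessed").  Prediction is an unweighted majority vote; class
probabilities (for the Hand–Till AUC) are mean leaf class frequencies.
Out-of-bag statistics aggregate only trees whose bootstrap excluded the
compound; compounds in-bag everywhere are flagged and excluded.

With only ~10 trees each compound has ≈3–4 OOB trees, so OOB probability
estimates are coarse; OOB AUC at the synthetic generator's default
conditions is accordingly 0.82–0.86 across seeds and rises to ≈0.89 at 50
trees.  The forest default stays at 10 (small forests are the intended
operating point); power assertions in the acceptance suite use the
strongly-separated 3-class fixture, where OOB AUC ≥ 0.95.

## Applicability domain

Hashed linear-path (Daylight-style) fingerprints, length configurable
(32 bits mirrors the original small fingerprint; 1024 is the practical
default — note all published threshold values depend on the exact
fingerprint and are not transferable).  From all pairwise training
Euclidean distances (= √Hamming on bit vectors): take the overall mean,
restrict to distances *strictly* below it (ties at the mean excluded),
and compute ⟨d⟩ and the sample (n−1) SD σ of the restricted set; the domain
threshold is AD = ⟨d⟩ + Z·σ with Z = 0.7 by default.  A query is in-domain
iff its nearest-training-neighbor distance (k = 1; k configurable) is ≤ AD.
Degenerate case: if every pairwise distance is equal, AD falls back to the
overall mean with a warning.  The in-domain set is nested and coverage
monotone as Z grows; the coverage/accuracy sweep quantifies the
accuracy-coverage trade-off.

## Validation statistics

* Q_e² — squared Pearson correlation of predicted vs observed (the
  regression-line R²); deliberately invariant to affine miscalibration of
  the predictions, unlike 1 − PRESS/SS.
* Fold errors — FE = max(pred/obs, obs/pred); MFE defaults to the geometric
  form 10^mean|log₁₀(pred/obs)| (standard for multiplicative PK error;
  the arithmetic mean is available behind a flag); band percentages report
  the share within 2-, 3- and 5-fold.
* Confusion matrix (rows = true), one-vs-rest sensitivity and specificity.
* Hand–Till multiclass AUC: M = 2/(K(K−1)) Σ_{i<j} Â(i,j) with Â the
  symmetrized one-vs-one ranking probability (ties 0.5), computed on the
  two classes' compounds only; reduces to binary AUC at K = 2 and is
  invariant under monotone transforms of the scores.
* Y-randomization: refit on row-permuted responses; regress R²Y and Q² on
  |corr(Y_perm, Y)| including the unpermuted model at correlation 1; pass
  iff the intercepts are below 0.3 (R²Y) and 0.05 (Q²).  Builder failures
  on a permutation are logged and skipped.
* External-validation outlier exclusion is an explicit, logged id list
  supplied by the user — never automatic.

## Synthetic generator

Two latent axes: lipophilicity L and solubility S, standard normal with
corr(L, S) = −0.5 (opposed but not collinear).  Descriptors load sparsely on
one axis each (35% on L, 35% on S, the rest pure noise; magnitudes
U(0.6, 1.4)) plus N(0, 0.3) noise.  Responses:
log₁₀ V_ss = −0.04 + 0.4 L − 0.4 S + ε and logit(f_u) = −0.7 − 0.8 L + 0.8 S + ε,
ε ~ N(0, 0.3).  The intercept/coefficient defaults were chosen analytically
so the three V_ss classes land near 26/26/48% (the motivating imbalance) and
high-f_u compounds are a small minority; V_ss is clipped to the observed
0.035–60 L/kg range; f_u is masked missing at rate 0.157 by default.
n = 400 compounds and p = 30 descriptors are the default problem size —
large enough for stable latent recovery, small enough that the full test
suite runs in seconds.

The generator reproduces the *statistical* structure the models assume —
latent low-rank descriptors, opposite-signed responses, class imbalance,
missing responses — and none of the distributional quirks of real
descriptor packages (discreteness, heavy tails, block correlations beyond
rank 2).  Passing parameter-recovery tests therefore demonstrates
correctness of the estimation machinery, not predictive performance on real
chemistry.  Toy structure generation (alkane and substituted-benzene
families) exists solely to exercise fingerprints and the applicability
domain; a separate, explicitly synthetic stand-in table mirrors published
marginal class totals (642 compounds, 541 with f_u, 9 compounds at exactly
1.0 L/kg) to exercise the counting/imputation bookkeeping at realistic
scale.

## Known limitations

* The PLS handles missing f_u by row exclusion, not EM-style NIPALS with
  missing elements.
* The forest mimics the *construction* of the original balanced RP models;
  proprietary tree heuristics are not reproduced bit-for-bit, and published
  AUC/sensitivity values depend on commercial descriptors unavailable here.
* The AD threshold is fingerprint-specific; values computed with one
  fingerprint length/type do not transfer to another.
* Hierarchical-clustering-based splitting is O(n²) in memory and intended
  for datasets up to a few thousand compounds.
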