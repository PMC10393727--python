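# Methods

This note records the statistical procedures implemented in `attspace`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Survey ingestion

Surveys are RFC-4180 CSV files with a header row, one row per respondent,
a group-label column and optional nonnegative weights; item metadata
(kind, level codes or bounds, reverse coding) lives in a YAML sidecar.
Missing answers are empty cells or a sentinel string — never a numeric
code, so a stray "9" on a 5-point item is a validation error naming the
cell, not a silent missing value.

* **Missing-data filter.** Respondents with strictly more than
  `max_missing_frac` (default 0.10) of their items missing are removed;
  a respondent at exactly the threshold is retained. The filter is
  idempotent and order-preserving.
* **Imputation.** PCA needs complete data, so residual gaps are filled
  with the per-item median — rounded to the nearest admissible code for
  ordinal items — and flagged. Median imputation is deliberately simple;
  it biases variances slightly downward but, after the 10% filter, at
  most a few cells per respondent are affected. Multiple imputation is
  out of scope. The Gower route (below) needs no imputation at all.
* **Encoding.** Reverse-coded items are reflected on their own scale
  (code → min + max − code); each column is then z-scored with the n−1
  denominator. Constant items are an error: they carry no information
  and would produce a degenerate axis.

## 2. Building the space

**Dimensionality.** A factor analysis on the mixed-type correlation
matrix decides how many axes carry signal: d = number of eigenvalues
strictly greater than 1 (falling back to 1, with a warning, if none).
The polychoric/polyserial matrix is used *only* here; the coordinates
come from a PCA of the z-scored codes, which is appropriate because the
supported item types are numeric or ordinal.

**Polychoric / polyserial estimation** is two-step maximum likelihood:
thresholds are fixed at inverse-normal transforms of the marginal
cumulative proportions, then the latent correlation ρ is found by bounded
scalar minimization (|ρ| ≤ 0.999, absolute tolerance 1e-6) of the
negative log-likelihood — bivariate-normal rectangle probabilities over
the contingency table for two ordinal items, mixed normal-CDF terms for
an ordinal–continuous pair. Pairs are estimated after pairwise deletion
and require at least 20 complete observations and two observed levels
per margin. The assembled matrix is smoothed to near positive
semi-definiteness (eigenvalue floor 1e-8, diagonal restored) and the
repair is flagged.

**Rotation.** Varimax maximizes the standard criterion with Kaiser row
normalization (iterative SVD algorithm); promax follows the classic
recipe — varimax, then an oblique least-squares transform toward the
element-wise power-4 target, columns normalized so the implied factors
have unit variance — returning pattern loadings and the interfactor
correlation Φ = (UᵀU)⁻¹. The promax power is 4 by convention and
configurable. `rotation="auto"` fits promax and keeps it iff
max |Φᵢⱼ| ≥ 0.3, otherwise reverts to varimax.

**Scores** are unit-variance component scores: orthogonal rotations act
as F → FR, the oblique case as F → F(Tᵀ)⁻¹, which gives correlated
scores whose correlation matrix equals Φ. This matches the common
standardized-score convention for rotated principal components; because
the metrics layer min–max scales every axis anyway, metrics other than
the reported variance shares are insensitive to this choice.

**Sign convention.** Each axis is flipped so its largest-|loading| item
loads positively (ties broken toward the lowest item index), fixing
PCA's sign indeterminacy so reruns and row permutations reproduce
identical scores.

**Variance explained.** Per-axis shares are SS of structure loadings
divided by p (structure = pattern·Φ under promax, where obliquely rotated
variances are non-additive); the unrotated cumulative proportion for the
retained d is reported alongside, since the two attributions differ once
axes are rotated.

**Gower + PCoA route.** For tables with categorical items or retained
missing cells: Gower dissimilarity (range-normalized absolute difference
for ordinal/continuous items, simple mismatch for categoricals, pairwise
deletion of missing cells; a pair of respondents with no item in common
is an error) embedded by principal coordinates analysis. Negative
eigenvalues of the double-centred matrix trigger the Lingoes correction
(add −2λ_min to off-diagonal squared dissimilarities); variance shares
come from the corrected positive eigenvalues; eigenvalues below 1e-12 of
the largest are treated as exactly zero.

## 3. Scaled cloud and metrics

Axes are min–max scaled over the **pooled** sample — groups must remain
comparable, so no per-group scaling — and all distances are divided by
√d, the unit-hypercube diagonal, putting every distance-valued metric in
[0, 1]. An alternative normalizer (maximum observed pooled distance) is
available behind `normalize_by="observed"`; the default is preferred
because it does not depend on the two most extreme respondents.

Weights enter as community weighting: centroids and metric means are
weighted; occupancy-type quantities (convex hulls, TOP peeling, nearest
neighbours, spanning trees, entity counts) ignore weights. A run with all
weights equal is identical to an unweighted run.

Conventions for degenerate cases: a singleton group has dispersion 0 and
undefined originality; richness is undefined (flagged NaN, never an
error) when a group has ≤ d points or a degenerate hull; TOP is defined
for d = 2 only and returns 0 with a warning below 3 points; evenness
needs 3 members and is 1 by convention for an all-coincident group; MST
ties break deterministically toward the lexicographically first index
pair; entity counts use ordinal items only (continuous items are excluded
from both the key and the level-count product, with a warning).

## 4. Bootstrap inference

Each metric's uncertainty comes from B (default 1000) subsamples of
n_sub respondents drawn **without replacement** within the group (a
with-replacement flag exists). Coordinates and min–max scaling stay
fixed from the full pooled sample: resampling only changes who enters
the metric, so draws are comparable across groups, times and metrics.
Percentile 95% intervals are reported; point estimates (and the percent
changes derived from them) always come from the full sample.

Contrasts use the paired-difference p-value
p = 2·min(#(D ≤ 0)+1, #(D ≥ 0)+1)/(B+1), capped at 1, where
D_i = a_i − b_i over paired iterations; the +1 smoothing bounds p below
by 2/(B+1) and makes the test exchange-symmetric. When no n_sub is
given, contrasts default to **half the smaller group**: for
without-replacement subsampling, the finite-population-corrected
variance of a half-sample mean equals the sampling variance of the
full-sample estimator, which is what keeps this p approximately
calibrated (the suite measures a ~0.04 null rejection rate at α = 0.05).

Centroid equality between two groups ("distance" significance) is tested
from the per-draw vector difference of subsampled centroids: each axis
gets the straddle-zero paired p, combined across axes by Bonferroni.
The same logic governs the position gate of the classifier: the most
significant axis is reported with its p multiplied by d, so the "none"
verdict keeps a family-wise error near α. Beyond this, p-values are raw
— no correction across metrics or group pairs (documented non-goal).

**Classification.** Given position, extremization and dispersion
contrasts on one group pair: position not significant → `none`;
otherwise count the supporting signals (extremization significantly
increased; dispersion significantly decreased): 2 → `strong`,
1 → `moderate`, 0 → `weak`. The moderate case covers the empirically
common pattern where groups move apart and extremize while also growing
internally more heterogeneous.

## 5. Synthetic surveys

The generator emulates the statistical structure the analysis assumes:
respondents carry latent positions z drawn from group-specific
multivariate normals; item scores are λⱼᵀz + ε with independent normal
noise (default sd 0.6, i.e. item communalities ≈ 0.64 for the default
simple-structure loadings of 0.8 — typical of well-behaved attitude
scales); scores are divided by the item's reference sd (its sd under a
standard-normal latent population) and cut at fixed thresholds into
Likert codes 1..L (default L = 5, thresholds at normal quantiles k/L).
Thresholds are a property of the instrument, *not* of the population
being surveyed: a strongly polarized population therefore genuinely
saturates the scale ends rather than being re-quantiled into balanced
categories. Missingness is injected completely at random; ground-truth
latents are returned separately and never written into the survey file.

What a green test does **not** establish: the generator has no
informative missingness, no acquiescence/style factors, no
differential item functioning between groups, and item noise is
homoscedastic — real surveys violate all four, so recovery results here
bound the idealized, not the practical, behaviour.

**Preset scenarios** (n = 500 per cell by default, 12 items, 2 latent
factors) encode polarization histories as two time populations per group:

* `null` — two groups, one distribution (means 0, identity covariance).
* `weak` — means split 0.15 → 2.2 along axis 1 while covariance
  *inflates* 0.2 → 1.5·I: positions differ, groups stay diffuse.
* `strong` — identical mean history but covariance *shrinks* to 0.08·I:
  tight camps pinned at the scale ends.
* `case1_like` — means 0.5 → 1.0 with covariance 0.4 → 0.8·I:
  extremization and dispersion both rise, the classifier's `moderate`.

Two design notes, decided during construction. Means separate along one
latent axis: separating diagonally on both axes drives the pooled latent
correlation toward 1, collapses the second eigenvalue and turns the
standardized second component into amplified noise — a space no analyst
would keep at d = 2. And because a bounded 5-point instrument saturates
identically for tight and diffuse extreme groups, a *cross-scenario*
ordering of extremization point estimates at equal mean separation is
not a property of this world (the diffuse group's spread always adds to
its raw mean distance); the discriminating signal between `weak` and
`strong`, here as in the diagnosis itself, is dispersion.

## 6. Known limitations

* Component scores only (no regression/Bartlett factor scores); one
  rotation family (varimax/promax).
* Polychoric estimation is two-step, not joint ML; standard errors of ρ
  are not produced (the downstream bootstrap covers uncertainty).
* TOP peeling is restricted to d = 2.
* Subsampling inference assumes n_sub ≪ group size for its
  conservativeness argument; with n_sub close to the group size the
  draws collapse toward the full-sample value and p-values lose power
  to separate (at n_sub = n they are degenerate by construction).
* Group discovery (clustering in the space) and drivers/consequences of
  polarization are out of scope.
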