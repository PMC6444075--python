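# Methods

## Model

`copulamri` treats each patient's tumor as a bivariate sample: at every
voxel of the contrast-enhancing tumor mask, the NAWM-normalized ADC value
x and rCBV value y. By Sklar's decomposition, the joint distribution of
(X, Y) factors into the two marginals and a copula C(u, v) on the unit
square that carries all of the dependence. The analysis deliberately keeps
only the copula: the empirical copula transform replaces each channel by its
midranks scaled by 1/(n+1),

    u_k = rank(x_k)/(n+1),   v_k = rank(y_k)/(n+1),

so the marginals become (near-)uniform by construction and anything that
acts as a strictly increasing distortion of one channel — scanner gain,
sequence differences, the NAWM normalization constant itself — cancels
exactly. The transformed pairs are binned on an equal-width N × N grid
(default N = 10) over [0,1]², giving a discretized copula density p(i, j):
the identity copula (independence) gives the flat matrix p ≈ 1/N², the
comonotone copula puts all mass on the main diagonal, the countermonotone
copula on the anti-diagonal.

Nine second-order statistics summarize p (indices i, j = 1..N, marginals
p_x, p_y, means μ_x, μ_y, standard deviations σ_x, σ_y,
p_{x+y}(k) = Σ_{i+j=k} p(i,j)):

| feature | formula |
|---|---|
| energy | Σ p(i,j)² |
| contrast | Σ (i−j)² p(i,j) |
| entropy | −Σ p log₂ p (0·log 0 ≡ 0) |
| homogeneity | Σ p/(1+\|i−j\|) |
| correlation | (Σ i·j·p − μ_x μ_y)/(σ_x σ_y) |
| sum_average | Σ_{k=2}^{2N} k·p_{x+y}(k) |
| variance | Σ (i−μ_x)² p(i,j) |
| dissimilarity | Σ \|i−j\| p(i,j) |
| autocorrelation | Σ i·j·p(i,j) |

The identity autocorrelation − μ_x μ_y = correlation·σ_x σ_y is used as an
internal cross-check. Variance is defined against the row-marginal mean
(the GLCM convention) and is the one feature not invariant under transpose.

The cohort's patients × 9 table is z-scored column-wise and clustered by
agglomerative hierarchical clustering, complete linkage, Euclidean
distance. The cluster count k is chosen over k = 2..10 by majority vote of
a validity-index battery (below). Stability is assessed by leave-one-out
consensus: n repetitions, each dropping one patient and re-standardizing
and re-clustering the rest at the chosen k; M(i,j) is the co-clustering
fraction over the n−2 repetitions in which both i and j are present.
Co-membership is label-free, so no label matching across repetitions is
needed.

Downstream, subtypes are compared on per-patient quantities by the
Kruskal-Wallis rank-sum test with Benjamini-Hochberg adjustment across the
tested family, and on survival by Kaplan-Meier (median = first t with
S(t) ≤ 0.5), the k-sample log-rank test, and Cox proportional-hazards
models. Subtype enters Cox as indicator variables against the
intermediate-interdependence subtype, identified as the cluster with the
middle mean matrix-correlation; all clinical covariates are kept in the
multivariate model rather than gated by univariate screening. Two-sided
α = 0.05.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| `bins` | 10 | matrix resolution; 10 balances resolution against per-cell counts for tumors of ~10³–10⁵ voxels |
| `k_min`, `k_max` | 2, 10 | candidate cluster counts |
| `linkage` | complete | the only supported method; farthest-neighbor merging gives compact clusters |
| `entropy_base` | 2 | bits; base only rescales the feature and cannot change clustering after z-scoring |
| `homogeneity_variant` | inverse_difference | `inverse_difference_moment` (1+(i−j)² denominator) available |
| `standardize` | true | complete linkage is scale-sensitive and the features span ~3 orders of magnitude |
| `cox_tie_method` | breslow | `efron` available; synthetic survival times are continuous so ties are measure-zero |

## Numerical choices

- Pseudo-observation denominator n+1 (not n) keeps all values strictly
  inside (0,1), so the final bin needs no special casing. Ties get average
  ranks (midranks), which preserves the channel-swap/transpose symmetry;
  with midranks the exact-marginal property (every row marginal = n/N when
  N | n) can fail — documented, not an error.
- Bins are half-open [l, r) with the final bin closed; irrelevant for
  pseudo-observations, which never touch 0 or 1.
- Matrix orientation: rows = ADC bins, columns = rCBV bins, index 1 = lowest
  values.
- Voxels are scanned in fixed lexicographic array order and non-finite
  voxels inside the tumor mask are dropped with a warning (no other outlier
  handling); the rank transform is order-insensitive, so this matters only
  for bit-reproducibility of intermediate files.
- Z-scoring treats a column as constant when its SD is below 1e-10 relative
  to its mean and maps it to zero. This is load-bearing: for tie-free
  samples with N | n, sum_average and variance are constant *up to float
  rounding* (SD ~1e-15), and scaling that rounding noise to unit variance
  would inject two pure-noise dimensions into the distance.
- Cluster labels are renumbered by first appearance, so label numbering is
  independent of dendrogram internals. Merge order for exactly tied heights
  follows the deterministic order of scipy's nearest-neighbor-chain
  algorithm; runs are bit-reproducible.
- Cox models are fit by partial-likelihood maximization (statsmodels PHReg);
  a non-finite or absurdly large coefficient (|β| > 50) is reported as a
  monotone-likelihood failure naming the covariate. The pipeline's
  univariate screen excludes such covariates from the multivariate model
  with a warning; calling `cox_fit` directly keeps the hard error.
- Correlation of a degenerate matrix (σ_x σ_y = 0) is returned as 0 with a
  warning rather than NaN.

## Cluster-count vote

The battery contains 21 classical indices: silhouette, Calinski-Harabasz,
Davies-Bouldin, Dunn, C-index, McClain-Rao, point-biserial,
Ratkowsky-Lance, Ball-Hall, Hartigan, Krzanowski-Lai, TraceW, Duda-Hart,
pseudo-t², Beale, SD, S_Dbw, Scott, Marriott, Rubin and Friedman, each with
its standard decision rule (maximize, minimize, largest difference between
successive hierarchy levels, or a critical-value stopping rule; Duda-Hart
and pseudo-t² use the conventional z = 3.20 critical score). Ties in the
modal vote break toward smaller k. Indices abstain rather than guess when
undefined: the determinant-based four require non-singular scatter matrices
(computed in log-determinant form on the non-degenerate feature columns),
and the stopping rules abstain when no level satisfies their criterion. A
wide battery is the point of the design — individual indices have known
biases (McClain-Rao degenerates toward large k, Ratkowsky-Lance and
Ball-Hall toward small k), and the majority vote is what buys robustness.

## Synthetic cohorts

The generator draws each patient's voxel pairs through a Gaussian copula:
(z₁, z₂) bivariate standard normal with correlation ρ, mapped to uniforms
by Φ and to map values by inverse-CDF of the marginals (ADC ~ Normal(1.3,
0.25) truncated at 0; rCBV ~ LogNormal(log 2.5, 0.5), both in
NAWM-normalized units). The default cohort has three subgroups —
ρ = 0.05 (near-uniform copula matrix), 0.45 (intermediate), 0.90
(diagonalized) — in 35/42/23% proportions, 3,000 voxels per patient.
Survival is exponential with per-subgroup medians 400/550/400 days for the
OS-like endpoint (PFS-like medians at 0.65× those values) and independent
Uniform(0, b) censoring with b solved so the expected censored fraction is
0.2; constant hazard makes the true between-subgroup log hazard ratio
analytically known for recovery tests. Clinical covariates (age, sex,
extent of resection, MGMT, IDH, tumor volume) are drawn independently of
subgroup at glioblastoma-plausible frequencies, so subgroup is the only
survival-linked factor by construction. Fixture images pack each patient's
voxels into a small box-shaped tumor with a disjoint NAWM slab of constant
1.0, so NAWM normalization is exactly the identity and the samples
round-trip bit-exactly through the NIfTI path.

What the generator does *not* emulate: spatial autocorrelation between
neighboring voxels (every voxel is an independent draw), partial-volume and
edge artifacts, registration error between the two maps, segmentation
variability, non-Gaussian dependence families (tail-asymmetric copulas such
as Clayton/Gumbel are a natural extension point; the empirical method
itself is family-agnostic), covariate-linked survival confounding, and
informative censoring. Passing tests therefore demonstrate correctness of
the computational pipeline and its behavior under controlled dependence —
not clinical validity on real cohorts, where subgroup separation will be
weaker and consensus values below 1.

## Problem sizes

The test suite and the acceptance script run cohorts of 20–115 patients
with 200–3,000 voxels per patient; the cluster-count-vote check uses 20
independent cohorts of 60 patients × 3,000 voxels, and the acceptance
script uses the full default 115-patient cohort at 3,000 voxels per
patient. These sizes were chosen to match the default cohort structure
while keeping a full run in seconds on a single core.

## Known limitations

- Equal-width binning assumes the marginals are near-uniform after the
  copula transform; with heavy ties (strongly quantized maps) midranks
  concentrate mass and bins can be uneven.
- The consensus means of well-separated synthetic subgroups saturate at
  1.0, so the LOOCV machinery's discriminating power (values like
  0.91–0.98) is only exercised on borderline cohorts.
- Complete linkage is the only implemented linkage; the voted k is
  conditional on it.
- The Cox implementation inherits statsmodels' Breslow/Efron tie handling;
  exact partial likelihood for heavily tied data is not offered.
- No spatial features: the matrix discards voxel positions by design, so
  intratumoral habitat structure is invisible to it.
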