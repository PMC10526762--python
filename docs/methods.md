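# Methods

This note documents the models behind `repsurv`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not establish about behavior on real cohorts.

## Synthetic data

**Fractional Brownian fields.** `gen_fbm_volume` synthesizes isotropic
fBm-like fields spectrally: Gaussian noise is shaped by an amplitude
spectrum with power ~ f^-(2H+d) and inverse-FFT'd. Sampling a continuous
process on a lattice folds all above-Nyquist power into the band; we
therefore synthesize the *aliased* spectrum — the sum of the target
power over integer frequency shifts (one shell by default) plus the
analytic isotropic integral of the remaining tail, added as a white
floor. Without the aliasing correction, lag-1 increments are too smooth
and any small-lag Hurst estimate is biased upward by ~0.15 at low H;
with it, the variogram-slope estimate at lags {1, 2, 4} on 64³ fields is
within 0.05 of the target for H in [0.3, 0.7]. Fields are returned
zero-mean, unit-variance.

**Phantoms.** Nested axis-aligned (optionally rotated) ellipsoids carry
the BraTS label codes; intensities are region mean + scaled fBm texture
+ i.i.d. Gaussian noise. Defaults give a ~2 cm tumor at 1 mm spacing
with distinct region means (enhancing bright, necrosis dark). The
phantoms emulate the *statistical* structure the features respond to —
region contrast, texture roughness, sub-region geometry — not MRI
physics: no bias fields, partial-volume effects, registration error or
multi-sequence contrast. Tests passing on phantoms verify the estimator
mathematics, not robustness to acquisition artifacts.

**Survival.** `gen_copula_survival` draws (V_T, V_U) from a Clayton
copula by conditional inversion and pushes them through Cox-Weibull
margins S(t|x) = exp(-(t/b)^k · e^{beta'x}). Defaults (death Weibull
shape 1.3, scale 600 days; censoring shape 1.2, scale 1100 days; n = 70)
give a median survival near one year and roughly a third of subjects
censored, matching the scale of a small glioma cohort. The latent (T, U)
pair is retained (truth columns) so dependence diagnostics are testable;
real data never carry it. Note that the marginal Kendall tau of (T, U)
mixes copula dependence with dependence induced by shared covariates;
the tau = alpha/(alpha+2) identity holds for the latent copula pair,
i.e. for simulations with zero covariate effects.

## Feature extraction

Quantization is equal-width over the in-mask range, 32 levels by
default (configurable); a constant region maps to level 1. GTSDM uses
distance 1 and the 13 unique 3D directions with symmetric accumulation;
per-direction statistics can be emitted with a direction index in the
name (off by default — the direction-indexed names seen in legacy
feature lists are treated as naming metadata, and NGTDM in particular
has no canonical directional variant, so it is computed once per
region/source). GLZSM zones use 26-connectivity; NGTDM uses the
26-neighborhood restricted to the mask. Histogram energy/entropy use 64
fixed bins over the in-mask range, log base 2.

Shape descriptors come from the spacing-scaled voxel-coordinate
covariance: axis lengths 4·sqrt(eigenvalue), per-axis orientation as
the angle (degrees) between each principal axis and the corresponding
image axis, eccentricity sqrt(1 - λ2/λ1), extent = volume /
bounding-box volume. Feature names follow the mixed legacy conventions
of published glioma radiomics feature lists (`ET2`, `L2_Orientation`,
`nec_SecondAxis_1`, `T1C_mBm_GLZSM_LargeZoneLowGrayEmphasis`, ...) so
published selected-feature lists resolve directly; the full name list is
a pure function of the feature config (~554 features with defaults).
Per-feature failures (e.g. a missing region) are recorded as NaN with a
log entry; imputation happens only inside model fitting, with
training-fold medians.

## Fractal maps

**PTPSA** tiles a 2D axial window (radius 8) around each voxel with
cells of size s ∈ {2, 4, 8}; each cell contributes the area of the four
triangles spanned by its corner intensities and their mean at the cell
center; the local fractal dimension is 2 − slope of log A(s) vs log s,
clamped to [2, 3]. Two numerical choices matter: (i) the per-voxel area
A(s) is the window-mean cell area rescaled to the window tiling, which
lets the whole map be computed with uniform filters; (ii) intensities
are internally rescaled to a fixed lag-1 increment scale (gain 24)
because the prism construction mixes spatial and intensity units — the
area-scaling regime is only visible when vertical relief dominates the
cell size, and the rescale also makes the map invariant to affine
intensity changes. A constant image yields FD = 2 exactly; fBm slices
give FD within 0.1 of 3 − H for H ≥ 0.5 (within 0.25 across the range
tested).

**mBm** regresses the log local mean squared increment (all six axis
directions, averaged over a radius-4 cube) on log lag over lags
{1, 2, 4}; H = slope/2 clamped to [0, 1]. **GmBm** replaces the second
moment with the oscillation (max − min over Chebyshev balls); its
default radii are {2, 4, 8} because single-voxel balls are dominated by
discreteness and bias the slope upward. Both are slope-based and exactly
invariant to affine intensity transforms. Zero-variance voxels are
flagged perfectly smooth (H = 1) and logged. Boundary voxels use
shrunken supports rather than padding, so a band of width (max lag +
neighborhood radius) near the volume edge is estimated from partial
data; on a linear ramp the interior is exactly H = 1.

On homogeneous fBm both Hölder maps are noise around a constant level,
so their voxel-wise correlation is weak; on fields with spatially
varying roughness — the case the maps exist to detect — they agree
(Spearman > 0.5 across a two-Hurst composite).

## REP classification

Every iteration draws all minority-class cases plus an equal-size random
majority subset (13 + 13 with the default cohort shape), then runs
stratified k-fold CV of a gradient-boosted decision-tree ensemble
(scikit-learn `GradientBoostingClassifier`, 100 trees, depth 2, learning
rate 0.1 — pinned in config; a sweep over depth/trees/rate moved
separable-table AUC by < 0.01). AUC uses mid-rank tie handling
(`roc_auc_score`); PPV is NaN-and-logged when a fold has no positive
predictions; accuracy is reported in percent. Fold-level AUC on ~5-case
test folds is coarse: even an almost perfectly separated table yields
mean fold AUC ≈ 0.94–0.99 depending on the margin, which is the honest
ceiling of this evaluation geometry.

Feature selection is two-step: (1) across balanced resampled iterations,
features are ranked by how often the univariate screen (Shapiro-Wilk
gated ANOVA / Wilcoxon-Mann-Whitney, two-sided) reaches p < 0.05 —
a selection-frequency ranking; an F1-based ranking over single-feature
classifiers is available behind the same switch and is the default for
the survival branch; (2) the top-ranked features that remain significant
on the full cohort are kept (default 3). With 3 informative features of
2 SD shift among 597 nulls at the 13/57 cohort shape, the informative
triple is recovered in ≥ 9 of 10 seeds.

## Survival under dependent censoring

**Likelihood.** With Y = min(T, U), δ = 1(T ≤ U), Cox margins
S_T(t|x) = exp(−Λ(t) e^{βx}) and S_U(t|x) = exp(−Γ(t) e^{γx}), and a
Clayton copula C_α joining them, the per-subject log-likelihood is

    δ = 1:  log dΛ(Y) + βx − α·A + ((1+α)/α)·(−log S)
    δ = 0:  log dΓ(Y) + γx − α·B + ((1+α)/α)·(−log S)

with A = Λ(Y)e^{βx}, B = Γ(Y)e^{γx} and S = e^{αA} + e^{αB} − 1 (signs
arranged so the α → 0 limit is the independent likelihood). Both
baselines are step functions with jumps at the observed event/censoring
times, and everything — β, γ and all log-jumps — is maximized jointly
with L-BFGS using an analytic gradient whose risk-set sums are suffix
cumulative sums over time-sorted subjects (O(n log n) per evaluation).
The log-S term is evaluated in max-shifted form so α up to 30 with deep
tails does not overflow. At α = 0 the problem separates and the profile
maximizer equals the Cox partial-likelihood estimate: the implementation
agrees with an independent Newton solver to ~1e-6 at n = 500, and the
fitted β at the generating α = 8 has |bias| ≈ 0.01 over 20 seeds.
Standard errors come from the curvature of the profile log-likelihood in
β (two warm-started re-optimizations at β ± h, h ≈ 0.25/sqrt(events));
Wald p-values are two-sided. Ties are handled Breslow-style (each tied
event keeps its own jump over the common risk set); continuous survival
times are assumed.

**Dependence selection.** `select_alpha` follows the cross-validated
concordance recipe: per grid α, univariate coefficients are fit on
training folds, the PI is scored on held-out folds with Harrell's
c-index against the observed (Y, δ), and the best mean c-index wins
(ties to the smaller α). A caveat the simulations make explicit: the
c-index is computed on *observed* outcomes, and when censoring is
covariate-predictable the misspecified independence fit genuinely ranks
observed times best (censoring-driven covariates earn spurious death
coefficients that help observed-data concordance), so the criterion is
drawn toward α = 0; the joint semiparametric likelihood is conversely
monotone increasing in α. The dependence parameter is weakly identified
from (Y, δ) alone — consistent with the known nonidentifiability of
Archimedean competing-risks models without covariates — and the
selected α should be read as a sensitivity-analysis device, not a
consistent estimate. c-index scoring uses the PI (not per-feature
predictors).

**Copula-graphic estimator.** With φ the generator and π̂(t) the at-risk
proportion, Ŝ(t) = φ⁻¹[−Σ_{events ≤ t} (φ(π̂) − φ(π̂ − 1/n))], processed
sequentially through tied events. At α = 0 this telescopes exactly to
Kaplan-Meier (verified to 1e-10 against an independent implementation),
and with no censoring it is the empirical survival function for every α.
The last event at risk-set size 1 sends φ(0) = ∞ through φ⁻¹ to S = 0.

**Grouping and testing.** The PI uses z-scored features (coefficient
magnitudes of published prognostic indices are consistent with
standardized inputs). The median split puts the extra subject of an odd
cohort in the bad (high-PI) group — 67 subjects split 33 good / 34 bad —
with PI ties broken by stable subject order and logged. D is the mean
|S_good − S_bad| over the union of event times restricted to the overlap
of the groups' observed time ranges; the permutation test permutes group
labels preserving sizes and uses the add-one p-value
(1 + #{D_perm ≥ D_obs})/(1 + n_perm), which is super-uniform under the
null (measured type-I error 0.058 at nominal 0.05 with 200 permutations,
granularity included). Two-step survival feature selection mirrors the
REP branch with an F1 pre-screen (default threshold 0.7, configurable —
the meaningful threshold depends on the cohort's F1 range) followed by
per-feature dependent-Cox fits kept at p < 0.05, ascending p.

The three subjects neither dead nor censored in a cohort table are
excluded from survival modeling; censored-then-died subjects contribute
δ = 1 at the death time when one is recorded, else δ = 0 at last
follow-up — exposed as a loading policy since conventions differ.

## Problem sizes in the test suite

The suite verifies at desk scale, chosen to keep the full run in a few
minutes: Kendall-tau checks at n = 5000; Cox equivalence/recovery at
n = 500 over 20 seeds; permutation calibration over 500 replicates of
n = 60 with 200 permutations; fractal recovery on 64³ volumes and 96²
slices over 5 seeds; selection recovery on 600-feature, 70-subject
tables. Texture statistics are validated against exhaustive brute-force
enumeration on randomized masks up to 6³.

## Known limitations

- The dependence parameter α is weakly identified (above); analyses
  should report results across an α grid rather than trusting a single
  selected value.
- Fold-level AUC on ~26-case balanced subsamples is coarse; distribution
  means should be read together with their spread.
- PTPSA's absolute FD level depends on the window/scale schedule; the
  defaults are config-exposed and only the constant-image value (FD = 2)
  and the ordering in H are schedule-free.
- Phantoms do not emulate MRI acquisition physics, multi-sequence
  contrast, or segmentation error; real-data performance claims require
  real cohorts.
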