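# Methods

## Problem and pipeline

The analysis asks whether quantitative texture of a single 2D tumor ROI on
T2-weighted MRI (a) distinguishes treated from untreated tumors in a small
two-arm animal cohort, and (b) correlates with overall survival and with
histological markers (fibrosis fraction, CK19-positive fraction, Ki67
counts). The pipeline is: per-subject intensity normalization → 152-feature
extraction → correlation-based redundancy removal → exhaustive-search
kernel-SVM subset selection under leave-one-out (LOO) validation →
univariate association statistics and Kaplan–Meier survival.

## Preprocessing

ROI intensities are min–max normalized to [0, 1] using the masked min/max
(per subject), and matrix-based features are computed on an equal-width
quantization of [0, 1] into `n_levels` gray levels (1-based inside the mask,
0 outside). `n_levels` defaults to 32: small enough that 8-per-arm cohorts
populate 32×32 co-occurrence matrices, and exposed as a knob. Because
normalization precedes quantization, every matrix-based feature is invariant
to affine intensity rescaling of the raw acquisition; base first-order
statistics are computed on the intensities as given to the extractor, and
the analysis drivers normalize first. A constant masked region normalizes to
zeros with a warning rather than an error. The alternative reading of
"scaled to the same range" as cohort-wide standardization is noted as an
ambiguity; per-subject min–max is the implemented default.

## The 152-feature inventory

The total (152) and the structure (seven families, gradient and wavelet
filters, power/FoS/GLCM/GLRM on four wavelet sub-bands, FoS of the HoG) pin
the family sizes almost uniquely; the inventory used here is the consistent
reconstruction with FoS = {mean, variance, skewness, entropy} and GLCM =
{contrast, correlation, energy, homogeneity, entropy, dissimilarity}
(7·|FoS| + 6·|GLCM| + 88 = 152 with GLRM at the standard 11, riu2 LBP at 10,
fractal at 2, shape at 6, band power at 1). It is frozen — names, order and
count are constant across inputs — and contains every feature named in the
published results (gradient long-run emphasis, diagonal-band mean and
variance, vertical-band LGRE/LRE/skewness, approximate-band SRE, HoG
entropy). **This breakdown is a reconstruction, not a published inventory.**

Conventions (all exposed or documented):

- Matrix features use distance-1 offsets at 0°/45°/90°/135°, only pixel
  pairs/runs wholly inside the mask, symmetrized and normalized GLCMs, and
  direction-averaged features (the dominant radiomics convention; the
  alternative of per-direction features would triple-count anisotropy).
- A masked-out pixel breaks a run; runs are maximal same-level segments
  along each scan line.
- Entropies are base 2 with 0·log 0 := 0; FoS entropy uses a 32-bin
  histogram over the observed min–max (constant input ⇒ 0 bits).
- Gradients are 3×3 Sobel with reflect padding; the mask is eroded by one
  pixel so no stencil crosses the tumor boundary. The HoG is one global
  magnitude-weighted 9-bin histogram of unsigned orientation in [0°, 180°),
  with linear vote splitting between neighboring bin centers (10°…170°,
  wrapping across the fold) — no cells or blocks, since only its first-order
  statistics enter the feature vector.
- The Haar transform is the single-level orthonormal 2D transform, defined
  per 2×2 block; odd dimensions are symmetric-padded. Orthonormality makes
  band energies comparable and energy conservation exactly testable
  (verified to 1e-9 together with perfect reconstruction). Which detail band
  is "horizontal" versus "vertical" is a convention; it is fixed as
  horizontal = (a+b−c−d)/2, vertical = (a−b+c−d)/2. Band masks are the 2×2
  logical-OR downsample of the tumor mask (keeping boundary texture); band
  "power" is the mean squared coefficient over the band mask (mean rather
  than sum, so it is ROI-size invariant). Detail bands are independently
  min–max normalized before quantization so their signed, near-zero-mean
  coefficients populate all gray levels.
- LBP uses the 8 square neighbors at radius 1 (bit set iff neighbor ≥
  center), mapped to the 10 rotation-invariant uniform (riu2) labels.
- Fractal dimension is the box-counting slope over dyadic box sizes spanning
  the bounding box of the Otsu-binarized masked image; lacunarity is the
  gliding-box statistic var/mean² + 1 at a 4-px window. Fewer than 2
  occupied pixels yields 0 with a warning.
- Shape: area; perimeter as the count of exposed pixel edges
  (4-connectivity, so a 3×3 square has perimeter 12); circularity 4πA/P²;
  moment-based eccentricity; solidity; extent — on the largest connected
  component.

## Reduction and selection

The correlation filter greedily removes features while any kept pair has
|r| > 0.50: among the worst pair, the feature with the larger mean absolute
correlation to the remaining features is dropped (ties drop the later
canonical column). Absolute r is used deliberately — an anti-correlated
duplicate is equally redundant. Constant columns are dropped first with a
warning. The filter is deterministic and row-order invariant.

Selection scores every size-k subset by LOO accuracy of an SVM and stops
when the best accuracy improves by ≤ 10⁻³ (with best(0) := 0, so k = 1 is
always evaluated); the selected subset is the best at the last improving k.
Ties go to the lexicographically first subset in canonical order. When a
level reaches accuracy 1.0 the next level cannot improve, so the rule fires
without enumerating it. The classifier is an RBF SVM with C = 1 and
γ = 1/(k · variance of the fold-standardized training matrix); kernel, C, γ
and standardization were not published and are exposed in `SelectionConfig`.
Standardization is computed strictly on each training fold — a leakage test
asserts that an extreme outlier in the held-out subject cannot perturb the
scaler. A guard aborts searches beyond 10⁷ subset evaluations unless forced.
LOO accuracy is the honest reading of the published "increasing accuracy";
resubstitution accuracy of the final model would be the optimistic
alternative and is not implemented.

## Association statistics

Pearson r carries a two-sided p from the t distribution with n − 2 df
(t = r·√((n−2)/(1−r²))). Group comparisons use the pooled-variance Student
t (Welch available) and report Cohen's d as an absolute standardized
difference; for summary-statistics input with unknown n the equal-weight
pooled SD √((s₁²+s₂²)/2) is used — this reproduces four of the seven
published effect-size rows to <0.1% (3.162, 3.971, 2.058, 2.233); the
remaining three rows do not reproduce under any standard pooling of their
printed means/SDs. Kaplan–Meier estimation and the log-rank test come from
lifelines. The feature screens are reported uncorrected for multiplicity by
default (matching the published analysis), with a Benjamini–Hochberg option
off by default.

## Synthetic cohorts

Each subject's image is a Gaussian random field — white noise smoothed by an
isotropic Gaussian kernel of width `correlation_length` (px), rescaled to
marginal SD `noise_sd` (0.15) around `mean_level` (0.5) — masked by a filled
ellipse with semi-axes uniform on 8–14 px (both arms share the size
distribution, so size carries no signal). The arms differ only in
correlation length (defaults 1 px control vs 6 px treated, with 1 px
per-subject jitter), which moves spatial-smoothness statistics without
changing mean intensity. Survival is baseline 30 d + 4.2 d/px × realized
correlation length + N(0, 19 d), floored at 1 d — chosen to emulate arm
means near 55 vs 34 days with ~16–20-day within-arm spread and a frequently
non-significant log-rank test at n = 8+8. Events are observed for all
subjects by default; a censoring fraction is available for the survival
tests. Histology markers are loc + scale·(ρ·z + √(1−ρ²)·ε) with z the
standardized designated extracted feature (defaults: fibrosis ↔ HoG entropy
ρ = 0.84, CK19 ↔ HoG entropy ρ = −0.97, Ki67 ↔ vertical-band mean ρ = 0.81),
so the population correlation equals ρ exactly. All randomness flows from
one seed through `SeedSequence` spawning (one stream per subject, one per
marker); equal seeds give bit-identical cohorts.

What the generator does *not* emulate: MRI physics (bias fields, Rician
noise), pseudoprogression dynamics, 3D anatomy, inter-rater segmentation
variability, or realistic feature scales. Passing tests therefore
demonstrate statistical and algorithmic correctness of the pipeline — not
that these features are biomarkers on real scanners.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study scale: 64-px canvases,
8+8 subjects, 20-seed recovery experiments, 100–300-replicate null
calibrations, 100-image brute-force oracle comparisons (8×8 images, 4
levels, 1e-12 agreement), and n = 500 cohorts for the histology-link
convergence check. Null calibration draws labels iid Bernoulli(0.5) rather
than permuting a fixed 8/8 split: with fixed margins the held-out subject is
always in the training minority, giving LOO its classic pessimistic bias
(a majority-rule classifier would score 0, not 0.5); under iid labels the
held-out label is independent of the training fold and the expected accuracy
of any classifier is exactly 0.5, which is the property being calibrated.

## Known limitations

- The 152-name inventory is a reconstruction (see above); absolute feature
  values are not comparable to other radiomics software (no IBSI alignment).
- At n = 16, the correlation filter keeps ~15–25 features and which
  texture family wins the subset search varies by seed: correlation length
  moves LBP, band-skewness and fractal features as well as GLCM/GLRM, and
  the selected subset contains a GLCM/GLRM feature in only ~70% of seeds
  even though selection accuracy itself is stable (≥ 0.90 in ~85–90% of
  seeds).
- Printed p-values of the published group comparisons are not recomputable
  without the per-analysis n and are not targeted.
- Single-slice 2D analysis only; no Cox regression or multivariable
  survival modeling.
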