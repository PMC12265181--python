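# Methods

This note records the modeling conventions of `brainsym`, the choices
made where the underlying procedure admits more than one reasonable
reading, and what the synthetic test bed does and does not establish.

## Per-slice asymmetry (GMSD)

**Gradient operator.** The gradient magnitude uses a 3×3 derivative
kernel pair; `prewitt` (default), `sobel` and `scharr` are available.
Kernels are normalized by the sum of their positive weights (Prewitt
1/3, Sobel 1/4, Scharr 1/16) so a unit step produces a unit response;
the documented step-edge examples in the tests rely on this
normalization.  Convolution uses symmetric (reflect) padding, which
keeps the output the size of the input and makes GMSD exactly invariant
under joint mirroring of both images.

**Stability constant.** The GMS map's constant is C = 170 for images on
a 0–255 scale, the convention of the original GMSD formulation.
Because C is added to *squared* gradient terms, automatic rescaling to
an image pair's dynamic range is quadratic: C = 170·(range/255)².  This
makes the score invariant to a global intensity rescaling of both
images.  C is configurable for users who want the literature value
regardless of scale.

**Pooling.** GMSD is the *population* standard deviation (divisor N)
of the GMS map about its mean, over all N pixels.  Skull-stripped
slices contain large zero backgrounds where GMS ≡ 1; an optional
foreground mask (either image nonzero, dilated 3 px) can exclude them,
but pooling over all pixels is the default.  No prefiltering or
downsampling is applied: the score feeds an axis search, where slice
geometry must be preserved; a `downsample`-style option was
deliberately not added.

## Symmetry-axis search

The search is exhaustive over a finite grid: centroid recentering
(rounded to whole pixels — sub-pixel refinement is delegated to the
perturbation grid), all integer center offsets with |dx|, |dy| ≤ 2
(25 candidates; "one and two pixels in all directions" is read as the
full integer grid, a superset of any 4- or 8-direction reading),
and rotations in 0.5° steps to ±5° (21 angles).  Rotation uses
bilinear interpolation with zero fill; the interpolation scheme is a
package convention, as is the tie-break on equal scores (smallest
|angle|, then smallest |dx|+|dy|, then enumeration order) chosen for
bit-reproducibility.  The reported `angle_deg` is the tilt of the
symmetry axis in the input image; `axis_line_original` maps the axis
back through the inverse transform for overlay rendering.

## Slices and volume conventions

Volumes are assumed skull-stripped and atlas-aligned upstream, nominal
shape (176, 208, 176) with the left–right anatomical axis first.
Axial indices fix the third coordinate, coronal indices the second;
the published slice numbers (axial 68–108, coronal 84–124, spaced 10
voxels to avoid extreme inter-slice correlation) are used verbatim as
0-based indices.  `extract_slice` returns the plainly indexed plane;
the profiling stage transposes it so the left–right axis lies along
image columns, making the mirror reflection a hemispheric flip.

The "diagonal" slice (frontal lobe to cerebellum) is defined as the
plane through the volume center obtained by pitching the axial plane
about the left–right axis, default 45°, resampled trilinearly.  The
exact oblique plane used in prior work is not recoverable from its
description; the pitch is configurable and this definition is a
documented convention, not a claim about that plane.

## MIMIC estimation

**Discrepancy and χ².** ML fitting minimizes
F = ln|Σ(θ)| − ln|S| + tr(SΣ⁻¹) − p with S the divisor-(n−1) sample
covariance; χ² = (n−1)·F (Wishart convention).  An n·F convention
would change χ² by under 1% at n = 132 and no reported two-decimal
index.

**Exogenous block.** The predictor covariance block Φ is saturated.
By the conditional-likelihood factorization its ML estimate is exactly
S_xx, so it is fixed there and the remaining parameters (10 free
loadings, ψ, 3 paths, 11 residual variances, 4 residual covariances —
29 in all) are optimized.  Counting Φ's 6 exactly-fitted moments as
parameters gives df = 105 − 35 = 70 for the full model and 40 for the
CFA.  Standard errors from the inverse expected information over the
29 free parameters are therefore fixed-x standard errors: exact
asymptotics given the observed predictors, regardless of the
predictors' own (non-normal) distributions.

**Identification and standardization.** Default identification fixes
the first indicator's loading to 1; fixing the latent (disturbance)
variance to 1 instead is available and yields the same fitted
covariance.  The standardized solution (loadings as indicator–factor
correlations, paths scaled by sd(x)/sd(η)) is invariant to that
choice, which the tests verify to 1e-6.

**Optimization.** Start values take loadings from the first principal
axis of S_yy and residual variances at half the indicator variances;
L-BFGS with analytic gradients is followed by Fisher-scoring polish
(step-halving, gradient tolerance 1e-11) for the quadratic tail — this
is what lets population-moment fits return the generating parameters
to 1e-6.  For conditioning the optimization runs on sd-standardized
moments; the discrepancy is invariant to that rescaling and every
parameter maps back by a fixed factor.  The procedure is fully
deterministic: no random restarts.  Non-convergence and Heywood cases
(negative variance estimates) are flagged on the fit object and warned
about, never silently accepted.

**Fit indices.** CFI and TLI use the independence baseline (indicators
mutually uncorrelated) with the exogenous block kept saturated,
consistent with the main model's convention; the baseline optimum has
a closed form.  RMSEA = √(max(χ²−df,0)/(df(n−1))); its 90% CI inverts
the noncentral χ² distribution in the noncentrality parameter by
bracketed root-finding (tolerance 1e-8), and the close-fit probability
is P(χ²_df(ncp = 0.05²·df·(n−1)) ≥ χ²_obs).  SRMR is the root mean
square of the standardized covariance residuals over all p(p+1)/2
unique elements, standardized by sample standard deviations.

**Modification indices.** Univariate score (Lagrange-multiplier)
tests for each indicator residual covariance fixed at zero, with the
expected parameter change; entries with numerically singular
information are reported as NaN rather than fabricated.  A refit
comparison in the tests confirms the MI approximates the actual χ²
drop within 15%.

**Two-step procedure.** The measurement model (CFA) is fitted and
judged against conventional cutoffs (CFI/TLI ≥ 0.95, RMSEA ≤ 0.08,
SRMR ≤ 0.10) before the structural model; a failing measurement model
produces a warning but does not abort step 2, so failing pipelines
remain inspectable.

**Codings.** Sex is 0 = female, 1 = male; SES is the raw Hollingshead
score treated as numeric (1 = highest status, so a negative path means
less asymmetry with fewer socioeconomic resources); age is in years,
uncentered.  Missing data are handled by listwise deletion.

## Synthetic test bed

**Phantoms** are deliberately minimal: an ellipse with an inner core
and mirrored dark blobs, all built from |column − center| so the clean
image is mirror-exact; a one-sided Gaussian blob injects a controlled
asymmetry amplitude; tilt and offset are applied by bilinear rotation
and integer shift; Gaussian, salt-and-pepper and speckle noise (the
distortion types GMSD is robust to) are available, seeded.  Phantoms
exercise centroid, rotation, mirroring and GMSD — they do not emulate
anatomy, partial-volume effects, bias fields or registration error, so
passing axis-recovery tests demonstrates correctness of the search,
not field performance on real MRI.

**Cohorts** are drawn from the MIMIC model in the standardized metric,
with defaults at the published generating values: loadings 0.79, 0.82,
0.85, 0.87, 0.68, 0.72, 0.84, 0.81, 0.69, 0.78, 0.64; paths −0.22
(SES), 0.57 (age), 0.40 (sex); SES categorical on {1..4} with
proportions 25.8/34.8/22/17.4%; sex Bernoulli(0.28); age normal(69,
12) truncated to [33, 94] — a convenience emulation of the study
population's margins, not a claim about the real marginals.  The
residual correlation for the four freed adjacent-slice pairs defaults
to 0.3 (moderate; no published value exists).  A population-moment
mode emits the exact implied covariance for zero-discrepancy tests.
All generators are pure functions of (parameters, seed).

## Problem sizes in the validation battery

Axis recovery runs the full default grid (525 candidates) on 30
full-size (176×208) phantoms across tilts {−4°…4°} and offsets
{0, ±2 px}, clean and at Gaussian noise σ = 5% of range.  SEM
parameter recovery uses 200 cohorts of n = 2000; Wald 95% intervals
for all 29 free parameters must cover their generating values in
90–99% of replicates, and standardized estimates must be mean-biased
by at most 0.02.  Unit-level simulations (MI detection, two-step
behavior under gross misspecification) use 10–30 replicates each —
enough to pin down effects that occur in ≳90% of runs.  The end-to-end
CLI test profiles 30 synthetic volumes at 44×52×44 with a reduced
search grid, chosen to exercise every pipeline stage rather than to
benchmark.

## Known limitations

- The angle grid bounds recovery at ±5°; strongly rotated inputs need
  upstream registration (assumed done for atlas-aligned data).
- GMSD responds nonlinearly to asymmetry amplitude, so phantom-derived
  indicator sets need not follow an exact one-factor model — the
  end-to-end test's measurement model can legitimately miss the strict
  fit cutoffs while converging cleanly.
- Only normal-theory ML is implemented (no robust/WLS estimators, no
  FIML, no ordinal-indicator SEM, no multi-group invariance testing).
- The estimator assumes a single latent factor with simple structure;
  it is not a general SEM engine.
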