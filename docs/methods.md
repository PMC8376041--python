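# Methods

`embryograd` quantifies anterior-posterior (AP) intensity gradients of
maternal factors — *bicoid* (*bcd*) mRNA and the Staufen (Stau) transport
protein — in sagittal sections of early *Drosophila* embryos, and stages
embryos from the fitted gradient parameters.  This note describes the
models, the numerical choices, and what the synthetic data used throughout
the test-suite does and does not establish.

## Profile model

An intensity profile I(x), x in percent egg length (%EL, 0 = anterior
pole), is modeled as a sum of exponentials

    I(x) = sum_i C0_i exp(alpha_i x)  [+ B],

with three model kinds:

* `1expB`: one decaying exponential plus uniform background B — the
  classical single-source description of the Bcd protein gradient; kept for
  diagnostics.
* `2exp`: a steep *anterior* component plus a *shallow* posterior
  component; the default for bcd mRNA profiles.
* `3exp`: additionally a posteriorly *rising* component (alpha > 0),
  needed for Stau profiles with a posterior signal (likely unrelated to
  bcd, e.g. *oskar* transport).

Derived quantities: the exponential base lambda = exp(alpha) per %EL
(closer to 1 = shallower) and the length constant -1/alpha (%EL, distance
over which intensity falls by e).  Components are stored in canonical
order — anterior = largest contribution C0·exp(alpha·lo) at the window
start among decaying components (ties to the steeper alpha), then the
shallow component, then any rising component.

x enters the exponentials as raw %EL (not shifted to the window start), so
C0 always refers to the x = 0 extrapolation and lambda values are
comparable across fit windows.  The default windows are (10, 90) %EL for
bcd and (10, 80) %EL for Stau; both configurable.

### Fitting

Multi-exponential least squares is notoriously ill-conditioned, so
`fit_profile` uses:

* bounded trust-region least squares (`scipy.optimize.least_squares`, trf)
  with an analytic Jacobian; amplitudes C >= 0, decaying rates
  alpha in [-1, 0], the rising third rate in [0, 0.2];
* multi-start over log-spaced decay-rate grids with the amplitudes solved
  linearly by non-negative least squares at each start (default 8+
  starts), best-of-restarts returned;
* internal normalization of the intensities by their maximum, which makes
  the fit exactly gain-equivariant: scaling the data scales the C0 and B
  and leaves every alpha unchanged;
* a final polish solve restarted at the incumbent optimum, to remove
  trust-region termination error;
* missing samples (NaN) skipped, never interpolated.

The decaying-rate interval is closed at 0 deliberately: `1expB` is then
exactly the alpha2 = 0 boundary of `2exp`, and `2exp` the C3 = 0 boundary
of `3exp`.  The restart list of each model includes the optimum of the
next simpler model mapped onto that boundary, so the fitted SSE values are
nested by construction — SSE(3exp) <= SSE(2exp) <= SSE(1expB) — rather
than only up to optimizer luck.  A component returned on the alpha = 0
boundary is background-like and carries no slope information; feature
computation flags it as missing (below).

`select_model` returns `3exp` over `2exp` only when the 3exp fit
converges, its third component genuinely rises, and the SSE improves by
more than a relative threshold (default 5%).

### Estimation limits

The anterior amplitude C1 is an extrapolation to x = 0 from data starting
at 10 %EL, so errors in alpha1 and ln C1 are strongly correlated and grow
with gradient steepness.  At additive noise of 2% of the anterior
amplitude on a 1 %EL grid, the Cramér–Rao bound gives sd(lambda1) ≈ 0.01
for a shallow anterior gradient (alpha1 = -0.1), but ≈ 0.04 for a steep one
(alpha1 = -0.2): no fitting algorithm can beat this.  The parameter-recovery
benchmark (`BENCHMARK_2EXP`: C = (100, 10), alpha = (-0.1, -0.008)) is
therefore defined in the shallow regime typical of syncytial-stage
profiles, where the anterior base sits close to 1; measured median errors
(|lambda1| ≈ 0.007, |ln C1| ≈ 0.06 over 100 noise draws) agree with the
bound, confirming the estimator is essentially efficient.

## Staging features and classification

Four features per embryo, computed from the paired (apical, basal) 2-exp
fits:

| feature | definition | meaning |
|---|---|---|
| lambda1_apical | exp(alpha1) of the apical anterior component | gradient steepness under the surface |
| lambda1_basal | same, basal layer | steepness below the nuclei |
| cab | ln(C1_apical / C1_basal) | which layer is brighter at the anterior |
| shallow_ratio | (C2_ap·alpha2_ap)/(C2_ba·alpha2_ba) | amplitude-slope ratio of the shallow parts |

cab and shallow_ratio are invariant under a common positive rescaling of
both layers (arbitrary microscope gain); the invariance is exact up to the
conditioning of the statistic, since fitting is performed on
max-normalized data.  shallow_ratio is used raw (not logged), and flagged
missing (NaN) when either layer's shallow component degenerates to the
alpha = 0 boundary; such rows are excluded from classification, never
imputed.

Staging uses standard linear discriminant analysis (pooled within-class
covariance, empirical priors; `scikit-learn` under the hood) over the
three main stages — cleavage (pre-blastoderm, cc 1-9), syncytial
blastoderm (cc 10-13), cc14 (cellularization).  Prediction ties are broken
by the fixed developmental order cleavage < syncytial < cc14.  A
numerically singular pooled covariance (checked scale-invariantly, on the
correlation matrix) triggers a logged shrinkage refit.  Evaluation reports
a confusion matrix under leave-one-out by default — the honest choice at
these sample sizes; resubstitution and stratified 5-fold are also
available — with an optional label-permutation p-value for
above-chance accuracy.  Group differences are tested by permutation on a
standardized between-group statistic (per feature, plus an omnibus sum);
per-class accuracies measured on the original confocal dataset cannot be
reproduced here because that dataset is not publicly deposited.

## Synthetic data

Because no real data are available, the generator produces data with the
statistical structure the analysis assumes; it is phenomenological and
simulates no transport or reaction-diffusion mechanism.

**Profiles/cohorts.**  Stage presets (three main stages, nine age
sub-groups CleavageEarly … cc14late) hold per-layer 2-exp means chosen to
reproduce the qualitative developmental trends: cleavage has the sharpest
apical anterior gradient (lambda1 ≈ 0.87) and apical brighter than basal
(cab > 0); syncytial is shallower (lambda1 ≈ 0.93) with the flip to basal
brighter (cab < 0); cc14 keeps lambda1 high (≈ 0.95) and flips back to
apical brighter, strongly so by late cc14 (cab up to ≈ 1.1); lambda1 rises
monotonically from CleavageEarly through cc13.  Between-embryo variation
is lognormal on amplitudes (sd of ln C0 = 0.15) and on decay-rate
magnitudes (sd 0.10), preserving signs.  Measurement noise defaults to
additive Gaussian with sd = 2% of the nominal anterior amplitude;
multiplicative and baseline terms are available but off by default, since
no published noise magnitudes exist for these preparations.  All preset
means and noise levels are generator configuration, not measured values.

**Images.**  A scene is an axis-aligned ellipse (default 192×384 px,
semi-axes 80×180) with two cortical bands at the apical (8 px) and basal
(26 px) depths below the surface (half-width 6 px), modulated along the AP
axis by the per-layer gradients; optional nuclei (discs in the nuclear
layer between the bands), smooth sinusoidal texture, and noise.  Gradients
are parameterized by the AP-chord projection in %EL with origin at the
anterior pole — the same coordinate the extraction reports — rather than
cortical arc length; dorsal and ventral halves may carry different
parameters.  The rendered image stores an exactly decomposable ground
truth: trend + texture + noise equals the pixel grid bitwise.

**What passing tests show.**  Synthetic embryos are ellipses with sharp
band edges, stationary Gaussian noise and no scattering, bleaching,
segmentation error or staging-label noise.  Tests on them establish the
*correctness* of the algorithms (recovery at the information limit, exact
algebraic identities, above-chance staging under the assumed regimes), not
the robustness of the pipeline to real-microscopy artifacts.

## Profile extraction

Contours offset a given depth inside the embryo mask are obtained from the
Euclidean distance transform (sub-pixel, via marching squares), ordered
from the anterior pole posteriorly, restricted to the dorsal or ventral
branch or run ventral → anterior pole → dorsal for whole-cortex sweeps.
ROI centers are placed at uniform arc-length spacing (a spacing above the
disc diameter warns about coverage gaps); each sample is the mean over
pixels whose centers fall inside the disc intersected with the mask
(0-based row/col, pixel centers at integers).  Positions are the AP-chord
projection in %EL so apical and basal profiles share one axis; custom
contours report arc-length fraction.  ROIs with no valid pixel yield NaN.
Default depth/radius/spacing values are configuration: the original
acquisition parameters are unpublished.

## 2D and shaped 2D SSA

2D singular spectrum analysis embeds every Lx×Ly sliding window of the
image as a column of a Hankel-block-Hankel trajectory matrix, takes its
SVD, groups eigentriples, and reconstructs each group by averaging all
patch placements covering a pixel.  The default grouping follows the
trend / mid-frequency convention: F1 = eigentriple 1 (smooth expression
surface), F2–F4 = eigentriples 2–4 (local cytoplasmic inhomogeneities),
residual = everything else (noise), with the residual defined as the
difference so the three parts sum exactly to the input on the analyzed
region.  A w-correlation matrix (weights = per-pixel placement coverage)
is provided as a grouping diagnostic.  The shaped variant admits an
arbitrary pixel mask: only window placements lying entirely inside the
mask enter the trajectory matrix, and pixels covered by no placement are
reported as NaN, never zero-filled; a full-rectangle mask reduces exactly
to plain 2D SSA.  Window sizes default to a quarter of the region extent
per axis (the originally used windows are unpublished); dense SVD is used
up to moderate sizes with an iterative truncated SVD for large trajectory
matrices.

## Gradient summaries

*Prototypical profiles* average the fitted (C0, alpha) parameters
arithmetically per canonical component over a stage group and evaluate the
mean model (averaging parameters, not curves; a group mixing model kinds
is reduced to the common two components).  *Cumulative distributions* of
intensity mass use trapezoid integration on the observed grid after
subtracting a flat background anchored at 95 %EL (negative values clipped
at zero, with the clipped fraction reported) — the ECDF of an exponential
sampled on a uniform grid is exactly reproduced by the trapezoid rule
after normalization, since the per-segment quadrature factor cancels.  The
reference curve is the closed-form ECDF of a single exponential with
length constant 20 %EL (the standard Bcd protein approximation); curves
are compared by sup-norm distance.  RNA-like cohorts generated with length
constants in the 0.15–0.25 EL band stay in that band after fitting (tested
on cohort means).

## Problem sizes and determinism

The test-suite and the acceptance script run entirely on synthetic data at
desk scale: 100 profiles for the recovery benchmark, cohorts of 20 embryos
per stage for staging (leave-one-out with 199 label permutations), 128×128
images for the SSA identities and 96×96 for the denoising check.  Every
stochastic step is driven by explicit `numpy` generator seeds; identical
seeds give bitwise-identical data.

## Known limitations

* The exact ROI geometry, fit initialization, LDA priors and SSA windows
  of the original analysis are unpublished; defaults here are documented
  package choices, so numeric agreement with the original per-class
  accuracies is neither expected nor claimed.
* Prototype averaging on (C0, alpha) is one of several defensible
  conventions (vs averaging lambda, log C, or the curves themselves).
* shallow_ratio is heavy-tailed and ill-conditioned when the shallow
  component is weak; it is the least reliable of the four features, and
  rows lacking it are dropped from staging.
* The synthetic generator's stage presets encode ordering relations, not
  measured parameter values; staging accuracy on synthetic cohorts says
  nothing quantitative about accuracy on real embryos.
* Real-image segmentation is out of scope: masks come either from the
  generator or from a simple threshold + largest-component rule.
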