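# Methods

`petidif` implements an image-derived input-function (IDIF) workflow for
dynamic [18F]-FEPPA brain PET: two ways of extracting the arterial
whole-blood curve from the image itself (carotid-signal hottest pixels, and
blind unmixing of the cranial blood pool with an asymmetric-Laplace source
prior), the blood processing that turns a whole-blood curve into a
metabolite-corrected parent-plasma input function, two-tissue-compartment
quantification of the total distribution volume V_T, the agreement
statistics used to compare input-function methods, and a synthetic
dynamic-PET phantom that provides ground truth for all of it.

## Blood processing

The input function is assembled as

    Cp_parent(t) = C_wb(t) / r(t) * pf(t)

where `C_wb` is whole-blood activity, `r(t)` the whole-blood-to-plasma
concentration ratio fitted to manual samples with a bi-exponential
`r(t) = offset + a1 e^{-b1 t} + a2 e^{-b2 t}` (rates per minute), and
`pf(t)` the parent (un-metabolized) fraction fitted with a Hill curve

    pf(t) = 1 - A * t^s / (t^s + h^s),

which satisfies `pf(0) = 1` and is monotone non-increasing; `h` (minutes)
is the half-metabolism time when `A = 1`. Both conventions of the
blood/plasma ratio are supported (`ratio_is_plasma_to_blood`), guarding
against convention drift between sites.

Continuous arterial sampling lines disperse the blood curve; this is
modelled as convolution with `(1/tau) exp(-t/tau)`, `tau = 16 s` by
default. The inverse used for correction is the exact continuum identity
`C_true = C_meas + tau dC/dt`, with a Savitzky-Golay smoothed derivative
(window 7, order 3) for noise stability. The round trip is accurate to well
under 1% for smooth curves; a bolus with a derivative kink at its onset
(e.g. the linear-rise Feng model) degrades any finite-difference derivative
near the kink, which is a known limitation of the derivative-based inverse.
Delay between the blood curve and the head signal is estimated by fitting
the first 50 s of the head curve to an irreversible one-compartment uptake
`head(t) = K * int blood(s - delta) ds`, grid-searching `delta` with the
gain profiled out in closed form.

Image-derived curves carry no line delay or dispersion; they are instead
(1) repaired for a single inversion point near 1.5 min (a locally
non-monotone sample is replaced by the manual sample value when it
coincides, else by neighbour interpolation), and (2) calibrated by one
whole-blood sample at 15 min (pure rescaling). Calibration resolves the
scale ambiguity of blind unmixing, so the whole ICA pipeline is invariant
to a global rescaling of the image.

## Carotid-signal extraction

A binary mask is built by thresholding the mean of the first 10 frames at
0.48 x its global maximum, restricted to the lowest 36 axial planes on
full-size images (a proportional lowest third on reduced grids); the
boundary is inclusive (>= threshold). The whole-blood TAC is the per-frame
mean of the ten hottest masked voxels of each plane. Hot voxels are
re-selected each frame by default (a fixed early-mean-based set is a config
option); ties at the selection boundary are all included and the mean
renormalized, so the result does not depend on voxel ordering.

## ALD-prior ICA extraction

The blood-pool ROI (same 0.48 threshold, all planes) is smoothed within the
mask (3 mm FWHM, kernel renormalized over the mask) and rearranged into a
frames x voxels matrix X. Rows are centered over voxels, the time
covariance eigendecomposed, and the top two eigenpairs kept and whitened.
The demixing matrix W is estimated by maximum likelihood with each source's
voxel-intensity distribution modelled as an asymmetric Laplace density
(location m, scale sigma, skew kappa; kappa = 1 symmetric), whose
parameters are re-estimated from the current sources at every iteration by
a moment scheme: kappa from the sample skewness through the exact ALD
skewness-kappa relation, sigma from the variance, and m from the mean minus
the analytic mean offset `sigma/sqrt(2) (1/kappa - kappa)`. The sample
median is *not* used for m because it is not a consistent estimator of the
ALD location for kappa != 1.

Two optimizers are provided. `ica_mle` is the symmetric natural-gradient
update `W <- W + lr (I - <phi(y) y^T>) W` with the ALD score phi, step
halving on likelihood decrease, and convergence on the Frobenius norm of
the update; it is accurate when the spatial sources are close to
independent. Thresholded blood-pool masks, however, produce strongly
anti-correlated spatial patterns (the threshold forces the total blood
loading of every retained voxel into a narrow band, so the arterial and
venous patterns are nearly affinely dependent); the joint likelihood then
has its optimum away from the true demixing. Each true demixing *row*
remains a minimum of the per-direction ALD negative log-likelihood —
projecting the voxel cloud along its own demixing row collapses one source
to the sharp peak of the histogram, which is exactly the sharply peaked,
skewed shape the ALD models. `ica_pursuit` therefore estimates the two rows
one at a time (dense angular scan plus refinement, then a local joint
natural-gradient polish), and is the default for two components.

Component time courses (the columns of the back-projected mixing estimate)
are kept on the results object. For the pipeline's whole-blood curve,
however, the arterial curve is read from the *source voxels*: voxels are
ranked by their arterial-source loading minus competing-source loadings
(each normalized to its 95th percentile), screened by a washout criterion
(late-scan activity relative to the voxel's own peak must be in the lowest
40% — blood washes out, tissue retains), and the top 30 original voxel TACs
averaged. This keeps venous and tissue spill-in out of the curve where the
back-projected mixing column would be contaminated by cross-talk whenever
the demixing rows are oblique. The arterial component is identified
automatically as the blood-like curve (early positive peak, essentially
one-signed) with the earliest peak, ties broken by the sharper peak; both
candidates and the rule are recorded so the occasional manual override can
be audited, and a component that does not look like blood at all (e.g. the
second component of a carotid-only ROI, which holds only one vascular
source) is flagged as degenerate rather than silently returned.

## Kinetics

The two-tissue compartment model

    dC1/dt = K1 Cp - (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 - k4 C2,
    C_PET = (1 - vb)(C1 + C2) + vb C_wb

is solved analytically (bi-exponential impulse response) and evaluated by
discrete convolution on a 1 s grid with trapezoid end-point correction,
then averaged over the frame schedule through a precomputed linear
operator. The endpoint is `V_T = K1/k2 (1 + k3/k4)`. Fitting is weighted
nonlinear least squares (scipy trust-region reflective), blood volume
fixed at vb = 0.05 by default (estimable via config), rates bounded in
[1e-6, 10] /min, with five multi-starts perturbed around a physiological
initialization and standard errors from the Jacobian at the optimum.

Frames are weighted by `w_i = dt_i^2 / (T_i dc_i^2)` with `T_i` the trues
and `dc_i = exp(-lambda t_mid)` the 18F decay factor
(lambda = ln2/109.77 min ~= 6.31e-3 /min; a printed value of 6.3e-2 /min
in circulation is a factor-of-ten slip and is not used). Frames acquired
before tracer arrival have nearly zero trues and would receive essentially
infinite weight, letting two empty frames dominate the fit; weights are
therefore capped at 25 x the median positive weight. Uniform weighting is
a config option. All image activities are treated as decay-corrected, so
decay enters only through the weights.

## Agreement statistics

Input functions are compared by trapezoidal AUC ratios over the first
180 s (peak) and the remainder of the scan (tail). V_T sets are compared by
ordinary least squares (r^2 = squared Pearson correlation, slope t-test
with n-2 degrees of freedom) and Bland-Altman analysis (bias, 95% limits of
agreement at bias +/- 1.96 SD with the sample SD; a small-sample t-quantile
is available via the `quantile` argument). The difference convention is
first-argument minus second (reference minus IDIF in the pipeline
comparisons). The Amari index (normalized to [0, 1]) benchmarks the
source-separation stage against known mixings.

## Synthetic phantom

The phantom emulates an HRRT-like acquisition at desk scale: a 48x48x48
grid of 2 mm voxels, the OSEM frame schedule (a fixed 10 s first frame,
then 2x7, 2x8, 3x10, 2x15, 2x30, 1x45, 2x60, 1x90, 1x120, 1x210 and
22x300 s; ~122 min total), an isotropic 2.5 mm FWHM Gaussian PSF, and
zero-mean Gaussian noise with variance proportional to (local mean / frame
duration), clipped at zero. The default noise scale gives single-voxel
coefficients of variation around 20% in the short early frames —
conservative relative to real HRRT voxel noise. A Poisson count model is a
config option; the true HRRT reconstructed-image noise law is unknown, so
the family is a stand-in and exposed in config.

The arterial input is a Feng tri-exponential bolus (continuous at onset,
single fast peak, multi-exponential tail); the venous curve is the same
bolus delayed 3 s and dispersed with tau = 5 s, chosen so the venous
component peaks roughly 5 s after the arterial one at frame resolution.
Ground-truth metabolite parameters (bi-exponential ratio rising from 0.8
to ~1.2; Hill parent fraction falling to ~0.1 by 90 min) generate both the
true parent-plasma input and exact "manual samples".

The vascular tree is rasterized from sub-voxel tubes with varying caliber
(partial-volume fractions; no two planes identical): two thin carotid
trunks (~4 mm diameter, in the lowest third of planes) with adjacent
jugular veins, a wide sagittal-sinus column with a thin artery winding
alongside, and two deep-vein bundles braided with thin arterial branches.
Venous structures deliberately occupy more voxels than arterial ones and
thin arteries run close to large veins, so blurred voxels genuinely mix
both signals — the statistical situation a thresholded blood-pool ROI
actually presents, with sparse right-skewed arterial and dominant
left-skewed venous loading histograms. An idealized "uniform" profile
(pure voxel boxes) is available for exactness tests. Cuboid tissue regions
follow 2-TCM kinetics spanning V_T ~ 6-15 mL/cm^3, embedded in a low-uptake
background (K1 = 0.12, V_T ~ 2.4) that acts as the spill-in source.
Per-frame trues are synthesized as total field-of-view activity x duration
x decay factor, since the phantom has no list-mode data.

The multi-subject phantom study varies, per subject: bolus appearance time,
amplitude and washout; all tissue rate constants (15% lognormal jitter)
plus a global specific-binding scale (25% lognormal, emulating the TSPO
affinity-genotype spread); vessel calibers and positions (15% lognormal
radius, sub-voxel position jitter); and the noise realization. Each subject
is processed end to end by the carotid-signal and ICA pipelines and
compared against a reference fit that uses the exact ground-truth input
function.

What the phantom does *not* emulate: scanner physics (scatter, randoms,
attenuation, reconstruction artifacts), subject motion (a major real-world
failure mode of carotid extraction), metabolite-analysis error, or
anatomical variability beyond the parameterized jitter. Passing tests on
the phantom therefore demonstrate algorithmic correctness and the stated
comparative behavior under these conditions, not clinical performance.

## Numerical choices and degenerate inputs

* Frame averaging uses exact trapezoid weights with edge interpolation,
  exposed as a linear operator and cached inside the kinetic model.
* `apply_dispersion` samples its kernel at midpoints so the discrete first
  moment matches the continuum to second order; kernels are normalized to
  unit sum, preserving AUC.
* PCA eigenvector signs are fixed (largest-magnitude entry positive) so
  whitening, and hence the whole ICA path, is bit-reproducible.
* Component sign ambiguity is resolved by making each component's global
  extremum positive; magnitude ambiguity is left to calibration.
* Zero-variance sources, empty masks, rank-deficient covariances, flat
  head curves, zero reference AUCs and non-finite inputs raise errors with
  stage-labelled messages in the pipeline.
* The 1.5-min repair sample is interpreted in whole-blood units; because
  repair runs before calibration, the pipeline passes a provisional scale
  so the replacement value is expressed in the still-uncalibrated curve's
  units.

## Problem sizes

Default analyses use the 48^3 phantom grid, ground-truth curves sampled at
0.1 s, kinetic-model convolution at 1 s, 12 simulated subjects in the
comparison study, 20 mixtures of 5000 voxels in the source-recovery
benchmark, and 50 replicates in the noisy kinetic-recovery check.
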