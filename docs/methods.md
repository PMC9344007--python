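# Methods

## Spectral model

A spectrum is a superposition of pseudo-Voigt bands on a smooth
fluorescence background, sampled on a uniform wavenumber axis
(default 550–1550 cm⁻¹ at 1 cm⁻¹, the working range of a confocal Raman
instrument). Each band is

    V(ν) = θ·α·exp[−4ln2·(ν−ω)²/γ²] + (1−θ)·α·γ²/((ν−ω)²+γ²)

with mixing coefficient θ ∈ [0,1], height α (a.u.), centre ω (cm⁻¹) and
width γ (cm⁻¹). The two terms deliberately use different width
conventions — γ is the FWHM of the Gaussian term but the HWHM of the
Lorentzian term — and the mixture is implemented in exactly this form
rather than normalised to a single convention; both terms peak at ν = ω,
so V(ω) = α for every θ. The stand-alone contours are kept in the same
convention: the Lorentzian `L(v) = (1/π)·γ_L²/((v−ω)²+γ_L²)` is not
unit-area normalised (its maximum is always 1/π, with γ_L the HWHM), and
the Gaussian `G(v) = (1/γ_G)·√(ln2/π)·exp[−((v−ω)/γ_G)²·ln2]` has γ_G as
its HWHM.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
standing in for instrument data that is not publicly deposited.

**Peak libraries.** Thiram: bands at 562, 929, 1146, 1379, 1514 cm⁻¹
(S–S stretch, C=S/C–N stretch, C–N stretch + CH₃ rock ×2, C–N stretch +
CH₃ deformation), θ = 0.7, γ = 10 cm⁻¹, relative heights 0.55 / 0.45 /
0.50 / 1.00 / 0.60. Only the 1379 cm⁻¹ dominance is constrained by the
analyte's known spectrum; the other relative heights are free parameters
chosen once to look like a realistic SERS trace. R6G probe: 1362 and
1510 cm⁻¹. Fruit epidermis: 750 cm⁻¹ (concentration-sensitive) plus fixed
matrix bands at 830, 1165, 1560 cm⁻¹.

**Concentration response.** Each library designates a quantitation band.
All concentration-sensitive bands are scaled jointly so that the clean
(noise- and baseline-free) intensity *at the quantitation centre* —
including overlap from neighbouring sensitive bands — equals
`slope·N + intercept` (defaults 11644 and 4536.5 a.u. per μg·mL⁻¹ for
thiram). Evaluating the constraint at the centre itself, not the nearest
grid point, makes the generator's peak-height linearity exact to machine
precision, which the round-trip tests exploit.

**Baseline.** A single decaying exponential plus constant offset:
amplitude 3000 a.u., decay constant 400 cm⁻¹, offset 200 a.u. Any smooth,
broad function would do; this one is easy to document and gives the
baseline-correction step realistic work at roughly peak-comparable
magnitude near the low-wavenumber edge.

**Noise.** Multiplicative Gaussian, SD = `noise_rsd` × clean intensity,
default 0.015 — matching the 1.4–1.6% replicate RSD regime of a
well-prepared Au-NP substrate. Optional additive dark noise (default 0).
All randomness flows through an explicit seed in the config; there is no
global state.

**What it does not emulate:** cosmic-ray spikes, wavenumber-axis
miscalibration or drift, detector saturation, heteroscedastic shot noise,
peak-shape changes with concentration, or matrix-dependent band shifts.
Tests passing on this generator demonstrate the correctness of the
algorithms under the stated noise model, not robustness to every artefact
of real instrument data.

`generate_nonlinear_study` produces a series whose quantitation response
follows `w·√N + (1−w)·N` (default w = 0.7) while the metadata records the
true N — a controlled sensor-saturation scenario used to demonstrate when
kernel features beat linear models.

## Preprocessing

Defaults: Savitzky–Golay smoothing, window 9, polyorder 3 (standard for
Raman; preserves peak height far better than a moving average — measured
attenuation of the default γ = 10 cm⁻¹ bands is under 1%). Baseline by
modified polynomial fitting (modpoly): degree 5, up to 50 iterations,
convergence when the relative change of the clipped signal drops below
1e−4; asymmetric least squares (λ = 1e5, p = 0.01, 10 iterations) as the
alternative. Derivatives are SG derivatives with respect to wavenumber
using the smoothing window, so differentiation never amplifies unsmoothed
noise; they require a uniform axis. Feature ranges are closed intervals
(default 653–683, 705–728, 847–872 cm⁻¹, fully configurable — quantitation
work around specific bands passes its own ranges). Edge handling is SG
polynomial extrapolation; exactness guarantees in the tests are asserted
on interior points.

## Max–min split

Seed step: the samples at minimum and maximum Euclidean distance from the
mean spectrum enter the calibration set. Iteration: each remaining
sample's minimum distance to the current calibration set is computed once
per iteration; the farthest sample is added, then the nearest (from the
same distance vector), one only if one slot remains. Ties break to the
lowest input index, so the split is fully deterministic, and every
selection is logged with its distance. Distance is Euclidean on whatever
feature representation is supplied (preprocessed spectra or extracted
ranges). Default calibration fraction 3:1.

## Kernel PCA

RBF kernel `k(x,y) = exp(−‖x−y‖²/2σ²)`; σ is in the units of
feature-space distances, i.e. raw intensity counts for unnormalised
spectra — that is the scale on which a sweep grid like
{1000, 5000, 8000, 10000} is meaningful. The Gram matrix is centered with
the elementwise correction (subtract row and column means, add the grand
mean), which equals H·K·H and is verified against that oracle. Full
symmetric eigendecomposition is used (sample counts are tens; no
iterative solver needed). Coefficient vectors are normalised so
λ_k·(α_k·α_k) = 1 (unit-norm feature-space eigenvectors); without this the
projection is ill-scaled. Components with λ ≤ 1e−12·λ_max are dropped.
Sign convention: each coefficient vector is flipped so its
largest-magnitude entry is positive, making scores reproducible across
runs and platforms. Out-of-sample rows are centered against the
*training* kernel statistics before projection, so transforming the
training matrix reproduces the training scores exactly. Explained
variance is λ_k over the sum of all non-negative eigenvalues. A
`kernel="linear"` mode exists to support the classical-PCA comparison and
the PCA-equivalence oracle in the tests.

`sigma_sweep` refits the whole KPCA + regression pipeline inside every
cross-validation fold (held-out samples are projected with the transform
equation), so the reported RMSECV is honest out-of-sample error. The
characteristic pattern on a non-linear concentration response: σ far
below the typical inter-sample distance makes the Gram matrix
near-diagonal (held-out points project to noise, RMSECV near the response
SD); σ far above it collapses KPCA to linear PCA (the linear-model bias
floor); intermediate σ gives a flexible basis and the lowest RMSECV.

## Regression and figures of merit

PLS is NIPALS PLS1 with column-centered X and y, deterministic, with
coefficients assembled as B = W(PᵀW)⁻¹q; with as many latent variables as
the rank of X its predictions coincide with OLS (tested). A constant
response yields zero coefficients rather than an error. MLR is OLS with
intercept, refusing rank-deficient or under-determined problems with a
pointer toward KPCA/PLS.

RMSECV = √[(1/n)·Σ(ŷ₍₋ᵢ₎ − yᵢ)²] with deterministic fold assignment:
contiguous blocks after sorting by y; leave-one-out by default (sample
counts in the tens make LOO cheap and unambiguous).

Calibration curve: OLS of peak intensity on concentration, r² the squared
Pearson correlation. LOD: the concentration whose calibration response
equals blank mean + 3·sample-SD (default) or 3·blank mean
(`rule="3s_only"`), floored at zero; the blank signal is the preprocessed
intensity at the quantitation wavenumber. RSD = 100·SD/mean (sample SD).

Peak detection: prominence-thresholded local maxima (threshold a fraction
of the intensity *range*, making detection invariant to constant
offsets), minimum separation in cm⁻¹, centres and heights refined by
3-point parabolic interpolation.

## Problem sizes and numerical choices

The simulation studies used throughout the tests and the reproduction
script are desk-scale by design: 20-sample calibration series, 24-sample
non-linear σ-sweep study (8 log-spaced concentrations × 3 replicates),
kernel matrices ≤ 24×24, LOO cross-validation throughout. Eigenvalue
cutoff 1e−12·λ_max; PLS stops extracting when the residual covariance
norm falls below 1e−14 of the data scale; modpoly convergence 1e−4
relative. Degenerate inputs (flat spectra, identical samples, constant
response) return the mathematically natural result (no peaks, index-order
tie-breaks, mean prediction) rather than erroring.

## Known limitations

* Recovered calibration slope carries a small systematic attenuation
  (≈1%: SG smoothing ≈0.8%, modpoly under the peak ≈0.5%) — inherent to
  any smoothing/baseline chain, and well inside the reported tolerances.
* The default ALS parameters under-recover sharp peak heights relative to
  modpoly on this generator (~3% attenuation); modpoly is therefore the
  default.
* KPCA + PLS predicts poorly outside the calibration concentration range
  (kernel methods do not extrapolate); the max–min split mitigates this
  by always placing the extreme samples in the calibration set.
* SVR and PLS2 (multi-analyte) are out of scope; the regression interface
  takes any `fit(X, y) -> predict` factory, so a kernel regressor can be
  added without touching the KPCA module.
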