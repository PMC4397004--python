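# Methods

This note records the models implemented, the conventions adopted where
the underlying formulations are ambiguous, the default parameters and why,
and what the synthetic data do and do not establish.

## Intensity normalization

Radiographs digitised from film carry a per-image exposure factor. Five
vertebral landmarks (C7, T1–T4) are measured as mean intensities over a
disk of radius 3 px (radius configurable; a disk rather than a single
pixel for noise robustness). Only T1–T4 enter the signature; C7 is
measured because it is routinely annotated.

With cohort means $\bar T_1 \dots \bar T_4$, image $i$'s signature is
$s_i = \tfrac14\sum_j T_{ji}/\bar T_j$ and the normalized image is
$I_n = I / s_i$. The cohort mean of the $s_i$ (the *central signature*,
CS) equals 1 by construction and is kept as a diagnostic. This convention
is the only reading of the signature idea under which division is
well-posed: defining per-landmark signatures as deviations
$T_{ji}/\bar T_j - 1$ instead would centre the statistic at zero and blow
up the division. Normalization is exactly invariant to a global
multiplicative factor on an image, because its landmarks scale with it.

Histogram equalization is global (not adaptive), with $2^{\text{bit
depth}}$ bins, mapping intensities through the cumulative histogram onto
the full bit-depth range; a constant image is returned unchanged since
its mapping is undefined. The pipeline order is: equalize → landmark
signature → divide → crop the 256×256 region of interest.

## Phase congruency

The model is the log-Gabor quadrature formulation described in the
README. Conventions that the formulation leaves open, and the choices
made:

- **Phase deviation.** $\Delta\Phi = \cos(\phi - \bar\phi) -
  |\sin(\phi - \bar\phi)|$, with the absolute value on the sine term so
  the measure is symmetric in the sign of the deviation (without it the
  measure is not a deviation penalty at all).
- **Mean phase.** Per orientation, $\bar\phi$ is the direction of the
  vector sum of the even/odd responses over scales; the per-channel
  products $A\,\Delta\Phi$ are evaluated through the quadrature identity
  $A\cos\Delta = e\,\bar e + o\,\bar o$, $A|\sin\Delta| = |e\,\bar o -
  o\,\bar e|$ on the unit mean-phase vector $(\bar e, \bar o)$.
- **Noise threshold.** $T_o = \mu_R + k\,\sigma_R$ with the Rayleigh
  scale estimated from the *median* of the smallest-scale amplitudes at
  orientation $o$: $\hat s = \mathrm{med}/\sqrt{2\ln 2}$, then
  $\mu_R = \hat s\sqrt{\pi/2}$, $\sigma_R = \hat s\sqrt{2-\pi/2}$. The
  median estimator is the standard robust choice for a Rayleigh noise
  floor under sparse signal. $k=0$ still thresholds at $\mu_R$
  (definitional); `noise_mode="none"` disables thresholding entirely.
- **Weights and floor.** The sigmoid weight
  $W_o = 1/(1+e^{\gamma(c-s)})$ uses the frequency spread
  $s = \tfrac1N \sum_n A_n / (\varepsilon + A_{\max})$ per orientation;
  the threshold is applied after weighting,
  $\max(0,\, W_o \sum_n A\,\Delta\Phi - T_o)$, per orientation.
- **Input standardization.** The image is shifted and scaled to zero
  mean, unit variance before filtering. PC is dimensionless, so this
  changes nothing about what the measure sees, but it makes PC *exactly*
  invariant to affine intensity changes $aI+b$ and gives $\varepsilon$
  (default $10^{-4}$) and the thresholds a fixed meaning relative to
  signal amplitude across images. A constant image maps to an all-zero
  PC map.
- **Boundaries.** `phase_congruency_map` mirrors the image to double
  size before the FFT (even symmetric extension) and crops back,
  suppressing the spurious wrap-around edge a periodic FFT would
  introduce; plain periodic behaviour is available via `extend="none"`.
  `channel_responses` itself is periodic (circular convolution), which
  is what its direct spatial-convolution oracle checks.
- **Filter grid.** Filters are built directly in the frequency domain on
  the `fftfreq` grid (DC at the corner, frequencies in cycles/pixel);
  the angular Gaussian covers a single half-plane so the complex inverse
  transform yields the even/odd quadrature pair. DC gain is exactly zero
  in every channel. With very few orientations (o ≤ 2) the angular
  Gaussian becomes wide enough to leak into the opposite half-plane and
  the quadrature interpretation degrades; the bank is meant for o ≥ 4.

Default parameters (tuned for 256² chest ROIs): n = 5, o = 6,
λ_min = 8 px, α = 3, σ = 0.55 (≈ 2 octaves), d = 1, γ = 50, c = 0.2,
k = 2. The PSNR optimum is flat between c = 0.2 and c = 0.3; both sets
are exported (`PCParams()` and `SELECTED_ALT`). The generic
natural-image start used by the tuner is n = 3, o = 6, λ_min = 3, α = 2,
σ = 0.55, d = 1.7, γ = 10, c = 0.4, k = 3.

One caveat on edge localization: on a finite image a single step edge
implies, after any symmetric/periodic extension, a square wave whose
plateau centres carry genuine higher-harmonic congruency. With the noise
threshold active (k = 2) or with the generic cut-off c = 0.4 the PC
maximum sits on the edge (±1 px); with thresholding off *and* the low
tuned cut-off c = 0.2 the plateau response can compete. This is a
property of the measure, not an artefact of the implementation.

## Gabor bank

Kernels follow the Gaussian-envelope cosine form with properly rotated
coordinates $x' = \Delta x\cos\Theta + \Delta y\sin\Theta$,
$y' = -\Delta x\sin\Theta + \Delta y\cos\Theta$ (a reflection variant
sometimes seen in print is not a rotation and does not preserve the
envelope). Defaults: two-octave bandwidth via
$\sigma^*/\lambda^* = \tfrac1\pi\sqrt{\ln 2/2}\,(2^b+1)/(2^b-1) = 0.3123$
at $b=2$, aspect ratio 0.5, phase offset $-\pi/2$ (odd-symmetric, zero
mean). Wavelengths replicate the PC bank's geometric sequence so both
banks have 30 matched channels.

Kernels are truncated at ±3σ* (odd size). At the two coarsest scales on
a 256² ROI that support exceeds the image; such kernels are truncated to
the largest odd size that fits so the full bank always runs
(`truncate_to_image=False` restores a hard error). Convolution is
cross-correlation with reflect padding — the integral form does not
define wrap-around, and reflection avoids it. Responses are rectified at
zero; the default texture input is the pixelwise sum of the 30 rectified
channels (per-channel maps remain available).

## Texture measures

Co-occurrence measures use min–max quantisation into 256 levels, offset
(0, 1), symmetric counting, matrix normalised to sum 1. Energy, entropy
(base 2), contrast, homogeneity and correlation follow the classical
definitions; correlation of a constant map is undefined and reported as
NaN. Because quantisation is min–max relative, all five are invariant to
affine rescaling of the map. Mean energy, STDV and the raw map energy
come from unquantised values; STDE is the SD of the 30 per-channel mean
energies when the channel stack is supplied (PC and Gabor both supply
it), else the SD of squared values. Absolute magnitudes of co-occurrence
measures depend on counting and quantisation conventions, so only their
discriminating behaviour — not any particular published magnitude — is a
meaningful comparison surface.

## Statistics and ROC

The KS statistic is evaluated at both one-sided steps of the empirical
CDF against a normal CDF with sample-estimated mean and SD (ddof 1).
The default critical value is $0.94/\sqrt n$ — chosen because it
reproduces the critical values conventionally quoted for this screen at
n = 20 and n = 25 (0.2101, 0.188) — and is deliberately conservative
relative to the Lilliefors α = 0.05 coefficient 0.886, which is also
available, as is the asymptotic two-sided coefficient 1.358.

Discrimination is univariate per texture measure. The LDF/QDF choice
follows a two-sided F-test at α = 0.05; the pooled variance uses
(n−1)-weights. Ties at the decision boundary ($Q = \ln C$) go to class 1
(the "≥" convention). The ROC sweep uses 201 uniform ln C values on
[−10, 10] by default — wide enough to saturate both curve ends for the
effect sizes arising here — with (0,0) and (1,1) appended and duplicate
points merged; AUC is trapezoidal. Scores are monotone in the feature
for the LDF, making the sweep a rank statistic (checked against
Mann–Whitney).

## PSNR tuning

The coordinate search sweeps parameters in the order n, o, λ_min,
(α, σ) jointly, d, γ, c, k, evaluating the mean PSNR between each image
(min–max rescaled to [0, 1]; a constant image is compared as-is) and its
PC map (already in [0, 1], so MAX = 1). The current value is always
among the candidates, so the search never degrades the objective; ties
break toward smaller parameter values. PSNR here is a relative
selection criterion — its absolute value depends entirely on the image
set supplied.

## Synthetic data

The phantom generator is parametric-geometric: only the signal structure
the pipeline relies on is modelled — edges between lung fields and soft
tissue, periodic rib ridges, a bright vertebral strip whose five landmark
blobs vary by a per-image lognormal factor (σ = 0.05, giving the ~5%
coefficient of variation typical of spine landmark intensities), and a
class-dependent opacity (compact 8th-order super-Gaussian nodule for LC;
Gaussian-smoothed lower-zone wedge for PNEU). Noise is additive Gaussian
(default SD 15 on the 12-bit scale). Per-image seeds derive from a master
seed; the three random streams (landmark factor, lesion variation, pixel
noise) are independent, so phantoms of different classes from the same
seed share an identical noise field. Defaults are 512² images with 256²
ROIs; the study driver also runs at 256² with 128² ROIs for desk-scale
turnaround. The default cohort composition is 40 NL / 50 LC / 50 PNEU
with a seeded half/half control/test split per class (20/25/25 each).

The feature-level simulator draws each measure from a univariate normal
per class, with default means/SDs at the magnitudes texture measures take
on clinical chest-radiograph response maps; near-degenerate spreads are
given a nominal 2×10⁻⁵ since the simulator requires positive SDs.

**What passing tests show — and don't.** The phantoms verify that the
pipeline is wired correctly end to end: normalization removes the
injected exposure factor, the maps respond to focal vs diffuse opacity,
measures are normally distributed enough to screen in, and the
discriminants separate classes whose opacities differ by construction.
The phantom classes are deliberately clean, so AUCs near 1.0 on them say
nothing about clinical discriminability; anatomy, projection physics and
scanner noise are all absent.

## Problem sizes and runtime choices

The shipped test suite and the acceptance script use 256² cohort images
(128² ROIs), 10 images per class, 20 random 128² images for the PC
range/invariance checks, 10⁵-sample simulations for the error-rate and
AUC closed-form checks, and a reduced tuner grid over two 64² ROIs.
These sizes keep a full run in the low minutes on one CPU while leaving
every check's statistical resolution well inside its tolerance.

## Known limitations

- Landmarks are supplied, not detected; automatic vertebra localisation
  is out of scope.
- The PC implementation covers the classical quadrature log-Gabor
  formulation only (no monogenic/Riesz variant, no 3-D).
- Gabor features use rectified single-phase responses, not quadrature
  energy.
- Univariate discriminants only; no multivariate combination or
  cross-validation.
- Published magnitude tables for co-occurrence measures are not
  reproducible without the original data and counting conventions; the
  package's comparisons are internally consistent instead.
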