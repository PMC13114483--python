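# Methods

`sfdibruise` implements a simulation-driven spatial frequency domain imaging
(SFDI) pipeline for detecting and grading subsurface fruit bruises. This
note records the models, the numerical choices behind them, and what the
synthetic experiments do and do not demonstrate.

## Optical forward model

A semi-infinite turbid medium under sinusoidal illumination at spatial
frequency `fx` (mm⁻¹) reflects a diffuse fraction

    Rd(fx) = 3A (μs′/μtr) / ((μeff′/μtr + 1)(μeff′/μtr + 3A))

with transport coefficient `μtr = μa + μs′`, effective attenuation
`μeff′ = sqrt(3 μa μtr + (2π fx)²)`, and boundary constant
`A = (1 − Reff) / (2(1 + Reff))` where
`Reff = 0.0636 n + 0.668 + 0.71/n − 1.44/n²`. The refractive index defaults
to `n = 1.43` (fruit tissue). A widely circulated variant of this formula
places the angular frequency `K = 2π fx` unsquared inside the root; that
form is dimensionally inconsistent, so the squared form is the default and
the variant is available behind the `mueff_dialect="printed"` flag. The two
coincide exactly at `fx = 0`.

Validity: the diffusion approximation assumes `μs′ ≫ μa` and breaks down
for strongly absorbing media; the inversion bounds (below) keep estimates
inside the regime the model was evaluated on.

## Analytic scene rendering

Rather than ray-tracing, raw acquisitions are rendered in closed form.
Each scene is a per-pixel coefficient map (apple: μa 0.0324, μs′ 1.726 mm⁻¹;
pear: 0.0418 / 2.102 mm⁻¹; bruised μs′ 1.215 / 1.702 mm⁻¹ at full severity,
interpolated linearly for partial severity). The bruise is a centered disc
(default radius 15 mm — a typical impact bruise); the sound-reference region
is the equal-area annulus around it. Pear scenes carry multiplicative
lognormal speckle on μs′ (sd 0.03) emulating lenticels.

Four frames are rendered per scene: one planar-illumination (DC) frame
`g·a0·Rd(0)` and three AC frames
`g·(a0·Rd(0) + a1·cos(2π fx x + ψ)·Rd(fx))` at phases 0, 2π/3, 4π/3, with
`a0 = a1 = 0.5`, gain 1, optional Gaussian read noise (default sd 0.005,
0.5 % of full scale) and clipping at zero. The field is 100 mm wide
regardless of pixel count (256² for production, 64² in the test suite).
Because the rendering and the inversion share the same forward model, the
ground truth is exact by construction — round trips therefore verify the
demodulation/calibration/inversion chain, not the realism of the scenes.
What the generator does not emulate: camera optics, wavelength dependence,
depth-resolved bruise structure, and specular peel reflections.

## Demodulation and calibration

The AC envelope is `M_AC = (2/3)·sqrt((I1−I2)² + (I2−I3)² + (I3−I1)²)`.
The 2/3 prefactor follows the applied SFDI convention (the textbook
derivation gives √2/3); the choice is immaterial because calibration against
a reference of known reflectivity (0.99) divides it out — asserted to
machine precision in the test suite. The DC channel is the planar frame
itself, calibrated the same way. Calibrated values above 1.05 are flagged
saturated; zero-reference pixels are flagged invalid, never divided.

## Inversion

Per pixel, `(μa, μs′)` minimizes the squared residual of the two-frequency
pair (0 and 0.2 mm⁻¹) under the forward model: trust-region bounded least
squares (scipy), init (0.05, 1.5), bounds μa ∈ [10⁻⁵, 0.5], μs′ ∈ [0.01, 4]
mm⁻¹ (the phantom design ranges), tolerances 10⁻¹⁰, ≤200 iterations.
Identical reflectance pairs are fitted once and cached, which makes
piecewise-constant synthetic scenes cheap. The LUT mode tabulates the
forward model on an 80×80 coefficient grid and inverts by scattered linear
interpolation in `(Rd_dc, Rd_ac)` space (nearest-neighbor fallback at the
hull); it agrees with the full fit to ≤1 % and is the default for cohort
experiments.

## Surface-profile correction

Fruit curvature produces a center-bright / edge-dark falloff. A four-step
fringe projection (phases 0, π/2, π, 3π/2) yields the wrapped phase
`atan2(F4−F2, F1−F3)`; unwrapping removes 2π jumps row-wise and reconciles
rows through the first column (adequate for smooth dome-shaped surfaces —
a quality-guided unwrapper would be needed for noisy or discontinuous
phase fields). Height is linear in the phase offset against a flat
reference scene processed identically, `h = k_height·Δφ`. The correction
coefficient is `c = h/max(h)` clamped to `[0.05, 1]` (clamped rim pixels
are flagged low-confidence), and corrected reflectance is `R/c`. The
synthetic curved scenes inject the distortion as multiplication by the same
`c`, so correction inverts it exactly; on real fruit `c = h/h_max` is a
heuristic flattening, not a Lambertian model, and is implemented as such.

## Coefficient prediction network

The image-to-coefficient translator is a conditional GAN: a residual U-Net
generator with a convolutional block attention module (CBAM: channel gate
from pooled statistics through a shared bottleneck MLP, then a spatial gate
from channel-wise mean/max maps, reduction 16, 7×7 spatial kernel) after
each down-sampling and before each up-sampling stage, and a three-layer
fully convolutional patch discriminator over the channel-concatenated
(input, candidate label) pair. The objective is `L_GAN + λ·L1` with λ = 60,
natural-log adversarial value, discriminator outputs clamped at 10⁻⁷.
Inputs are calibrated AC reflectance images normalized to [−1, 1]; labels
are 8-bit RGB encodings (R: μa over [0, 0.5]; G: μs′ over [0, 4]; B ≡ 0)
normalized to [0, 1] to match the sigmoid output head.

Three architecture choices matter on this data and deviate from stock
pix2pix:

1. **No normalization layers in the generator.** The scenes are nearly
   uniform images whose absolute intensity *is* the signal; per-sample
   normalization maps every constant input to zero and destroys the
   mapping. (With instance norm the trained network cannot beat an
   untrained one.)
2. **Attention gates initialized open** (positive gate-logit bias): with
   2·depth sequential sigmoid gates, a neutral init attenuates the forward
   signal by ≈0.5⁸.
3. **Outermost identity skip into the output head**, because the
   reflectance-to-coefficient map is largely pointwise.

Training uses Adam (β 0.5/0.999), batch 4, generator rate 10⁻³ decayed
linearly to zero, discriminator loss halved and rate scaled by 0.05. The
slow-discriminator regime reflects the λ = 60 objective: the task is
L1-dominated and a fast discriminator only injects gradient noise at short
schedules (the desk-scale schedule is 140 steps; conventions tuned for 10⁴+
steps do not transfer). The best-validation-L1 checkpoint is kept; both L1
and MSE validation curves are logged.

A single-channel input cannot fully separate absorption from scattering:
on the default sweep an ideal predictor still has NMAE(μs′) ≈ 0.12 from
this ambiguity alone. This matches the qualitative observation that μa is
predicted consistently worse than μs′, and is why discrimination relies on
μs′ only.

## Dataset generation

The default sweep crosses 20 absorption values (0.01–0.45 mm⁻¹), 10
reduced-scattering values (0.4–3.6 mm⁻¹) and 4 bruise severities (0, ⅓, ⅔,
1) — 800 paired samples, shuffled deterministically and split 7:3 into 560
training / 240 validation. Inputs are float-TIFF calibrated reflectance
images, labels RGB PNG, ground truth two-page float TIFF, plus a JSON
manifest. Generation is bit-reproducible under a fixed seed.

## Discrimination statistics

Step 1 (bruised vs not): the coefficient of variation (population sd over
mean) of the whole μs′ map — bruising makes the map heterogeneous. Step 2
(mild vs severe, on samples called bruised): the mean ratio
`M = mean(μs′ bruise disc) / mean(μs′ adjacent sound annulus)` — severe
bruising collapses μs′ and drives M down. Thresholds are chosen by
maximizing the Youden index (sensitivity + specificity − 1) along an ROC
sweep over the observed scores; the trapezoid AUC is exactly the
concordance (Mann–Whitney) statistic with ties credited ½, which the tests
assert against brute-force pair counting. Classification boundaries are
strict (`CV > t` ⇒ bruised, `M < t` ⇒ severe); since the ROC operating rule
is inclusive, the pipeline converts the selected score into a strict cut at
the midpoint toward the neighboring score. Population (not sample) sd is
used in the CV; the choice is a documented convention and trivially
switchable.

Cohort experiments draw per-fruit biological variability (2 % sd on base
μs′, 5 % on μa) and render with read noise; at the default conditions
(20 + 20 apples, severity 1, 64², LUT inversion) the CV classes are
separated by roughly a factor two and step-1 accuracy is 100 %. This shows
the chain is self-consistent end to end, not that real fruit achieve the
same separation: real cohorts add peel texture, bruise-depth variation and
calibration drift that the generator does not model.

## Evaluation metrics

NMAE `Σ|p−r| / Σr`; PSNR `10·log₁₀(255²/MSE)` on maps rescaled to 0–255
through the label ranges (identical maps report +∞); SSIM with global image
statistics and constants `(0.01·255)², (0.03·255)²` (an 11×11
Gaussian-windowed variant is available). Model comparisons use a two-tailed
paired Student's t-test on per-image errors with significance bands at
0.05/0.01/0.001; zero-variance differences are reported as degenerate
rather than tested.

## Problem sizes

Production scale is 256² with a depth-6 generator. The test suite and the
acceptance script run at 64² with a depth-4, base-16-channel generator and
a 40-pair, 20-epoch training smoke run — small enough to execute on one CPU
core in minutes while exercising every stage at full fidelity.
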