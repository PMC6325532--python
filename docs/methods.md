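# Methods

This note records the models behind `lightstripe`, the parameter choices
baked into its defaults, and the limitations of both.

## Beam model and wave-optics oracle

Closed-form relations (all lengths in µm, angles in radians):

- axicon cone half-angle: Θ = (n − 1)·α, valid for n > 1 and small α;
- Bessel depth of focus: δZ = d/Θ, with d the radius of the illuminated
  annulus at the axicon;
- Bessel core radius (first zero of J₀): r_c = 2.405·λ/(2π·sinΘ);
- Gaussian width: w(z) = w₀·√(1 + (z/z_R)²), z_R = π·w₀²/λ;
- shadow reconstruction distance behind an obstacle of radius r: r/tanΘ.

The reference oracle (`beams.propagate_field`) is a scalar angular-spectrum
propagator: FFT of the field, multiplication by the exact nonparaxial
transfer function exp(i·z·√(k² − k_x² − k_y²)), inverse FFT. Evanescent
components are truncated. A sampling guard rejects fields whose spectral
energy within 10% of the Nyquist band exceeds 1% of the total, because such
fields alias under the periodic boundary conditions of the FFT. The oracle
is validated against closed forms (plane-wave invariance, power
conservation, Gaussian divergence within 1%, axicon first zero within 5%)
and then used as the ground truth for shadow behavior.

## Synthetic generator

The generator emulates the *geometry and photometry* of stripe formation,
not wave optics per pixel.

**Phantom.** An ellipsoidal "brain" mask (semi-axes 0.9/0.85/0.9 of the
half-extents) on a background of 0.2 relative intensity, filled with bright
curved vessels (random walks of radius 3–10 µm) and/or Gaussian somata
(σ = 5–12 µm), amplitudes 0.6–1.4. The background is high enough that
shadows darken visible tissue rather than empty space, as in autofluorescent
cleared-tissue volumes.

**Obstacles and shadows.** Opaque discs sit at the mask surface on the
illuminated side(s). Under Gaussian illumination an obstacle's shadow is
semi-infinite: every pixel behind it in the propagation direction is
attenuated by the disc transmittance. Under Bessel illumination the shadow
recovers linearly from full depth to zero over
`HEAL_SCALE × r/tanΘ` (`HEAL_SCALE = 1.5`). The factor 1.5 was calibrated
against the angular-spectrum oracle before the acceptance thresholds were
frozen: the core-averaged on-axis intensity behind absorbing discs of 8 and
18 µm completes its recovery near 1.5·r/tanΘ, and a ramp ending at
1.0·r/tanΘ disagreed with the oracle's band-integrated shadow depth by more
than 20% for the larger disc.

**Bidirectional illumination.** Real instruments often illuminate from both
sides and fuse at the sample midline; the generator composites
left-illuminated and right-illuminated fields at the mask centroid column.

**Haze and noise.** The Bessel channel adds a haze term (default 10% of
local intensity, Gaussian-blurred at σ = 50 µm) emulating the energy carried
by the ring system; both channels get Poisson shot noise at gain 50 counts
per intensity unit plus Gaussian read noise (σ = 2 counts).

**Ground truth.** The truth mask marks pixels whose Gaussian attenuation
falls below 0.95 within the brain mask, i.e. the truth is defined by the
*shadow field*, not by the noisy rendered image. `gaussian_shadow_fraction`
is the percentage of brain pixels so marked; it is the quantity the Fourier
estimator is scored against. `obstacles_for_stripe_fraction` searches for an
obstacle set whose shadow fraction hits a requested target, so study
conditions are stated in terms of ground truth, not estimator output.

**Not emulated:** diffraction ringing around shadow edges, depth-dependent
defocus of the sheet, scattering haze under Gaussian illumination,
wavelength dependence, refraction at the tissue boundary.

## Fourier stripe estimator

The estimator follows the standard directional-filtering approach to
destriping:

1. **Downsample** to a 10.4 µm analysis pitch by block averaging (exact
   mean over blocks). Fine-pixel renders carry per-pixel shot noise that is
   isotropic; averaging suppresses it while stripes, being coherent along
   the illumination axis, survive.
2. **Isolate stripes** with a wedge mask in the 2D FFT: all energy within
   ±5° of the frequency axis perpendicular to the stripes, excluding a DC
   disk of radius 3 cycles. The wedge edge rolls off over 2 cycles with a
   raised cosine, *inward* — the fully passed core is the wedge eroded by
   the roll-off width. Rolling outward would capture low-frequency on-axis
   content (the specimen's own smooth intensity profile) and multiply the
   false-positive rate several-fold. The stripe and destriped components
   sum exactly to the input.
3. **Binarize** the stripe component at `level × median(|brain intensity|)`
   (default 0.1), keeping only *negative* excursions: stripes are shadows,
   so dark-side thresholding rejects half the symmetric noise.
4. **Striped fraction** = flagged brain pixels / brain pixels, in percent.
   The same filter rotated 90° gives the perpendicular control; real
   stripes are parallel to the illumination, so the control estimates the
   false-positive floor of everything else in the pipeline.
5. **Volume summary**: per-slice fractions are histogrammed and fitted with
   a Gaussian; the fitted peak and SD summarize a whole volume.

For bidirectionally illuminated images the slice is split at the brain-mask
centroid column and each half is analyzed with its own illumination
direction.

**Known limitation (documented false-positive floor).** Bright structures
produce dark ringing flanks in the stripe-filtered component; on
obstacle-free study-size scenes (1024 × 1280 at 2.6 µm) this flags about
2.5–3.5% of brain pixels in the parallel direction (the flagged pixels sit
~5 px from bright structures versus ~16 px for matched background). The
floor is well below the smallest study condition (5%) and is bounded in the
test suite at < 5% parallel / < 1% perpendicular.

## Profile bar-code metric

For a region of interest, each image is reduced to a column-mean profile
(mean over mask rows per column). Profiles are normalized by their 75th
percentile — robust to the stripe-darkened lower tail — and the absolute
difference between the Gaussian and Bessel profiles is thresholded; the
metric is the percentage of columns above threshold ("bar code"). A
threshold sweep is monotone nonincreasing by construction. Optional integer
-shift registration aligns the profiles by maximizing cross-correlation.
Per-slice percentages aggregate to a slab summary (mean ± SD, ddof = 1).

Column profiles average over rows, so one affected row flags the whole
column: the metric reads as "fraction of illumination lines affected", an
upper bound on the areal fraction and deliberately more sensitive than it.
Multi-plane mean projections are used for null comparisons to keep the
single-pixel noise floor low.

## Colocalization chain

Bessel→Gaussian registration (rigid by default: coarse 1° search over ±3°,
then 0.1° refinement, scored by normalized cross-correlation on a central
window; translation via phase correlation with Hann windowing and spectral
normalization disabled, which is more reliable on smooth images), gamma
correction (default γ = 1.1; rescale to [0,1], power, rescale back),
IsoData thresholding (256-bin histogram fixed point; per stack by default,
per slice via flag), then Manders coefficients per slice in both
directions. "Non-zero intensity" is interpreted as "above the IsoData
threshold": stacks are thresholded to zero below threshold, and Manders
sums run over the other channel's non-zero support, so a channel compared
with a copy of itself yields exactly 1. Pixels carried out of frame by
registration become NaN and are excluded from all sums (zero-filling would
bias the coefficients). Slices where either channel segments to an empty
mask are skipped and reported. Means ± SEM over slices and a two-sided
paired t test between the two directions complete the summary.

## Numerical choices

- All module-level randomness uses `numpy.random.default_rng` with explicit
  seeds; independent stages get independent streams via seed sequences, and
  derived seeds stay below 2³¹.
- Registration resampling is bilinear; sub-pixel shifts are estimated by
  upsampled phase correlation (factor 10).
- CSV output fixes floats at six decimals; JSON is sorted and indented;
  no timestamps appear in any output, making runs byte-comparable.
- TIFF stacks store the pixel size in the resolution tags as an exact
  rational (pixels per centimeter) and round-trip it to ~1 part in 10⁶.

## Limitations

- The synthetic shadow model is ray-geometric with an oracle-calibrated
  linear recovery; it reproduces shadow extents and depths, not diffraction
  texture.
- The slab profile metric is a property of a rendered scene (obstacle
  placement relative to the region of interest), so scene-to-scene spread
  of a few percentage points is expected and the study conditions quote
  mean ± SD across seeds.
- The Fourier estimator's false-positive floor (above) caps its usefulness
  below ~3% true striped fraction.
- The wave-optics oracle is scalar and paraxial-sampled; it is used for
  on-axis and band-integrated comparisons, not for polarization or
  high-NA vectorial effects.
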