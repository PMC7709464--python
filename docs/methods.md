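# Methods

## Measurement model

A transmission measurement of an egg in seawater compares, per wavelength,
the light reaching the sensor through the specimen (I) with the light
through the adjacent background (I₀):

    τ(λ) = I(λ) / I₀(λ)                      (transmittance, dimensionless)
    bio-transparency = mean over 400–760 nm of 100·τ(λ)      (percent)
    μ(λ) = −(1/x) · ln τ(λ)                  (attenuation coefficient, µm⁻¹)

with x the egg thickness, taken as the equivalent-circle diameter of the
segmented region. The visible band is [400, 760] nm inclusive on the
default 380–1000 nm / 5 nm grid, i.e. 73 of 125 bands. Everything the
light loses — absorption, scattering out of the aperture, surface
reflection — lands in μ; a transmission measurement cannot separate them,
and the package does not pretend to.

Assumptions: collimated, spatially uniform illumination (a per-cube
background spectrum, estimated as the per-band **median** over background
pixels, stands in for I₀ at every egg pixel); a homogeneous egg interior;
no refractive lensing. τ is deliberately **not clipped at 1** — clipping
would bias bio-transparency upward under noise — values above 1.05 are
QC-flagged instead. Bands with τ ≤ 0 yield no finite log-loss and are
masked (not floored: flooring would fabricate μ).

## Pipeline

1. **Segmentation** — average the cube over a reference band (default:
   the visible band, where eggs are darkest against seawater), threshold,
   fill holes, remove small objects, 4-connected components, reject
   border-touching or non-circular (< 0.6) components, sort by centroid.
   The default threshold is *relative*: pixels below 0.99 × the frame
   median. Otsu is available but is a poor default here: for a nearly
   transparent egg it lands inside the egg's own τ range and cuts off the
   bright rim, shrinking both the measured diameter and the transparency.
   With band-averaged noise at the modeled levels, a 1%-below-background
   threshold keeps the rim reliably. Centroids are rounded to whole
   pixels in the sort key so same-row eggs cannot swap order under noise.
2. **Background** — pixels farther than a 10-px guard margin (binary
   dilation) from every egg; per-band median → I₀(λ).
3. **Transmittance** — per egg, the mean over mask pixels of per-pixel
   ratios (identical to ratio-of-means for a band-constant I₀, but ready
   for per-pixel flat fields). An optional central-disk ROI
   (`roi_fraction`) supports sensitivity analysis against the rim.
4. **Statistics** — bio-transparency; μ per band, averaged over the
   visible band (per-λ first, preserving the Beer–Lambert relation
   band-wise; the log-of-band-mean alternative is behind
   `mu_from_band_mean` and is smaller by Jensen's inequality).
5. **Aggregation** — individuals: mean ± sample SD (n−1; SD 0, flagged,
   for single-egg individuals). Species: both the population variance and
   the range of individual mean bio-transparencies are reported — the
   "spread across individuals" of a species admits either reading, so the
   user picks.

## Synthetic phantoms and what they do (not) show

The generator renders spheres of radius r with total attenuation
μ(λ) = baseline + Σ Gaussian pigment bands, surface reflection loss R
(wavelength-independent), on a bright background with optional linear
illumination gradient and additive Gaussian sensor noise truncated at
zero (SNR ≡ background / noise SD). A ray at radial offset ρ crosses a
chord ℓ(ρ) = 2√(r²−ρ²), so the projected disk's area-averaged
transmittance has the closed form quoted in the README; ground truth is
always this analytic value, never a measurement of the rendered image,
which keeps oracle tests non-circular.

Default study conditions mirror the reported ranges: 380–1000 nm at 5-nm
steps, egg diameters 120–381 µm at 2.5 µm/pixel, bio-transparency
10–90% (the `bt_sweep` preset root-solves the baseline μ per target),
background 1000 counts, SNR 30 (SNR 20 for the size sweep), zero
gradient. Noise level and illumination uniformity are stated assumptions,
not reported instrument values.

Real data differ in ways the phantoms do not model: inhomogeneous yolk
and cortical pigment, chorion/follicle-cell layers, refraction at the
egg surface, shot noise, focus gradients and touching eggs. Passing the
recovery tests therefore validates the *computation* — segmentation
geometry, ratio estimation, the statistics and their inversion — not the
instrument model of any particular camera.

## Numerical choices

* The disk-transmittance closed form is evaluated by a 3-term series for
  2μr < 1e−4 to avoid catastrophic cancellation; it matches quadrature of
  the chord integral to < 1e−8 relative over μr ∈ [0, 5].
* `solve_baseline_mu` brackets and bisects (Brent) to machine tolerance.
* Local minima: centred moving average (default 3 bands), then
  `scipy.signal.find_peaks` on −τ with prominence ≥ 0.02 — prominence on
  the inverted signal equals the drop below the lower flanking maximum.
* Equivalent diameter = 2·pixel·√(area/π); masks are whole-pixel sets,
  no subpixel membership. Circularity 4π·area/perimeter² is clipped at 1
  (digital perimeters of small disks can exceed the ideal).
* Degenerate inputs fail loudly: nonpositive background bands, uneven
  wavelength spacing, all-τ≤0 spectra, eggs+margins covering the frame,
  zero tree-tip matches. Constant frames segment to zero eggs, which is a
  result, not an error.

## Slab-vs-sphere bias

The statistic divides the whole-egg log-loss by the full diameter while
most chords are shorter than 2r, so pipeline μ systematically
*underestimates* the generator's μ; the relative bias grows monotonically
with μr (a property test asserts both sign and growth). The statistic is
kept as defined — it is the field's definition — and the simulator is the
tool to quantify the bias where it matters.

## Known limitations

* No watershed splitting of touching eggs; touching eggs merge or fail
  circularity and are dropped.
* The relative threshold assumes background-dominated frames (median ≈
  background); fields crowded with eggs need `threshold_mode="otsu"` or a
  tuned `min_area_px`.
* Strong illumination gradients (≫ 1%) defeat the relative threshold and
  bias τ near the frame edges; no flat-field correction is applied.
* Tree annotation joins labels exactly (after alias mapping and
  underscore/space normalization); there is deliberately no fuzzy match.
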