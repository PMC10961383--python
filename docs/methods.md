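# Methods

## Specimen and scene model

Cells are modelled as spherical caps on a flat substrate: a cap of base
radius `a` and apex height `h` sits on a sphere of radius
`R = (a² + h²) / (2h)`, with thickness profile
`t(r) = sqrt(R² − r²) − (R − h)` and closed-form volume
`V = π h (3a² + h²) / 6`. Caps are placed by rejection sampling without
footprint overlap (an explicit error is raised when a field is too crowded
to place the requested count). Defaults: field 384×384 px at 0.26 µm/px
(20× magnification of a 5.2 µm camera pixel), 25 cells, base radius
3–5 µm, apex height 2–4 µm, refractive indices 1.385 (cell) / 1.335
(medium), so Δn = 0.05.

An optional porous-membrane background adds a square lattice of circular
phase wells (diameter 0.4 µm, pitch 4 µm, depth 1 rad) for insert-style
scenes.

Treatments scale each cell vertically by `1 − s_i` with
`s_i ~ N(μ, σ)` truncated to `[0, 1)`; the rendered profile is the cap
profile times the scale, so the per-cell volume decrease equals `s_i`
exactly. Encoded presets (mean shrink, dispersion): si-EV (0.07406,
0.0126), fol-si-EV (0.1462, 0.0216), DOX-EV (0.2725, 0.04026), fol-DOX-EV
(0.4854, 0.1140). The dispersions are the reported standard errors
expressed as fractions, which also keeps the truncation bias negligible
(every preset mean sits ≥ 4σ from both bounds).

Uptake is a two-component mixture of log10-normal fluorescence
intensities: negatives at `log10 I ~ N(1.0, 0.2)`, positives at
`N(2.5, 0.25)` — well separated, as for a bright membrane label. Encoded
positive fractions: si-EV 0.2959, fol-si-EV 0.7894, DOX-EV 0.8779,
fol-DOX-EV 0.9881.

## Forward optics

The object is a pure phase screen, `O = exp(iφ)`; imaging is modelled at
the conjugate plane with optional defocus applied by angular-spectrum
propagation:

```
H(fx, fy) = exp( i 2π dz sqrt( (n/λ)² − fx² − fy² ) )
```

with evanescent components zeroed (or exponentially decayed, selectable)
and an aliasing guard on the grid. The reference is a tilted plane wave at
the carrier (default (0.25, 0.25) cycles/px, diagonal so both ±1 orders
clear the DC term). The detector applies Poisson shot noise at a
configurable photon scale, Gaussian read noise, and quantization to the
configured bit depth (default 8).

Two exposure conventions are provided. `normalization="mean"` (default)
maps the mean intensity to half full scale, as an auto-exposed camera
would; strongly defocused cap scenes then clip on lens-like caustics, and
the clipped fraction is logged on the frame. `normalization="max"` maps
the maximum to full scale (no clipping) and is the appropriate setting for
refocusing studies, where caustic clipping would otherwise corrupt the
focus metric.

## Reconstruction

1. **Sideband demodulation.** The +1 order is located as the strongest
   half-plane spectral peak, windowed with a circular mask of radius
   `min(factor · |carrier distance|, NA/λ)` (factor 0.5 by default),
   recentred, and inverse transformed. The demodulated term is `O* R`, so
   the field is conjugated once to restore `O R*`.
2. **Reference correction.** Among candidate empty-field frames the one
   minimising the background circular roughness of the phase difference
   `arg(O R*)` is selected and divided out.
3. **Autofocus (optional).** Amplitude variance `var(|U|)/mean(|U|)²` is
   minimised over a propagation grid with parabolic refinement; pure phase
   objects are flattest at focus.
4. **Filtering.** A 3×3 circular median (median of cos and sin, then the
   argument) respects the ±π seam that defeats a real-valued median.
5. **Unwrapping.** Reliability-sorted region growing
   (`skimage.restoration.unwrap_phase`); the result is anchored by
   subtracting `2π · round(median/2π)`, preserving the mod-2π relation to
   the wrapped input while fixing the free 2πk constant.
6. **Background plane.** A least-squares plane is fitted with iterated
   sigma clipping (centre = median, σ = 1.4826·MAD, 3σ inliers, 5
   iterations) so cell pixels and rims cannot bias the zero level — a
   direct requirement for unbiased volume integrals.
7. **Height conversion.** `h = φ λ / (2π Δn)`.

A QC report carries the detected carrier, chosen reference, residue count
(2×2 loop sums of wrapped gradients), focus search curve, and clipping.

## Morphometry

Detection thresholds the height map at `max(Otsu, 0.3 µm)`; markers are
plateau-safe local maxima of the Gaussian-smoothed map (σ = 2 px);
watershed on the negated smoothed map splits touching cells down to a low
support level (0.1 µm); regions smaller than 5 µm² or never reaching the
detection threshold are pruned. Volumes integrate `Σ h · ΔA` over each
cell's **full watershed basin** rather than its thresholded footprint:
band-limited imaging redistributes phase into sub-threshold rims and
ringing lobes but preserves the integral, and noise is zero-mean over a
basin, whereas a hard cut at height `t` loses `∝ (t/h_max)²` of a cap and
would bias tall-versus-shrunken comparisons. On textured backgrounds
(membrane fields) footprint integration is available instead. Pores are
detected on cell-free fields as sub-background depressions, sized by their
half-depth (FWHM) footprint on the raw map so that detection smoothing
does not inflate diameters.

## Statistics

Per-field percent volume decrease is `100 (1 − V_post/V_pre)` on total
segmented volume of paired renderings; conditions are summarised as
mean ± sd over fields and contrasted with Welch's unequal-variance t-test.
Uptake gates treated events at the 99th percentile of the control
intensities; by construction the gate admits ~1 % of negatives, so gated
percentages carry a `+0.01·(1−p)` leakage, which the acceptance tolerance
accounts for explicitly.

For closed-loop recovery studies the per-cell shrink deviates can be drawn
in **antithetic pairs** (`s = μ ± σz` for the same z), which makes the
realized mean shrink equal the generating value exactly and removes the
generator's own Monte-Carlo draw from the comparison — the recovery error
then measures the imaging pipeline alone.

## Numerical choices and limits

- **Seeds.** All experiment-level randomness flows through
  `numpy.random.SeedSequence` spawning; derived integer seeds are reduced
  mod 2³¹.
- **End-to-end fidelity.** For scenes inside the imaging passband the
  reconstruction is exact to < 0.01 µm RMSE (quantization-limited).
  Spherical caps have a slope discontinuity at the rim, so their
  reconstruction carries an irreducible band-limit residual (~0.016 µm at
  the default window; plateauing at ~0.010 µm with the window opened to
  the full NA disc) — physics, not pipeline error.
- **Problem sizes.** Tests and examples use 192–256 px fields with ~10
  cells so a full field pair reconstructs in under a second; defaults for
  library use are larger (384 px, 25 cells). These sizes are the package's
  own choice for tractable closed-loop statistics.
- **Realism limits.** The generator omits coherent speckle, spatially
  varying illumination, reference wavefront curvature, cell internal
  structure, sub-pixel membrane texture under cells, and focus drift;
  cells never overlap, so segmentation difficulty is bounded. Absolute
  agreements should be read as validation of the analysis chain, not as
  claims about any particular instrument.
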