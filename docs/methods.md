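# Methods

## Pipeline model

`epidstitch` treats a multi-isocenter VMAT craniospinal plan as an ordered
list of isocenters (superior → inferior) connected by purely longitudinal
couch shifts. Each isocenter delivers several arcs whose portal-dose
fluences add pixelwise; each adjacent pair overlaps by the field height
minus the couch shift, and inside that overlap the optimizer's
auto-feathering ramps the two isocenters' fluences complementarily. The
pipeline is:

1. **Read** per-field DICOM RT Images; pixels are rescaled to calibration
   units (CU) via RescaleSlope/Intercept; negative rescaled pixels are
   clipped to zero and counted.
2. **Sum** all fields of an isocenter into one matrix (fixed superior →
   inferior, given-order summation for bit reproducibility).
3. **Back-project** imager-plane geometry to the isocenter plane: spacing
   scales by `target/current` by similar triangles; pixel values are left
   untouched because the downstream comparison is relative and thresholded,
   so an inverse-square rescale of both composites would cancel. An
   explicit `scale_values=True` option applies `(current/target)²` for
   users who want fluence-at-plane semantics.
4. **Align grids**: measured per-isocenter maps are resampled (bilinear)
   onto the calculated map's spacing and centre-padded/cropped to its
   shape. This absorbs the vendor behaviours where measured images are
   cropped or recorded in a non-1:1 aspect ratio.
5. **Layout**: couch shifts (cm) become integer row offsets
   `round(Σ Δz / s)` (ties to even); overlaps are reported in cm and
   pixels together with the sub-pixel residual
   `|Δz/s − round(Δz/s)|·s`, because the cm → pixel interpolation is a
   genuine positional uncertainty of the method. Overlap extents use the
   full image extent of the summed per-isocenter map; every report states
   this.
6. **Stitch**: maps are *added* at their offsets. Accumulation (not
   overwrite) is the physically meaningful treatment of the overlap — the
   junction dose is jointly delivered by both isocenters and the sum of
   the feathering ramps is precisely the quantity under test. An
   `overwrite` mode exists for reproduction studies. Conservation is
   exact: Σ composite = Σ inputs.
7. **Compare**: 2-D gamma analysis of the measured against the calculated
   composite (reference = calculated), and superior–inferior profiles.

## Gamma engine

Per reference pixel above threshold, γ is minimized over evaluated sample
positions on a regular lattice of step `interp_step_fraction · DTA`
(default DTA/10, the usual fine-interpolation guidance) inside a disc of
radius `search_radius_factor · DTA` (default 3 — doubling it changes no
value on our fixtures by more than 1e-6). Samples are bilinear
interpolations of the evaluated image; lattice points outside the image are
skipped. The engine visits offsets in increasing-distance order, evaluates
each offset for the whole image at once (the constant fractional offset
makes bilinear interpolation a separable four-term gather), and stops when
the pure distance term exceeds the worst running minimum; the result is
exactly the exhaustive minimum, which the test suite verifies against an
independent nested-loop brute-force implementation on 100 random pairs.

Numerical choices:

- The low-dose threshold always refers to the **global** reference
  maximum, in both global and local normalization modes; only the
  dose-difference denominator changes with the mode.
- A pixel passes when γ ≤ 1 + 1e-9; the guard absorbs floating-point
  round-off when a dose difference sits exactly at tolerance (e.g. a
  uniform 3 % offset under a 3 % criterion must pass at the boundary).
- Excluded (below-threshold) pixels are NaN in the gamma map and never
  enter the pass rate.
- The engine contains no randomness.

Monotonicity caveat: loosening the dose tolerance never decreases the pass
rate (pointwise domination). Loosening the DTA is strictly monotone only
when both analyses share a sampling lattice; with the step tied to the DTA
(the default), individual noise-dominated pixels can reorder, although on
realistic smooth fields the expected ordering (3 %/2 mm ≤ 3 %/3 mm) holds —
the suite checks it across ten noisy phantoms. Raising the low-dose
threshold is *not* asserted to be monotone: excluding easy-passing
low-dose pixels can lower the pass rate; this is a property of the
definition, not of the implementation.

## Profiles

The superior–inferior profile is taken at the lateral centre of mass of the
above-threshold region (craniospinal targets are laterally centred, but
"the middle of the target" deserves a definition that survives asymmetric
modulation), with a plain image-centre fallback and an optional ±k-column
band average. Comparison metrics are max |Δ|, RMS, per-junction-band
maxima (bands from the stitch layout, widened by 3 mm), and a body-region
maximum. The body region is the in-field part of the reference profile
(≥ 50 % of maximum) minus the junction bands and minus the outer 10 % of
the in-field extent at each end — the central-80 % convention of field
flatness analysis. The penumbra is excluded deliberately: a longitudinal
setup error translates the outer field edge, producing a large but
uninformative edge difference that would mask the junction signal the
comparison exists to isolate.

## Synthetic phantom generator

The generator emulates the delivered structure of a clinical multi-isocenter
plan: rectangular fields up to the 28 × 28 cm² platform cap, two arcs per
isocenter (equal split), 3–4 isocenters with longitudinal shifts chosen so
overlaps land in the 5–8 cm regime (defaults: 3 isocenters, 28 cm fields,
21 cm shifts → 7 cm overlaps), imager grids of 0.336 mm at SID 1540 mm,
linear (or cosine) complementary feathering ramps, a smooth multiplicative
modulation texture standing in for MLC modulation (Gaussian random field,
±20 % around unity, 2 cm correlation length, shared between calculated and
measured so it cancels in gamma), multiplicative Gaussian measurement noise
floored at zero (EPID noise scales with signal; default σ = 1 % of local
value), and injectable errors: a continuous (bilinearly interpolated, not
whole-pixel) longitudinal translation of one isocenter's measured fields —
sub-pixel realism at ~0.2 mm isocenter-plane spacing — or a per-isocenter
dose scaling.

The feathering ramps are constructed on the same integer canvas the
stitcher derives from the couch shifts, so complementary weights sum to
exactly 1 per pixel and the noiseless composite equals the modulation
texture (uniform 1 CU with modulation off). Field heights quantize to whole
pixels, so a "28 cm" field is 1283 px × 0.336 mm ≈ 27.99 cm and the nominal
8 cm overlap reports as 7.99 cm; tests allow this half-pixel.

All randomness flows from one `numpy` Generator seeded by the scenario
seed; identical scenario + seed reproduce every field bit for bit, and the
DICOM writer derives its UIDs from content hashes (no timestamps), so
written fixture trees are byte-identical across runs.

What the phantom does *not* emulate — and hence what passing tests do not
show about clinical data: MLC leaf sequences and arc delivery dynamics,
EPID energy response and scatter kernels, off-axis beam-profile shape,
couch/beam sag, and the vendor's portal-dose prediction algorithms. The
phantom validates the stitching arithmetic, the gamma engine and the
error-localization logic, not the dosimetric calibration chain.

## DICOM dialect

Reading requires Modality RTIMAGE, PixelData, ImagePlanePixelSpacing
(3002,0011) and RTImageSID (3002,0026); RescaleSlope/Intercept default to
1/0. When orientation metadata is absent, rows are assumed superior →
inferior top → bottom (a CLI flag flips the composite). Writing stores
32-bit unsigned integers with RescaleSlope = max(CU)/(2³² − 1) rounded to
10 significant decimal digits so the DS string re-parses to the identical
float; read-back error is therefore at most half a quantization step
(≈ 1.2e-10 of the maximum — negligible against a 3 % dose tolerance), which
is the information-theoretic floor for integer storage. Files are verified
to parse with an independent GDCM-based reader.

## Problem sizes

The default test phantom is a compact two-isocenter scenario (12 cm fields,
6 cm overlap, 1.4 mm imager grid → ~200 × 90 composite), chosen so the full
suite exercises every pipeline stage in seconds while keeping the junction
geometry in the clinical overlap regime. The acceptance script runs the
clinical-regime geometry (three isocenters, 28 cm fields, 0.336 mm grid)
with an 8 cm field width, a composite of ~3200 × 370 pixels at the
isocenter plane.

## Known limitations

- Only translational superior–inferior inter-isocenter shifts are modelled;
  no lateral/vertical shifts, rotations, or divergence-aware junction
  geometry (junctions are treated as parallel-ray overlaps).
- Gamma is 2-D on the fluence plane; no 3-D dose reconstruction.
- Clinical pass rates depend on the vendor's (undocumented) normalization
  and interpolation internals; this implementation documents its own
  choices and exposes them as parameters rather than claiming vendor
  equivalence.
- The cm → pixel layout rounding introduces up to half a pixel of junction
  position uncertainty; it is quantified and reported, not corrected.
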