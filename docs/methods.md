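# Methods

## Measurement model

A flow cell of fixed geometry (10 mm diameter, 4 mm depth) holds a
reagent–sample mixture whose reaction product absorbs light in proportion
to the analyte concentration. With the blank (reagent-only) frame's mean
channel intensity as the incident intensity I0 and a sample frame's as
the transmitted intensity It, the per-channel transmittance is T = It/I0
and the Beer-Lambert absorbance A = −log10(T). At fixed path length,
A = k·C with k the effective absorptivity of the product on that channel,
so concentration is linear in absorbance.

The model assumes: (i) the flow cell fills the region of interest
uniformly; (ii) illumination and camera gain are multiplicative and
identical between the blank and sample frames of one session, so they
cancel in T; (iii) the reaction has reached its endpoint (incubation is
outside this package's scope); (iv) absorbance is measured on a single
color channel per assay.

### Measurement channels

The camera's R/G/B channels stand in for spectral wavelengths. Each assay
measures on the channel complementary to its product's color, where
attenuation is strongest:

| assay      | product                  | color       | channel |
|------------|--------------------------|-------------|---------|
| uric acid  | quinoneimine             | pink-red    | green   |
| creatinine | Jaffe complex            | yellow-orange | blue  |
| albumin    | BCG–albumin complex      | green       | red     |

The channel is per-assay configuration, not a claim about any particular
reagent lot; a wrong choice is caught by the calibration-failure gate
(non-positive slope).

## Preprocessing chain

resize → (optional white balance) → ROI crop → spatial average.

- **Resize**: bilinear, longer edge to `preprocess.target_long_edge`
  (default 1000 — the common resolution is an artifact choice; no
  canonical value exists). Bilinear interpolation runs in float64
  (scipy.ndimage) because the downstream blank ratio needs more precision
  than a float32 image path retains.
- **White balance**: gray-world (each channel scaled so its mean equals
  the grand mean), chosen for being reference-free and testable; **off by
  default**. On a frame filled by the colored flow cell, gray-world
  equalizes the channel means and thereby erases exactly the chromatic
  signal the Beer-Lambert inversion needs; it is only appropriate when
  the frame contains enough neutral surround. It is applied full-frame,
  before the ROI crop, so that when enabled its statistics come from the
  whole scene rather than from the colored cell alone.
- **ROI**: default centered 50 × 50 px; explicit 0-based origin supported
  for off-center cells. Half-open extents, row-major.
- **Spatial average**: plain per-channel mean, no rounding. Averaging N
  pixels divides uncorrelated sensor noise by √N. Optional multi-frame
  averaging (`average_frames`) averages per-frame RGB triples.

## Calibration protocol

1. **Water check**: |A_water| ≤ `calibration.water_tolerance`
   (default 0.02 AU — no canonical value exists; 0.02 AU is ~0.5 % of the
   blank intensity, comfortably above pipeline numerics and below any
   real contamination signal). The check uses *unclipped* transmittance
   so negative deviations (water brighter than blank) are caught by the
   same symmetric band. Failure aborts the session.
2. **Blank baseline**: the blank normalized against itself gives T = 1,
   A = 0 on every channel identically, so the baseline compensates any
   intrinsic reagent absorbance by construction.
3. **Factor**: F = C_std / A_std from one standard frame
   (uric acid 8 mg/dL, creatinine 2 mg/dL, albumin 4 g/dL). A_std ≤ 0
   raises a calibration failure.
4. **Estimation**: C = A_test · F. Out-of-linear-range values are
   reported numerically and flagged, not truncated.

The calibration curve is a through-origin straight line (the blank pins
A(0) = 0): slope = Σ(c·a)/Σ(c²), with R² computed against the
through-origin fit. Multi-point fitting exists for one-time linearity
validation (`validate_linearity`, gate R² ≥ 0.99, configurable); routine
sessions use the single-point factor, whose one-point fit slope is
exactly 1/F. An intercept option was considered and rejected as the
default: with a blank-referenced baseline a nonzero intercept can only
absorb noise, and it breaks the single-point/multi-point consistency.

Transmittance above 1 (sample brighter than blank, possible under noise)
is clipped to 1 by default so absorbance stays non-negative; the clip is
configurable off. A sample channel of exactly 0 is floored to
`photometry.epsilon` (1e-6) with a warning so the log stays finite.

Calibration state persists as one JSON document per store file, keyed by
assay, with `schema_version` and an ISO-8601 timestamp. The CLI never
silently reuses a stale factor: `measure` requires an explicit
`--use-stored`.

## Performance statistics

- LoD = n · sd / slope. The multiplier n is a **required** argument —
  conventions differ (3.3 from the IUPAC blank model; some protocols use
  the replicate count, e.g. n = 5) and silently defaulting it would make
  reported LoDs incomparable. The sd is the standard deviation of
  replicate blank-level concentration estimates, computed upstream.
- %CV = 100 · sample sd (ddof 1) / mean. Intra vs inter repeatability is
  a grouping label (same sample repeated vs different samples at one
  concentration); the statistic is identical.
- Recovery % = (measured − baseline)/spike × 100. In the published
  spike-recovery table this formula reproduces only the row
  (8.23, 2.50, 10.64) → 96.4 % exactly; the other rows differ from the
  stated formula by 0.1–0.5 points (e.g. the first row computes 97.0
  against a printed 97.5). The formula is implemented as stated and the
  discrepancy is documented rather than reverse-engineered.
- Average variation % = mean over measurements of |m − actual|/actual ×
  100 — the cross-device/brand/lighting consistency statistic. All five
  published rows reproduce exactly at 2-decimal rounding.
- Method comparison: mean difference, mean absolute difference, Pearson r
  (scipy). r is flagged undefined (None) when either series has zero
  variance. No Deming or Bland-Altman regression — out of scope.

Display rounding: 2 decimals for variation %, 1 for recovery %, 3
significant figures for %CV. Raw values are always retained alongside.

## Synthetic forward model

Per channel: I = clip(base · gain · illum · 10^(−k·C) + ramp + noise, 0, 255),
with additive per-pixel Gaussian noise and an optional zero-mean linear
illumination ramp. Defaults:

- base intensity (210, 215, 205): near-white under a diffused LED;
- absorptivity per assay scaled so the standard renders at A = 0.4 on the
  measurement channel (mid-range, clip-safe across each linear range);
  off-channel absorptivity 20 % of the measurement channel, mimicking
  broad dye spectra (set to 0 for idealized tests);
- device gains within a few percent of 1; reagent-brand variation ±10 %
  on absorptivity; lighting as illumination scale {0.8, 1.0, 1.2}
  labelled morning/afternoon/evening;
- noise: additive Gaussian then clipping — the simplest model whose
  variance spatial averaging reduces.

What the generator does **not** emulate: camera ISP effects (demosaicing,
gamma, auto-exposure), lens vignetting beyond a linear ramp, chemical
kinetics and incubation drift, specular reflections, flow-cell placement
error. Passing tests therefore demonstrate the *algebra* of the pipeline
(inversion, cancellation, gating) under controlled perturbations — not
robustness to every artifact of real phone photography.

### Problem sizes in the tests and acceptance script

Synthetic frames are 100 × 100 native (controls and tests alike);
round-trip checks use 10 concentrations per assay across each linear
range; gain invariance uses 20 random scenes with illumination scale in
[0.5, 1.5] on clip-safe base intensities; oracle checks use 100 random
calibration designs and 1000 random statistic inputs. The noisy-recovery
study uses 5 concentrations × 5 replicates with per-pixel noise sd 3 on
base 160: after standardization the 50 × 50 ROI spans a 5 × 5 source
region, so the averaged intensity error is ≈ sd/5, which propagates
through dA = dI/(I·ln 10) to roughly a 1 % single-replicate %CV at
mid-range while keeping 0/255 clipping negligible (z > 5 even at the top
of the range, where I_t = 16). Noise-level monotonicity {2, 1, 0.5} uses
common random numbers across levels so the comparison isolates the noise
scale.

## Numerical choices and degenerate inputs

- Intensities are float64 in [0, 255] end-to-end; 8-bit quantization only
  on PNG write (round, then clip).
- In-memory round-trip accuracy is ~1e-12 relative; through 8-bit PNG
  files, quantization bounds accuracy at roughly the percent level.
- Grayscale input is rejected (photometry needs 3 channels); alpha is
  dropped.
- A blank with a zero channel is degenerate (ratio undefined) and aborts;
  an all-zero channel mean likewise aborts white balance.
- Ties/rounding: resize dimensions round half to even via Python round;
  ROI centering uses floor((H−h)/2).

## Known limitations

- Single-channel photometry: no multi-wavelength or weighted-RGB sensing.
- No flow-cell detection — the ROI is configured, not found; a misplaced
  cell silently measures the wrong pixels.
- The linear model has no extrapolation guard beyond the
  `in_linear_range` flag.
- LoD, %CV ranges and analyzer-agreement figures of a physical device
  depend on real optics and chemistry; the synthetic studies here
  characterize the computation, not the hardware.
- The albumin LoD is recorded with explicit units because published
  sources state it inconsistently (g/dL vs mg/dL); this package does not
  adjudicate.
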