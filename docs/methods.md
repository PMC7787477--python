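# Methods

This note documents the models, estimators, parameter choices, and known
limitations behind `aoreg`.  Conventions: volume arrays are indexed
`(y, z, x)` (slow axis, depth, fast axis); displacement vectors are
`(dx, dy, dz)` in pixels, in the target-minus-reference sign convention
(registering a volume whose eye position is `+e` against a motionless
raster yields `+e` in pixels); angles are degrees; pitches µm/px.

## Synthetic retina and eye motion

The simulator exists so that every registration stage can be validated by
parameter recovery.  It emulates:

- **Cone mosaic**: hexagonal lattice of Gaussian bright spots
  (nearest-neighbor spacing `cone_spacing`, default 6 µm; spot σ =
  spacing/4), with optional positional jitter.  A perfectly regular
  lattice is translation-ambiguous (correlation is near 1 at every lattice
  vector), so registration tests use jitter ≈ 0.6 µm — real mosaics are
  quasi-regular.  Note a hexagonal lattice's spectral ring sits at
  `2/(√3·spacing)`, i.e. the inverse *row* spacing; the metrics therefore
  take `spacing·√3/2` as the cone-spacing period.
- **Depth structure**: Gaussian reflective bands emulating the
  outer-retinal complex (IS/OS, COST, ROST, RPE) at 30/48/62/74 µm.
- **Static texture**: a multiplicative random field (correlation length
  0.8 µm, contrast 0.5) emulating the fixed sub-cellular scatterer
  structure that makes real OCT reflectance broadband.  Without it the
  phantom is spectrally too smooth and phase-only correlation degrades in
  a way it does not on real data.
- **Motion**: per-B-scan samples (B-scans are rigid) of
  - drift: piecewise-linear segments (0.25 s) at `drift_speed`
    (30 µm/s) whose direction is biased back toward fixation, bounding
    excursions at `drift_range` (4 µm).  Fixation is a slow
    position-control loop; a free random walk would wander without bound
    over a multi-second video, which fixating eyes do not.
  - tremor: randomized-phase sinusoid, 2.5 µm amplitude, 11 ms period;
  - microsaccades: Poisson-scheduled smooth steps (default 1/s, 60 µm
    over 25 ms);
  - axial ripple: 5 µm sinusoid with a 1 s period (head motion);
  - torsion ~ N(0, 0.15°) and isotropic scale ~ N(1, 0.005), drawn once
    per video and held constant within it.
- **Acquisition**: trilinear sampling of the phantom at the
  torsion/scale-transformed raster position minus the eye position, with
  multiplicative speckle-like noise `1 + c·(Exp(1) − 1)` (contrast `c`,
  default 0.3 in validation runs) and an additive Rayleigh floor.

What the simulator does **not** model: physical OCT signal formation
(interferometry, dispersion, depth-dependent PSF), fully developed
correlated speckle, pupil-plane tilt physics (only its image-space shear
is available via the rectification test fixtures), retinal blood flow and
temporal reflectance changes.  Passing recovery tests therefore show the
estimators are correct under realistic geometry and noise scales, not that
the pipeline is robust to every property of clinical data.

## Pre-processing

- Fast-axis rectification resamples A-lines from the (monotone) measured
  scan pattern onto a uniform grid by 1D linear interpolation.
- Tilt correction shears each B-scan along depth.  The tilt argument is a
  slope in z px per A-line (degrees are ill-defined without pitches), or
  `"auto"`, which regresses the intensity-weighted axial centroid on x.
- Intensity normalization clips to `[N, M]` and rescales to `[0, 1e5]`
  (single precision).  `N` = 95th percentile of the vitreous band (top 10%
  of depth pixels by default); `M` = `N` + 37.5 dB (midpoint of the 35–40
  dB convention).
- Reference selection scores each volume by `m = r̄/((σ_r+ε)(σ_Δx+ε))`
  (ε = 1e−6) from 1D NCC of adjacent en-face lines, searched within ±16
  px; the largest `m` wins, ties to the lowest index.
- Batch cropping: centered crop to the minimum common (z, x) extent,
  capped at 512×512.

## Coarse stage (POC)

The reference is zero-padded to powers of two in (z, x) and to a multiple
of the sample width 2d in y; each target sub-volume (width 2d, centers
every s B-scans) is embedded at its native offset in an equal-size zero
canvas.  Spectral bins of zero magnitude in the normalized cross-power map
to 0; the peak is decoded to centered shifts in `[−dim/2, dim/2)` with
ties broken in (z, x, y) scan order.  Defaults s = 15, d = 6 (ranges
5–30 and 2d = 8–16); validation runs use s = 5, d = 8 — dense sampling
with wide, tremor-averaging windows, which stabilizes the edge
extrapolation of the trend.  Sub-volumes clipped by a volume edge are kept
while at least half the width survives, else flagged invalid.

Trend filtering deviates from a literal two-sided rule (|ΔY_N − ΔY_{N±1}|
> s), which would also flag both neighbors of an isolated outlier: samples
are removed iteratively (worst first) when they deviate by more than s
from *both* nearest retained neighbors.  Isolated spurious samples
disappear; genuine displacement steps (microsaccades) survive, so the
retained trace may legitimately contain one step larger than s.

## Fine stage (NCC)

Per candidate reference B-scan, the correlation coefficient is computed at
every integer in-plane shift with means and variances taken over the
overlap region only (FFT cross term + integral-image normalization), so
zero padding never biases the coefficient.  Numerical choices:

- coefficients clipped to [−1, 1];
- shifts with less than 50% overlap are excluded: small-overlap
  coefficients are high-variance and on quasi-periodic mosaics produce
  spurious confident matches;
- predictions outside the reference mark the B-scan unmatched;
- an argmax pinned to an *interior* search-window boundary is rejected
  (the true match likely lies beyond the window); a window clipped by the
  reference edge may legitimately peak at that edge.

Search half-width w_y = 8 (17 candidates).  Displacements are pixel-level
by design; the ~0.3 px RMSE floor seen in recovery experiments is the
quantization limit.

## Outlier filtering and construction

A B-scan is excluded when its NCC coefficient is below 0.3 or the maximum
per-axis SD of displacements within a centered ~20 ms window (converted
via the B-scan rate, ≥ 5 B-scans) exceeds 3–5 px (default 4).  Note that a
single spurious B-scan raises the window SD of its ~20 neighbors as well;
the filter is deliberately conservative.  Construction places included
B-scans at slot `i − Δy_i` (last acquired wins on collision; out-of-canvas
slots are dropped and counted) and masks unfilled slots; averaging skips
masked slots per volume and reports a coverage count.

## Global solve

With the correction-convention displacements δ = −(measured Δd) — exactly
the shift applied when constructing a registered volume — the chain is:

- `a_{j;R}` = mean of δ over all target B-scans matched to reference
  B-scan j (grouping by `j = i − Δy`), gaps filled by linear
  interpolation.  Because the underlying reference motion is band-limited
  (tremor ≈ 11 ms, many B-scan intervals) while the per-j mean is
  shot-noise-limited at small target counts, the trace is smoothed along j
  by a Savitzky–Golay filter (window 7, quadratic; width well below the
  tremor period, so the oscillation is tracked).  Setting the window to 0
  recovers the plain mean.
- `p = δ − a_{j;R} + s_i`, with `s_i = (0, i − ⟨i⟩, 0)` the explicit
  scanner raster term.
- Per-reference constant offsets minimize the sum over reference pairs of
  squared differences of `p + ε` on shared B-scans.  The quadratic has an
  exact minimizer — a weighted graph-Laplacian linear system — which is
  solved directly (a test asserts agreement with an independent numerical
  minimizer).  Gauge: ε = 0 on the first reference; disconnected overlap
  components get their own gauge and a warning.
- `τ = ⟨p + ε̂⟩_R` minus its grand mean (global coordinates are referenced
  to the ensemble average of eye motion).  B-scans registered to no
  reference remain undefined.

Accuracy scales with the number of targets contributing to each `a_{j;R}`
and with the number of references averaged in τ; validation runs use 30
volumes and 5 references, recovering τ to well under a pixel RMS per axis.

## Torsion/scale correction and A-line coordinates

Per video (torsion/scale are stable within a ~5 s video), the registered
volumes are averaged into an en-face subset on the τ grid (bilinear
splatting — nearest-pixel rounding leaves a measurable bias in the
subsequent fit) and a similarity transform onto the subset of the
reference video (the one containing the volume with the lowest τ variance)
is fitted by Mattes mutual information (SimpleITK, full sampling —
deterministic), over the region both subsets cover.  Failures fall back to
an identity transform with a failure flag, excluding the video from
A-line rendering.

Because the τ solve already absorbs the *between*-B-scan part of each
video's torsion and scale, the τ-rendered subsets differ only by the
*within*-B-scan (fast-axis) residual field; a single similarity fit
therefore captures roughly half of the distortion.  Two consequences:

- the fit is iterated (fit → re-render → fit, ≤ 8 rounds, geometric
  convergence at ratio ≈ 1/2);
- the affine is applied to the fast-scan raster term only,
  `χ_{α,i,T} = τ_{i,T} + A_T·ς_α` with `ς_α = (α − ⟨α⟩, 0, 0)`:
  applying it to `τ + ς` as a whole would re-distort the already-correct
  between-B-scan positions (and the fit fixpoint would sit at exactly half
  the true torsion).  With `A = I` this reduces to `τ + ς` exactly; depth
  passes through unchanged (the 4×4 augmentation has an identity z
  row/column).

The recovered transform maps a video into the reference video's frame, so
the recovered rotation/scale are *relative* to that reference video.

## Rendering

Each A-line's pixel column is splatted to the nearest grid voxel column at
`χ` (half-up rounding: half-integer-centered rasters of even dimension
stay uniform, unlike banker's rounding); per-voxel accumulation and count
give the average, and the 2D per-column count map totals the number of
placed A-lines.  Collisions average (the global average is a multi-volume
mean by definition), unlike single-volume construction's last-wins rule.
The grid auto-fits the χ bounding box, which is what extends the field of
view beyond a single volume; the same routine serves mosaicking and focus
stacking.

## Metrics

Spectra are estimated from mean-subtracted, Hann-windowed images; the
radial profile averages one-bin annuli with DC excluded.  "Power at the
cone-spacing period" is a one-annulus band (width configurable) at the
inverse period; the noise floor is the median over the top 20% of radial
frequencies.  The ISR/MSE sums run over pixels common to both images (an
optional mask), with central-difference gradients.  dB values are
`10·log10` of power ratios; `db_percent` converts to percent increase.

## Validation experiments (study conditions)

- **B-scan stage**: 10 volumes, 64(y)×96(z)×96(x), drift + tremor + axial
  ripple, speckle contrast 0.3, registered to a motion-free acquisition;
  per-axis RMSE of included displacements ≤ 1 px.  A separate run injects
  one 12 µm/25 ms microsaccade mid-volume: the volume still registers and
  errors outside the saccade interval stay within a pixel.
- **Global stage**: 3 videos × 10 volumes, 72×40×64, every volume (the
  references included) distorted by drift + tremor + axial ripple,
  noise-free; τ must match ground-truth content positions to ≤ 1 px RMS
  per axis up to one global constant, with the gauge and zero-mean
  invariants at 1e−6.  A second run imposes 1.0° torsion and 1.02 scale
  on one video: recovery within 0.1° and 0.005.
- **Metric trends**: 9 volumes with independent session-scale positions
  (fixation offsets SD 10 µm — without them the unregistered average is
  barely misaligned relative to a cone spacing and the comparison is
  uninformative).  Registered averages must beat unregistered averages in
  contrast, ISR, and MSE at every count ≥ 2, and mosaic SNR must order
  global ≥ single-reference ≥ unregistered.  Gap slots are filled from
  the nearest covered slot before spectral metrics (zero rows would
  dominate), and pixelwise metrics run over covered rows only.

Problem sizes were chosen so the full suite runs in minutes while each
stage operates in its intended regime (search windows, outlier windows,
and coarse sampling all non-degenerate relative to the volume size).

## Known limitations

- Pixel-level displacements: sub-pixel residuals (~0.3 px) are not
  corrected and bound the attainable mosaic contrast.
- The within-B-scan affine residual is modeled as a similarity transform;
  shear and anisotropic terms are out of scope.
- Reference-motion estimation needs tens of targets per reference; with
  very few volumes τ degrades gracefully but measurably, dominated by the
  per-j shot noise of `a_{j;R}`.
- Volume edges (first/last few B-scans) are intrinsically less reliable:
  coarse predictions are extrapolated there and content may fall outside
  a given reference.
- Torsion/scale are assumed constant within a video; z scaling is not
  corrected.
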