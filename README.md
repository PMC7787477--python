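# aoreg

Motion-artifact correction for adaptive-optics OCT (AO-OCT) retinal volume
images: a coarse-to-fine 3D B-scan registration cascade followed by
multi-reference global A-line registration, with cone-mosaic image-quality
metrics and a synthetic retina/eye-motion simulator for validation.

## Who this is for

AO-OCT (and OCT) imaging groups who acquire many volumes of the same
retinal patch and need to average them at cellular resolution.  During the
98–414 ms it takes to raster a volume, fixational eye movements — drift,
tremor (~2–3 µm at ~11 ms), microsaccades (tens of µm over ~25 ms) — and
axial head motion displace every fast B-scan, and torsion/scale differences
accumulate between videos.  Averaging without registration destroys the
cone mosaic; registering to a single reference volume leaves the
reference's own distortion in every result.

## Method

**Stage 1 — 3D B-scan registration.**  Fast B-scans (acquired in well under
a millisecond) are treated as rigid.  A target volume is registered to a
reference volume by:

1. *Coarse:* 3D phase-only correlation (POC) of evenly spaced sub-volume
   samples, `R_N = F(a_N)∘F(b)* / |F(a_N)∘F(b)*|`, giving a sparse
   displacement trend along the slow axis;
2. *Predict:* linear upsampling of the trend to a per-B-scan position
   prediction `y′_i = i − Δy′_i`;
3. *Fine:* full-extent, overlap-normalized cross-correlation (NCC) of each
   B-scan against the reference B-scans inside `y′_i ± w_y`, at pixel
   precision; `Δy_i = i − j*`;
4. *Filter:* exclusion of B-scans with weak correlation (ρ < 0.3) or
   locally erratic displacement (windowed SD over ~20 ms above 3–5 px),
   then placement at slot `i − Δy_i` with in-plane shift `(−Δx_i, −Δz_i)`
   (collisions: last acquired wins; empty slots are masked as gaps).

**Stage 2 — global A-line registration.**  Every volume is registered to
*several* references.  Averaging the displacements that many targets report
against each reference B-scan estimates that reference's own motion
(`a_{j;R}`, zero-mean for a fixating eye); per-reference constant offsets
`ε̂_R` are reconciled by an exact least-squares solve over the
reference-overlap graph (gauge: `ε̂_{R0} = 0`), and averaging across
references yields one zero-mean global 3D coordinate `τ_{i,T}` per B-scan.
A per-video similarity transform `A_T` (rotation + isotropic scale +
translation, fitted by Mattes mutual information) removes torsion and scale
differences; each A-line then receives the coordinate
`χ_{α,i,T} = τ_{i,T} + A_T·ς_α` with `ς_α` the centered fast-scan raster
term.  Rendering at `χ` averages hundreds of volumes, extends the field of
view beyond a single volume, and supports focus stacking.

**Metrics.**  Relative power spectral contrast at the cone-spacing
frequency, image sharpness ratio `ISR = Σ‖∇I_avg‖ / Σ‖∇I_ref‖`, MSE, and
the cone-mosaic spectral SNR (mosaic-frequency power over the
high-frequency noise floor), all on en-face projections.

## Worked example

```python
import numpy as np
import aoreg

# a textured, quasi-regular cone mosaic (6 um spacing) and a raster scanner
phantom = aoreg.build_phantom((170, 170, 90), cone_spacing=6.0,
                              seed=1, mosaic_jitter=0.6)
scan = aoreg.ScanParams(n_x=72, n_z=48, n_y=56, volume_rate=2.4)

# a still reference and a drifting, trembling target
still = aoreg.MotionParams(drift_speed=0, tremor_amplitude=0,
                           microsaccade_rate=0, axial_amplitude=0,
                           torsion_sd=0, scale_sd=0)
quiet = aoreg.simulate_motion(0.06, still, scan.bscan_rate)
reference, _ = aoreg.acquire_volume(phantom, quiet, scan, origin_um=(40, 40))

moving = aoreg.MotionParams(microsaccade_rate=0, torsion_sd=0, scale_sd=0, seed=3)
trace = aoreg.simulate_motion(0.06, moving, scan.bscan_rate)
target, truth = aoreg.acquire_volume(phantom, trace, scan, origin_um=(40, 40),
                                     speckle_contrast=0.3, noise_sd=0.02, seed=7)

disp = aoreg.register_volume(target, reference,
                             aoreg.CoarseSampling(s=5, d=8))
err = disp.disp[disp.included] - truth[disp.included]
print("included fraction:", disp.included.mean().round(3))
print("RMSE (x, y, z) px:", np.sqrt((err ** 2).mean(axis=0)).round(3))
```

Output:

```
included fraction: 1.0
RMSE (x, y, z) px: [0.3   0.282 0.276]
```

All of the target's B-scans pass the displacement filters, and the
estimated per-B-scan displacements recover the simulated eye motion to
about a third of a pixel per axis — the residual is the quantization floor
of a pixel-level method.

The command line exposes the same stages:

```bash
aoreg simulate --preset drift --seed 1 --out sim/
aoreg register3d --target sim/volume_001.h5 --reference sim/volume_000.h5 --out disp.csv
aoreg run --input sim/ --out results/
```

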