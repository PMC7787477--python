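# File formats

All indices are 0-based; displacements are in pixels; angles in degrees;
pitches in µm/px.

## Volumes

**HDF5** (canonical, `.h5`/`.hdf5`): dataset `intensity`, shape
`(n_y, n_z, n_x)` = (B-scan, depth, A-line), single precision.
Attributes on the dataset:

| attr            | meaning                         |
|-----------------|---------------------------------|
| `axis_order`    | always `"y,z,x"`                |
| `pitch_um`      | (x, y, z) µm per pixel          |
| `bscan_rate_hz` | fast B-scan rate                |
| `video`, `index`| acquisition identifiers         |

**TIFF** (interchange, `.tif`/`.tiff`): one page per B-scan, each page
z rows × x columns.  TIFF carries no pitch metadata; reading defaults to
1.0 µm/px with a logged warning.

Rendered volumes written by the pipeline additionally ship a
`count_map.csv` (per-column A-line counts, rows = y, cols = x).

## Motion traces

CSV columns `bscan_index, t_ms, dx_px, dy_px, dz_px` plus a JSON sidecar
(same stem, `.json`) holding `{"torsion_deg": ..., "scale": ...}`.

## Displacement tables

`displacements.csv` from the multi-reference stage: one row per included
(target B-scan, reference) pair with columns
`T, R, i, j, dx, dy, dz, ncc`.  `T`/`R` are volume positions in the batch,
`i` the target B-scan, `j = i + dy` the matched reference B-scan.  The
`dx, dy, dz` here are in the *correction* convention (the shift applied
when constructing a registered volume); the single-pair CSV written by
`aoreg register3d` (`i, dx, dy, dz, ncc, included, y_pred`) uses the raw
measured (target-minus-reference) convention.

## Global coordinates

`tau.csv`: `T, i, x, y, z, defined` — per-B-scan global coordinates (NaN
where undefined).  `affines.json`: per video, the 4×4 row-major matrix
(en-face similarity augmented with an identity depth row/column),
rotation (deg), scale, and a convergence flag.

## Scan-pattern lookup

One-column CSV of fast-axis positions per A-line index, strictly
increasing, unit-normalized or not (positions are rescaled to the pixel
grid).

## Pipeline configuration

JSON or YAML mapping of the `PipelineConfig` fields (`s`, `d`, `w_y`,
`ncc_min`, `sigma_max_px`, `window_ms`, `vitreous_fraction`,
`m_db_above_n`, `crop_cap`, `min_registered_frac`, `target_frac`,
`normalize`, `tilt`, `cone_period_um`, `seed`).  Unknown keys are
rejected; every run writes its resolved configuration alongside the
outputs (`config_resolved.yaml`).
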