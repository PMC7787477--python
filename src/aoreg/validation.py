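"""Parameter-recovery experiments on synthetic data.

Each experiment simulates AO-OCT-style volumes under known eye motion,
runs the registration stages, and measures how well the known parameters
are recovered.  They are the package's quantitative self-checks: the
acceptance script and the test suite both call them.

All sizes and motion magnitudes are the experiments' study conditions:
10-20 volumes of 48-96 pixel extent, drift bounded at a few micrometres,
2.5 um tremor, ~1 s axial ripple, and (for the global stage) a 1 degree /
2 percent torsion-scale difference between videos — scales at which the
method's behavior is representative while a full run stays within
desk-scale compute.
"""

from __future__ import annotations

import numpy as np

from . import bscan, globalreg, metrics
from .synthetic import MotionParams, acquire_volume, build_phantom, simulate_motion, simulate_video
from .volume import MotionTrace, ScanParams

__all__ = [
    "CONE_SPACING_UM",
    "CONE_PERIOD_UM",
    "bscan_recovery_experiment",
    "microsaccade_experiment",
    "global_recovery_experiment",
    "metric_trend_experiment",
]

#: nearest-neighbor cone spacing of the validation phantoms (um)
CONE_SPACING_UM = 6.0

#: spectral period of the hexagonal mosaic: the row spacing
CONE_PERIOD_UM = CONE_SPACING_UM * np.sqrt(3) / 2


def _drift_tremor(seed: int) -> MotionParams:
    return MotionParams(
        drift_speed=30.0,
        tremor_amplitude=2.5,
        microsaccade_rate=0.0,
        axial_amplitude=5.0,
        torsion_sd=0.0,
        scale_sd=0.0,
        seed=seed,
    )


def _phantom(size_um: float, seed: int):
    return build_phantom(
        (size_um, size_um, 90.0), CONE_SPACING_UM, seed=seed, mosaic_jitter=0.6
    )


def bscan_recovery_experiment(
    seed: int = 0,
    n_volumes: int = 10,
    n_y: int = 64,
    n_z: int = 96,
    n_x: int = 96,
) -> dict:
    """Register drift+tremor volumes to a still reference; compare with truth.

    Simulates ``n_volumes`` volumes under bounded drift, tremor, and axial
    ripple (moderate speckle and noise), registers each to a motion-free
    acquisition of the same patch, and reports the per-axis RMSE of the
    included per-B-scan displacement estimates against the simulator's
    ground truth.
    """
    rng_seed = (seed * 7919 + 11) % (2**31)
    phantom = _phantom(max(n_x, n_y) * 1.0 + 100.0, rng_seed)
    scan = ScanParams(n_x=n_x, n_z=n_z, n_y=n_y, volume_rate=2.4)
    origin = (50.0, 50.0)
    quiet = simulate_motion(
        scan.volume_span_ms / 1000.0 + 0.01,
        MotionParams(drift_speed=0, tremor_amplitude=0, microsaccade_rate=0,
                     axial_amplitude=0, torsion_sd=0, scale_sd=0, seed=0),
        scan.bscan_rate,
    )
    reference, _ = acquire_volume(phantom, quiet, scan, origin_um=origin)

    errors = []
    included_fracs = []
    sampling = bscan.CoarseSampling(s=5, d=8)
    cache: dict = {}
    for k in range(n_volumes):
        trace = simulate_motion(
            scan.volume_span_ms / 1000.0 + 0.01,
            _drift_tremor(rng_seed + 100 + k),
            scan.bscan_rate,
        )
        target, gt = acquire_volume(
            phantom, trace, scan, origin_um=origin,
            noise_sd=0.02, speckle_contrast=0.3, seed=rng_seed + 200 + k,
        )
        disp = bscan.register_volume(
            target, reference, sampling=sampling, ref_cache=cache
        )
        sel = disp.included
        included_fracs.append(float(sel.mean()))
        errors.append(disp.disp[sel] - gt[sel])
    err = np.concatenate(errors)
    rmse = np.sqrt((err**2).mean(axis=0))
    return {
        "rmse_x_px": float(rmse[0]),
        "rmse_y_px": float(rmse[1]),
        "rmse_z_px": float(rmse[2]),
        "included_fraction": float(np.mean(included_fracs)),
        "n_bscans": int(err.shape[0]),
    }


def microsaccade_experiment(
    seed: int = 0,
    n_y: int = 64,
    n_z: int = 96,
    n_x: int = 96,
    amplitude_um: float = 12.0,
    duration_ms: float = 25.0,
) -> dict:
    """One mid-volume microsaccade: the volume must still register, with
    errors confined to B-scans inside the saccade interval.

    A smooth saccade step (mostly along the slow axis) is injected halfway
    through acquisition on top of drift+tremor.  Reported: the included
    fraction, and the maximum per-axis error among included B-scans
    outside the saccade interval (padded by the outlier-filter window).
    """
    rng_seed = (seed * 7919 + 23) % (2**31)
    phantom = _phantom(max(n_x, n_y) * 1.0 + 100.0, rng_seed)
    scan = ScanParams(n_x=n_x, n_z=n_z, n_y=n_y, volume_rate=2.4)
    origin = (50.0, 50.0)
    still = MotionParams(drift_speed=0, tremor_amplitude=0, microsaccade_rate=0,
                         axial_amplitude=0, torsion_sd=0, scale_sd=0, seed=0)
    quiet = simulate_motion(scan.volume_span_ms / 1000.0 + 0.01, still, scan.bscan_rate)
    reference, _ = acquire_volume(phantom, quiet, scan, origin_um=origin)

    base = simulate_motion(
        scan.volume_span_ms / 1000.0 + 0.01, _drift_tremor(rng_seed + 1), scan.bscan_rate
    )
    t_start = (n_y // 2) * scan.bscan_period_ms
    u = np.clip((base.t_ms - t_start) / duration_ms, 0.0, 1.0)
    ramp = u * u * (3 - 2 * u)
    xyz = base.xyz_um.copy()
    direction = np.array([0.35, 0.94]) / np.hypot(0.35, 0.94)
    xyz[:, 0] += amplitude_um * direction[0] * ramp
    xyz[:, 1] += amplitude_um * direction[1] * ramp
    trace = MotionTrace(t_ms=base.t_ms, xyz_um=xyz)
    target, gt = acquire_volume(
        phantom, trace, scan, origin_um=origin,
        noise_sd=0.02, speckle_contrast=0.3, seed=rng_seed + 2,
    )
    disp = bscan.register_volume(target, reference, bscan.CoarseSampling(s=5, d=8))

    i0 = n_y // 2
    i1 = i0 + int(np.ceil(duration_ms / scan.bscan_period_ms))
    margin = max(5, round(20e-3 * scan.bscan_rate)) // 2
    outside = np.ones(n_y, dtype=bool)
    outside[max(0, i0 - margin) : min(n_y, i1 + margin + 1)] = False
    sel = disp.included & outside
    err = np.abs(disp.disp[sel] - gt[sel])
    return {
        "included_fraction": float(disp.included.mean()),
        "max_error_outside_saccade_px": float(err.max()),
        "n_outside": int(sel.sum()),
        "saccade_interval": (int(i0), int(i1)),
    }


def global_recovery_experiment(
    seed: int = 0,
    n_videos: int = 3,
    volumes_per_video: int = 10,
    n_y: int = 72,
    n_z: int = 40,
    n_x: int = 64,
    torsion_deg: float = 1.0,
    scale: float = 1.02,
    n_references: int = 5,
) -> dict:
    """Multi-reference global solve against distorted references.

    Two videos of the same patch are simulated noise-free under bounded
    drift + tremor; the second carries the imposed torsion and scale.
    Every volume (references included) is distorted by real motion.
    Reported: per-axis RMS of the recovered B-scan global coordinates
    against ground-truth content positions (one global constant removed),
    the gauge and zero-mean solver invariants, and the recovered
    between-video torsion and scale.
    """
    rng_seed = (seed * 7919 + 57) % (2**31)
    phantom = _phantom(max(n_x, n_y) + 130.0, rng_seed)
    scan = ScanParams(n_x=n_x, n_z=n_z, n_y=n_y, volume_rate=2.4)
    origin = (50.0, 50.0)
    volumes, truths = [], []
    imposed = [(0.0, 1.0), (torsion_deg, scale)] + [(0.0, 1.0)] * max(0, n_videos - 2)
    for vid in range(n_videos):
        th, sc = imposed[vid]
        vols, gts, _ = simulate_video(
            phantom, scan, _drift_tremor(0), volumes_per_video,
            seed=rng_seed + 11 + vid, torsion_deg=th, scale=sc,
            noise_sd=0.0, speckle_contrast=0.0, video=vid, origin_um=origin,
        )
        volumes += vols
        truths += gts

    # references: the best-quality volume of each video plus the next-best
    # overall, n_references total (the multi-reference averaging in the
    # solve is what suppresses per-reference noise)
    from .preprocess import reference_quality_metric

    scores = [reference_quality_metric(v).m for v in volumes]
    refs = []
    video_of = [v.video for v in volumes]
    for vid in range(n_videos):
        members = [t for t in range(len(volumes)) if video_of[t] == vid]
        refs.append(max(members, key=lambda t: scores[t]))
    for t in sorted(range(len(volumes)), key=lambda t: -scores[t]):
        if len(refs) >= n_references:
            break
        if t not in refs:
            refs.append(t)

    mrd = globalreg.multi_reference_register(
        volumes, references=refs, sampling=bscan.CoarseSampling(s=5, d=8)
    )
    motions = {r: globalreg.reference_motion(mrd, r) for r in mrd.references}
    ptable = globalreg.compute_p(mrd, motions)
    eps, ncomp = globalreg.solve_reference_offsets(ptable, mrd.references)
    coords = globalreg.global_bscan_coords(
        ptable, eps, mrd.n_volumes, mrd.n_y, ncomp
    )

    # ground-truth content positions: torsion/scale act on the raster
    # about the volume center, eye translation subtracts
    i_c = (n_y - 1) / 2.0
    errors = []
    for t, vol in enumerate(volumes):
        th, sc = imposed[int(vol.video)]
        theta = np.deg2rad(th)
        m = sc * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        y_rel = np.arange(n_y) - i_c
        true_xy = (m @ np.stack([np.zeros(n_y), y_rel])).T - truths[t][:, :2]
        true_z = -truths[t][:, 2]
        tau_true = np.column_stack([true_xy, true_z])
        sel = coords.defined[t]
        errors.append(coords.tau[t, sel] - tau_true[sel])
    err = np.concatenate(errors)
    err -= err.mean(axis=0)  # one global constant
    rms = np.sqrt((err**2).mean(axis=0))

    gauge = float(np.abs(eps[mrd.references[0]]).max())
    tau_mean = float(np.abs(coords.tau[coords.defined].mean(axis=0)).max())
    b_mean = max(
        float(np.abs(m.b.mean(axis=0)).max()) for m in motions.values()
    )

    affines = globalreg.estimate_affine_pipeline(volumes, coords)
    a0, a1 = affines[0], affines[1]
    rel = a1.matrix @ np.linalg.inv(a0.matrix)
    rel_rot = float(np.degrees(np.arctan2(rel[1, 0], rel[0, 0])))
    rel_scale = float(np.sqrt(np.linalg.det(rel[:2, :2])))
    return {
        "tau_rms_x_px": float(rms[0]),
        "tau_rms_y_px": float(rms[1]),
        "tau_rms_z_px": float(rms[2]),
        "gauge_residual_px": gauge,
        "tau_mean_residual_px": tau_mean,
        "reference_motion_mean_residual_px": b_mean,
        "recovered_torsion_deg": rel_rot,
        "imposed_torsion_deg": float(torsion_deg),
        "recovered_scale": rel_scale,
        "imposed_scale": float(scale),
        "fraction_registered": float(mrd.fraction_registered),
        "n_bscans": int(err.shape[0]),
        "coords": coords,
        "volumes": volumes,
        "affines": affines,
    }


def metric_trend_experiment(
    seed: int = 0,
    n_targets: int = 8,
    n_y: int = 64,
    n_z: int = 48,
    n_x: int = 64,
) -> dict:
    """Registered vs unregistered averaging, quantified by the metrics.

    One video of drift+tremor volumes (speckled) of a single patch; the
    best-quality volume serves as reference.  For each averaging count the
    registered average is compared against the unregistered average via
    relative spectral contrast, ISR, and MSE (all vs the reference
    en-face image), and the cone-mosaic SNR is computed for unregistered,
    single-reference, and global-coordinate averages.
    """
    rng_seed = (seed * 7919 + 91) % (2**31)
    phantom = _phantom(max(n_x, n_y) + 120.0, rng_seed)
    scan = ScanParams(n_x=n_x, n_z=n_z, n_y=n_y, volume_rate=2.4)
    origin = (50.0, 50.0)
    # volumes drawn with independent motion realizations: like volumes
    # from different videos of a session, their positions decorrelate at
    # the session-scale wander (a couple of cone spacings), so the
    # unregistered average genuinely smears the mosaic
    volumes = []
    span_s = scan.volume_span_ms / 1000.0 + 0.01
    offset_rng = np.random.default_rng(rng_seed + 77)
    for k in range(n_targets + 1):
        params = MotionParams(
            drift_speed=40.0, drift_range=12.0, tremor_amplitude=2.5,
            microsaccade_rate=0.0, axial_amplitude=5.0,
            torsion_sd=0.0, scale_sd=0.0, seed=rng_seed + 31 * k,
        )
        trace = simulate_motion(span_s, params, scan.bscan_rate)
        # between-volume fixation offset (look-ins): positions decorrelate
        # by about two cone spacings across the session
        trace.xyz_um = trace.xyz_um + np.append(
            np.clip(offset_rng.normal(0.0, 10.0, 2), -20, 20), 0.0
        )
        vol, _ = acquire_volume(
            phantom, trace, scan, origin_um=origin,
            noise_sd=0.02, speckle_contrast=0.3, seed=rng_seed + 500 + k,
        )
        vol.video, vol.index = 0, k
        volumes.append(vol)
    from .preprocess import select_reference

    ref_idx = select_reference(volumes)
    reference = volumes[ref_idx]
    targets = [v for k, v in enumerate(volumes) if k != ref_idx]

    sampling = bscan.CoarseSampling(s=5, d=8)
    cache: dict = {}
    registered = []
    kept_targets = []
    for t in targets:
        try:
            disp = bscan.register_volume(t, reference, sampling, ref_cache=cache)
            vol, gaps, _ = bscan.construct_registered(t, disp)
        except (bscan.CoarseRegistrationError, ValueError):
            continue  # target unregistrable to this single reference
        registered.append((vol, gaps))
        kept_targets.append(t)
    targets = kept_targets
    n_targets = len(targets)

    # metrics are computed over a common, artifact-free frame: x borders
    # zero-padded by construction shifts are cropped, and slow-axis gap
    # slots (no volume covered them) are filled from the nearest covered
    # slot — zero rows would otherwise dominate every metric at small
    # averaging counts
    x_margin = 14
    y_margin = 8

    def fill_gaps(avg, cov):
        data = avg.intensity.copy()
        ok = np.flatnonzero(cov > 0)
        for i in np.flatnonzero(cov == 0):
            data[i] = data[ok[np.argmin(np.abs(ok - i))]]
        return data

    def crop(data2d) -> metrics.EnFaceImage:
        return metrics.EnFaceImage(
            data=data2d[y_margin:-y_margin, x_margin:-x_margin]
        )

    ref_img = crop(metrics.enface_projection(reference).data)
    counts = list(range(2, n_targets + 1))
    curves = {"contrast_registered": [], "contrast_unregistered": [],
              "isr_registered": [], "isr_unregistered": [],
              "mse_registered": [], "mse_unregistered": []}
    for k in counts:
        avg_reg, cov = bscan.average_registered(registered[:k])
        raw = np.mean([t.intensity for t in targets[:k]], axis=0)
        img_reg = crop(fill_gaps(avg_reg, cov).mean(axis=1))
        img_raw = crop(raw.mean(axis=1))
        # pixelwise metrics run over pixels common to both images: rows the
        # registered average actually covered
        mask = np.broadcast_to(
            (cov > 0)[y_margin:-y_margin, None], img_reg.data.shape
        )
        curves["contrast_registered"].append(
            metrics.relative_spectral_contrast(img_reg, ref_img, CONE_PERIOD_UM, band_bins=3)
        )
        curves["contrast_unregistered"].append(
            metrics.relative_spectral_contrast(img_raw, ref_img, CONE_PERIOD_UM, band_bins=3)
        )
        curves["isr_registered"].append(metrics.isr(img_reg, ref_img, mask))
        curves["isr_unregistered"].append(metrics.isr(img_raw, ref_img, mask))
        curves["mse_registered"].append(metrics.mse(img_reg, ref_img, mask))
        curves["mse_unregistered"].append(metrics.mse(img_raw, ref_img, mask))

    # SNR ordering: unregistered vs single-reference vs global average
    avg_single, cov_single = bscan.average_registered(registered)
    raw_all = np.mean([t.intensity for t in targets], axis=0)
    from .preprocess import reference_quality_metric

    quality = [reference_quality_metric(v).m for v in volumes]
    refs = sorted(range(len(volumes)), key=lambda t: -quality[t])[:4]
    mrd = globalreg.multi_reference_register(
        volumes, references=refs, sampling=sampling
    )
    coords = globalreg.solve_global(mrd)
    affines = {0: globalreg.AffineTransform.identity(video=0)}
    aline = globalreg.aline_global_coords(coords, affines, volumes)
    rendered, count2d = globalreg.render_global(volumes, aline)
    # central well-covered window of the (larger) global canvas
    thresh = max(2.0, 0.3 * count2d.max())
    rows_ok = np.flatnonzero((count2d >= thresh).any(axis=1))
    cols_ok = np.flatnonzero((count2d >= thresh).any(axis=0))
    glob_enface = rendered.intensity.mean(axis=1)[
        rows_ok[0] + 4 : rows_ok[-1] - 3, cols_ok[0] + 4 : cols_ok[-1] - 3
    ]
    glob_img = metrics.EnFaceImage(data=glob_enface)
    snr_unreg = metrics.mosaic_snr(crop(raw_all.mean(axis=1)), CONE_PERIOD_UM)
    snr_single = metrics.mosaic_snr(
        crop(fill_gaps(avg_single, cov_single).mean(axis=1)), CONE_PERIOD_UM
    )
    snr_global = metrics.mosaic_snr(glob_img, CONE_PERIOD_UM)
    return {
        "counts": counts,
        **{k: np.asarray(v) for k, v in curves.items()},
        "snr_unregistered_db": float(snr_unreg),
        "snr_single_reference_db": float(snr_single),
        "snr_global_db": float(snr_global),
    }
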