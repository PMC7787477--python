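"""Synthetic retina: cone-mosaic phantoms, fixational eye motion, raster sampling.

The generator emulates the imaging situation the registration pipeline is
built for: a cone-photoreceptor mosaic with reflective outer-retinal bands,
raster-scanned B-scan by B-scan while the eye drifts, tremors, and makes
microsaccades, the head moves axially, and torsion/scale vary between
videos.  Every realization is fully determined by its seed, and the
per-B-scan eye pose is exported as ground truth so each registration stage
can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import MotionTrace, Phantom, ScanParams, Volume

__all__ = [
    "MotionParams",
    "build_phantom",
    "simulate_motion",
    "acquire_volume",
    "simulate_video",
    "PRESETS",
]

#: Default reflective bands: (depth center um, thickness um, brightness),
#: emulating the outer-retinal complex (IS/OS, COST, ROST, RPE).
DEFAULT_LAYERS: list[tuple[float, float, float]] = [
    (30.0, 8.0, 1.0),   # IS/OS
    (48.0, 8.0, 0.8),   # COST
    (62.0, 6.0, 0.4),   # ROST
    (74.0, 10.0, 0.6),  # RPE
]


@dataclass
class MotionParams:
    """Fixational eye-motion and head-motion magnitudes.

    Defaults reproduce the motion scales of normal fixation: slow drift of a
    few tens of um/s, ~2.5 um tremor with an ~11 ms period, microsaccades
    jumping tens of um over ~25 ms, ~1 s axial head-motion ripple, and
    between-video torsion/scale jitter (torsion SD ~0.15 deg).
    """

    drift_speed: float = 30.0          # um/s
    drift_range: float = 4.0           # um, stationary excursion scale of drift
    tremor_amplitude: float = 2.5      # um
    tremor_period: float = 11.0        # ms
    microsaccade_rate: float = 1.0     # events/s
    microsaccade_amplitude: float = 60.0  # um
    microsaccade_duration: float = 25.0   # ms
    axial_amplitude: float = 5.0       # um
    axial_period: float = 1.0          # s
    torsion_sd: float = 0.15           # deg
    scale_sd: float = 0.005            # fraction
    drift_segment_s: float = 0.25      # duration of each linear drift segment
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "drift_speed",
            "tremor_amplitude",
            "tremor_period",
            "microsaccade_rate",
            "microsaccade_amplitude",
            "microsaccade_duration",
            "axial_amplitude",
            "axial_period",
            "torsion_sd",
            "scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def build_phantom(
    size_um: tuple[float, float, float],
    cone_spacing: float,
    layers: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
    mosaic_jitter: float = 0.0,
    grid_pitch: float = 1.0,
    background: float = 0.02,
    texture_contrast: float = 0.5,
    texture_scale_um: float = 0.8,
) -> Phantom:
    """Build a hexagonal cone-mosaic phantom with reflective depth bands.

    Cones sit on a hexagonal lattice (spacing ``cone_spacing`` um, optional
    positional jitter) and are rendered as Gaussian bright spots; each
    reflective band modulates the mosaic along depth with a Gaussian
    profile.  A static multiplicative texture (correlation length
    ``texture_scale_um``) emulates the fixed sub-cellular scatterer
    structure that makes real OCT reflectance broadband — without it the
    phantom is too spectrally smooth for phase correlation to behave as it
    does on real data.  The field is continuous via trilinear
    interpolation of a fine grid (``grid_pitch`` um per voxel) and is
    deterministic given ``seed``.
    """
    if cone_spacing <= 0:
        raise ValueError("cone_spacing must be positive")
    sx, sy, sz = size_um
    if sx < 10 * cone_spacing or sy < 10 * cone_spacing:
        raise ValueError("phantom must contain at least a 10x10 cone field")
    layers = DEFAULT_LAYERS if layers is None else list(layers)
    for z0, th, _ in layers:
        if not (0.0 <= z0 - th / 2 and z0 + th / 2 <= sz):
            raise ValueError("layer depth ranges must lie inside the phantom")
    rng = np.random.default_rng(seed)

    # hexagonal lattice of cone centers, rows along x
    row_pitch = cone_spacing * np.sqrt(3) / 2
    centers = []
    row = 0
    y = 0.0
    while y <= sy:
        x0 = (cone_spacing / 2) if (row % 2) else 0.0
        xs = np.arange(x0, sx + 1e-9, cone_spacing)
        for x in xs:
            centers.append((x, y))
        row += 1
        y = row * row_pitch
    centers = np.asarray(centers, dtype=float)
    if mosaic_jitter > 0:
        centers = centers + rng.normal(0.0, mosaic_jitter, size=centers.shape)

    nx = int(round(sx / grid_pitch)) + 1
    ny = int(round(sy / grid_pitch)) + 1
    nz = int(round(sz / grid_pitch)) + 1

    # en-face mosaic: exact Gaussian spots stamped on local patches
    sigma = cone_spacing / 4.0
    half = max(2, int(np.ceil(4 * sigma / grid_pitch)))
    mosaic = np.zeros((ny, nx), dtype=np.float64)
    for cx, cy in centers:
        ix, iy = int(round(cx / grid_pitch)), int(round(cy / grid_pitch))
        x_lo, x_hi = max(0, ix - half), min(nx, ix + half + 1)
        y_lo, y_hi = max(0, iy - half), min(ny, iy + half + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.arange(x_lo, x_hi) * grid_pitch - cx
        gy = np.arange(y_lo, y_hi) * grid_pitch - cy
        patch = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma**2))
        mosaic[y_lo:y_hi, x_lo:x_hi] += patch

    # depth profile: sum of Gaussian bands
    zs = np.arange(nz) * grid_pitch
    profile = np.zeros(nz)
    for z0, th, brightness in layers:
        sz_band = th / 2.355  # FWHM -> sigma
        profile += brightness * np.exp(-((zs - z0) ** 2) / (2 * sz_band**2))

    reflectance = background + mosaic[:, None, :] * profile[None, :, None]
    if texture_contrast > 0:
        from scipy import ndimage

        tex = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, reflectance.shape), texture_scale_um / grid_pitch
        )
        tex /= max(tex.std(), 1e-12)
        reflectance = reflectance * (1.0 + texture_contrast * np.clip(tex, -1.8, 1.8))
    reflectance = np.clip(reflectance, 0.0, None).astype(np.float32)
    return Phantom(
        reflectance=reflectance,
        grid_pitch=grid_pitch,
        size_um=(sx, sy, sz),
        layers=layers,
        cone_spacing=cone_spacing,
        mosaic_jitter=mosaic_jitter,
        cone_centers=centers,
    )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_motion(
    duration_s: float,
    params: MotionParams,
    bscan_rate: float,
    torsion_deg: float | None = None,
    scale: float | None = None,
) -> MotionTrace:
    """Simulate a fixational eye/head motion trace sampled per B-scan interval.

    The trace is the sum of a piecewise-linear random-walk drift, a
    randomized-phase tremor sinusoid, Poisson-scheduled microsaccade steps
    (smooth ramps of the stated duration), and an axial sinusoidal ripple.
    Torsion and scale are drawn once (per volume/video) from their stated
    SDs unless given explicitly.  All-zero parameters yield a constant
    trace; a fixed seed fixes the full realization.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    dt_ms = 1000.0 / bscan_rate
    n = int(np.ceil(duration_s * 1000.0 / dt_ms)) + 1
    t_ms = np.arange(n) * dt_ms
    xyz = np.zeros((n, 3))

    # drift: piecewise-linear segments at drift_speed whose direction is
    # biased back toward the fixation point, so excursions stay bounded at
    # ~drift_range (fixation is a slow position-control loop, not a free
    # random walk)
    if params.drift_speed > 0:
        seg_ms = params.drift_segment_s * 1000.0
        n_seg = int(np.ceil(t_ms[-1] / seg_ms)) + 1
        knots_t = np.arange(n_seg + 1) * seg_ms
        step = params.drift_speed * seg_ms / 1000.0
        rng_range = max(params.drift_range, 1e-9)
        knots_xy = np.zeros((n_seg + 1, 2))
        pos = np.zeros(2)
        for k in range(n_seg):
            angle = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(angle), np.sin(angle)]) - pos / rng_range
            direction /= max(np.linalg.norm(direction), 1e-12)
            pos = pos + step * direction
            knots_xy[k + 1] = pos
        xyz[:, 0] += np.interp(t_ms, knots_t, knots_xy[:, 0])
        xyz[:, 1] += np.interp(t_ms, knots_t, knots_xy[:, 1])

    # tremor: sinusoid with randomized phase per axis
    if params.tremor_amplitude > 0 and params.tremor_period > 0:
        for axis in (0, 1):
            phase = rng.uniform(0, 2 * np.pi)
            xyz[:, axis] += params.tremor_amplitude * np.sin(
                2 * np.pi * t_ms / params.tremor_period + phase
            )

    # microsaccades: Poisson-scheduled smooth steps
    saccades: list[tuple[float, float]] = []
    if params.microsaccade_rate > 0 and params.microsaccade_amplitude > 0:
        t = rng.exponential(1000.0 / params.microsaccade_rate)
        while t < t_ms[-1]:
            t_end = t + params.microsaccade_duration
            angle = rng.uniform(0, 2 * np.pi)
            ramp = _smoothstep((t_ms - t) / params.microsaccade_duration)
            xyz[:, 0] += params.microsaccade_amplitude * np.cos(angle) * ramp
            xyz[:, 1] += params.microsaccade_amplitude * np.sin(angle) * ramp
            saccades.append((t, t_end))
            t += params.microsaccade_duration + rng.exponential(
                1000.0 / params.microsaccade_rate
            )

    # axial head-motion ripple
    if params.axial_amplitude > 0 and params.axial_period > 0:
        phase = rng.uniform(0, 2 * np.pi)
        xyz[:, 2] += params.axial_amplitude * np.sin(
            2 * np.pi * t_ms / (params.axial_period * 1000.0) + phase
        )

    if torsion_deg is None:
        torsion_deg = float(rng.normal(0.0, params.torsion_sd)) if params.torsion_sd > 0 else 0.0
    if scale is None:
        scale = float(rng.normal(1.0, params.scale_sd)) if params.scale_sd > 0 else 1.0

    return MotionTrace(
        t_ms=t_ms,
        xyz_um=xyz,
        torsion_deg=torsion_deg,
        scale=scale,
        saccade_intervals_ms=saccades,
    )


def acquire_volume(
    phantom: Phantom,
    trace: MotionTrace,
    scan: ScanParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0_ms: float = 0.0,
    speckle_contrast: float = 0.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[Volume, np.ndarray]:
    """Raster-sample the phantom under the motion trace into one volume.

    B-scan ``i`` is acquired at time ``t0_ms + i / bscan_rate``; all its
    A-lines share that single motion sample (B-scan rigidity).  The scanner
    raster position is rotated by the trace's torsion about the volume
    center and scaled isotropically, and the eye translation is subtracted
    (beam at apparatus position ``a`` images retina ``a - eye``).
    Multiplicative speckle-like noise and an additive floor are applied.

    Returns the volume and the per-B-scan ground-truth eye position in
    pixels, in the same (target minus reference) sign convention as the
    displacements estimated by the registration stages: registering this
    volume against a motion-free raster should recover these values.
    """
    rng = np.random.default_rng(seed)
    px, py, pz = scan.pitch
    t_bscan = t0_ms + np.arange(scan.n_y) * scan.bscan_period_ms
    if t_bscan[-1] > trace.t_ms[-1] + 1e-9 or t_bscan[0] < trace.t_ms[0] - 1e-9:
        raise ValueError("motion trace does not cover the volume acquisition span")
    eye_um = trace.sample(t_bscan)  # (n_y, 3)

    ox, oy = origin_um
    x_scan = ox + scan.fast_positions() * px          # (n_x,) um
    z_scan = np.arange(scan.n_z) * pz                 # (n_z,) um
    cx = ox + (scan.n_x - 1) * px / 2.0
    cy = oy + (scan.n_y - 1) * py / 2.0

    theta = np.deg2rad(trace.torsion_deg)
    m = trace.scale * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )

    intensity = np.empty((scan.n_y, scan.n_z, scan.n_x), dtype=np.float32)
    for i in range(scan.n_y):
        y_scan = oy + i * py
        # torsion/scale act on the en-face raster position about the center
        dx = x_scan - cx
        dy = y_scan - cy
        x_eff = m[0, 0] * dx + m[0, 1] * dy + cx
        y_eff = m[1, 0] * dx + m[1, 1] * dy + cy
        xs = x_eff - eye_um[i, 0]
        ys = y_eff - eye_um[i, 1]
        zs = z_scan - eye_um[i, 2]
        xx = np.broadcast_to(xs[None, :], (scan.n_z, scan.n_x))
        yy = np.full((scan.n_z, scan.n_x), 0.0) + ys[None, :]
        zz = np.broadcast_to(zs[:, None], (scan.n_z, scan.n_x))
        intensity[i] = phantom.sample(xx.ravel(), yy.ravel(), zz.ravel()).reshape(
            scan.n_z, scan.n_x
        )

    if speckle_contrast > 0:
        mult = 1.0 + speckle_contrast * (
            rng.exponential(1.0, size=intensity.shape) - 1.0
        )
        intensity = intensity * mult.astype(np.float32)
    if noise_sd > 0:
        intensity = intensity + rng.rayleigh(noise_sd, size=intensity.shape).astype(
            np.float32
        )

    gt_px = eye_um / np.array([px, py, pz])
    vol = Volume(intensity=intensity, pitch=scan.pitch, bscan_rate=scan.bscan_rate)
    return vol, gt_px


def simulate_video(
    phantom: Phantom,
    scan: ScanParams,
    params: MotionParams,
    n_volumes: int,
    seed: int = 0,
    torsion_deg: float | None = None,
    scale: float | None = None,
    noise_sd: float = 0.0,
    speckle_contrast: float = 0.3,
    video: int = 0,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[list[Volume], list[np.ndarray], MotionTrace]:
    """Acquire a video: ``n_volumes`` volumes under one continuous motion trace.

    Torsion and scale are held constant within the video (they vary between
    videos); volumes are spaced by the volume rate, so the trace includes
    the flyback dead time between them.
    """
    vol_period_ms = 1000.0 / scan.volume_rate
    if vol_period_ms < scan.volume_span_ms:
        vol_period_ms = scan.volume_span_ms
    duration_s = (vol_period_ms * n_volumes) / 1000.0 + 0.01
    p = MotionParams(**{**params.__dict__, "seed": seed})
    trace = simulate_motion(
        duration_s, p, scan.bscan_rate, torsion_deg=torsion_deg, scale=scale
    )
    volumes, truths = [], []
    for t in range(n_volumes):
        vol, gt = acquire_volume(
            phantom,
            trace,
            scan,
            noise_sd=noise_sd,
            seed=seed * 1009 + t,
            t0_ms=t * vol_period_ms,
            speckle_contrast=speckle_contrast,
            origin_um=origin_um,
        )
        vol.video = video
        vol.index = t
        volumes.append(vol)
        truths.append(gt)
    return volumes, truths, trace


#: Named motion presets for the command line simulator.
PRESETS: dict[str, MotionParams] = {
    "drift": MotionParams(
        tremor_amplitude=0.0, microsaccade_rate=0.0, axial_amplitude=0.0,
        torsion_sd=0.0, scale_sd=0.0,
    ),
    "tremor": MotionParams(
        drift_speed=0.0, microsaccade_rate=0.0, axial_amplitude=0.0,
        torsion_sd=0.0, scale_sd=0.0,
    ),
    "microsaccade": MotionParams(
        drift_speed=0.0, tremor_amplitude=0.0, axial_amplitude=0.0,
        microsaccade_rate=2.0, torsion_sd=0.0, scale_sd=0.0,
    ),
    "full": MotionParams(),
}
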