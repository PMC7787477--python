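"""Pre-registration conditioning: fast-axis rectification, tilt correction,
intensity normalization, cropping, and reference-volume selection.

These steps put a batch of volumes into the common, noise-floored,
uniformly sampled state the correlation stages assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = [
    "NormalizationParams",
    "ReferenceScore",
    "rectify_fast_axis",
    "normalize_intensity",
    "reference_quality_metric",
    "select_reference",
    "crop_batch",
]

#: Floor added to standard deviations in the reference-quality metric so
#: that perfectly clean (zero-variance) synthetic volumes stay finite.
EPSILON = 1e-6

#: Full-scale value of normalized volumes.
NORM_SCALE = 1e5


@dataclass
class NormalizationParams:
    """Noise offset ``N`` and saturation level ``M`` for normalization.

    ``M`` is typically set 35-40 dB above the noise offset; the default
    auto-estimation uses the midpoint, 37.5 dB.
    """

    noise_offset: float
    saturation: float
    scale: float = NORM_SCALE

    def __post_init__(self) -> None:
        if self.saturation <= self.noise_offset:
            raise ValueError("saturation level M must exceed noise offset N")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class ReferenceScore:
    """Quality score of a volume as a registration reference.

    ``m = r_bar / ((sigma_r + eps) * (sigma_dx + eps))`` where ``r_bar`` is
    the mean peak correlation between en-face projections of adjacent fast
    B-scans, ``sigma_r`` the SD of those peaks, and ``sigma_dx`` the SD of
    the lateral offsets at which they occur.  Motion shears the en-face
    image (raising ``sigma_dx``); noise lowers ``r_bar`` and raises both
    SDs — so the best reference maximizes ``m``.
    """

    m: float
    r_bar: float
    sigma_r: float
    sigma_dx: float
    degenerate: bool = False


def rectify_fast_axis(
    volume: Volume,
    scan_pattern: np.ndarray | None = None,
    tilt: float | str | None = None,
) -> Volume:
    """Resample A-lines to uniform fast-axis spacing and remove B-scan tilt.

    ``scan_pattern`` is the monotone lookup of fast-axis position per
    A-line index (unit-normalized); each (y, z) row is linearly resampled
    from those positions onto a uniform grid ("de-sinusoiding").  ``tilt``
    is a depth shear in z pixels per A-line, or ``"auto"`` to estimate it
    by regressing the axial centroid of the brightest layer on x; the shear
    is removed by per-A-line linear interpolation along z.
    """
    data = volume.intensity
    n_y, n_z, n_x = data.shape

    if scan_pattern is not None:
        pattern = np.asarray(scan_pattern, dtype=float)
        if pattern.size != n_x:
            raise ValueError("scan_pattern must have one entry per A-line")
        if not np.all(np.diff(pattern) > 0):
            raise ValueError("scan_pattern must be strictly monotone increasing")
        pos = (pattern - pattern[0]) / (pattern[-1] - pattern[0]) * (n_x - 1)
        uniform = np.arange(n_x, dtype=float)
        if not np.allclose(pos, uniform):
            flat = data.reshape(-1, n_x)
            out = np.empty_like(flat)
            for r in range(flat.shape[0]):
                out[r] = np.interp(uniform, pos, flat[r])
            data = out.reshape(n_y, n_z, n_x)

    if tilt is not None:
        slope = _estimate_tilt(data) if tilt == "auto" else float(tilt)
        if slope != 0.0:
            data = _shear_depth(data, slope)
    return volume.with_intensity(data)


def _estimate_tilt(data: np.ndarray) -> float:
    """Tilt slope (z px per A-line) from the brightest layer's axial centroid.

    For each A-line the axial centroid is intensity-weighted around the
    global brightest depth; the slope of centroid vs x, averaged over
    B-scans, is the tilt estimate.
    """
    n_y, n_z, n_x = data.shape
    mean_bscan = data.mean(axis=0)  # (n_z, n_x)
    w = mean_bscan - mean_bscan.min()
    z = np.arange(n_z, dtype=float)
    denom = w.sum(axis=0)
    denom[denom == 0] = 1.0
    centroid = (w * z[:, None]).sum(axis=0) / denom  # (n_x,)
    x = np.arange(n_x, dtype=float)
    slope = float(np.polyfit(x, centroid, 1)[0])
    return slope


def _shear_depth(data: np.ndarray, slope: float) -> np.ndarray:
    """Remove a depth tilt of ``slope`` z px per A-line (linear interp):
    content at ``z0 + slope*(x - x_c)`` returns to ``z0``."""
    n_y, n_z, n_x = data.shape
    z = np.arange(n_z, dtype=float)
    x_c = (n_x - 1) / 2.0
    out = np.empty_like(data)
    for ix in range(n_x):
        shift = slope * (ix - x_c)
        src = z + shift
        for iy in range(n_y):
            out[iy, :, ix] = np.interp(src, z, data[iy, :, ix], left=0.0, right=0.0)
    return out


def normalize_intensity(
    volume: Volume,
    params: NormalizationParams | str = "auto",
    vitreous_fraction: float = 0.1,
    m_db_above_n: float = 37.5,
) -> Volume:
    """Clip-and-rescale intensities into ``[0, 1e5]`` single precision.

    Values at or above the saturation level ``M`` map to the full scale,
    values below the noise offset ``N`` map to zero, and the span in
    between maps linearly.  With ``params="auto"``, ``N`` is the 95th
    percentile of the vitreous (the top ``vitreous_fraction`` of depth
    pixels, which contains no reflective structure) and ``M`` sits
    ``m_db_above_n`` dB above it.
    """
    data = volume.intensity
    if isinstance(params, str):
        if params != "auto":
            raise ValueError("params must be NormalizationParams or 'auto'")
        n_vitreous = max(1, int(round(vitreous_fraction * data.shape[1])))
        vitreous = data[:, :n_vitreous, :]
        n = float(np.percentile(vitreous, 95))
        if n <= 0:
            n = max(float(data.mean()) * 1e-3, 1e-12)
        m = n * 10.0 ** (m_db_above_n / 10.0)
        params = NormalizationParams(noise_offset=n, saturation=m)
    n, m, scale = params.noise_offset, params.saturation, params.scale
    out = (data.astype(np.float64) - n) / (m - n) * scale
    out = np.clip(out, 0.0, scale)
    return volume.with_intensity(out.astype(np.float32))


def _ncc_1d(a: np.ndarray, b: np.ndarray, max_lag: int) -> tuple[float, int]:
    """Peak normalized correlation between two 1D lines within ``±max_lag``.

    Returns (peak coefficient, lag at peak); ties break toward the smallest
    |lag| then the smaller lag.  Degenerate (constant) overlaps score 0.
    """
    n = a.size
    best_r, best_lag = -np.inf, 0
    lags = sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l))
    for lag in lags:
        if lag >= 0:
            s_a, s_b = a[lag:], b[: n - lag]
        else:
            s_a, s_b = a[: n + lag], b[-lag:]
        if s_a.size < 2:
            continue
        da = s_a - s_a.mean()
        db = s_b - s_b.mean()
        denom = np.sqrt((da**2).sum() * (db**2).sum())
        r = float((da * db).sum() / denom) if denom > 0 else 0.0
        if r > best_r + 1e-12:
            best_r, best_lag = r, lag
    return best_r, best_lag


def reference_quality_metric(volume: Volume, max_lag: int = 16) -> ReferenceScore:
    """Score a volume's suitability as a reference from en-face line coherence.

    The en-face projection (mean over depth) is computed; for each pair of
    adjacent lines the 1D normalized cross-correlation peak ``r`` and its
    lateral offset are recorded, and ``m = r_bar / ((σ_r + ε)(σ_Δx + ε))``.
    """
    if volume.n_y < 3:
        raise ValueError("reference metric needs at least 3 B-scans")
    enface = volume.intensity.mean(axis=1)  # (n_y, n_x)
    peaks, offsets = [], []
    for i in range(volume.n_y - 1):
        r, lag = _ncc_1d(enface[i], enface[i + 1], max_lag)
        peaks.append(r)
        offsets.append(lag)
    peaks = np.asarray(peaks)
    offsets = np.asarray(offsets, dtype=float)
    r_bar = float(peaks.mean())
    sigma_r = float(peaks.std())
    sigma_dx = float(offsets.std())
    degenerate = sigma_r == 0.0 or sigma_dx == 0.0
    m = r_bar / ((sigma_r + EPSILON) * (sigma_dx + EPSILON))
    return ReferenceScore(
        m=m, r_bar=r_bar, sigma_r=sigma_r, sigma_dx=sigma_dx, degenerate=degenerate
    )


def select_reference(volumes: list[Volume]) -> int:
    """Index of the volume with the largest quality metric (ties: lowest index)."""
    if not volumes:
        raise ValueError("cannot select a reference from an empty list")
    scores = [reference_quality_metric(v).m for v in volumes]
    return int(np.argmax(scores))  # argmax returns the first maximum


def crop_batch(
    volumes: list[Volume], max_bscan: tuple[int, int] = (512, 512)
) -> list[Volume]:
    """Center-crop all volumes to the minimum common (z, x) B-scan extent.

    The common extent is additionally clamped to ``max_bscan`` (z, x),
    defaulting to the 512x512 processing cap.  Output shapes are equal.
    """
    if not volumes:
        return []
    z_min = min(v.n_z for v in volumes)
    x_min = min(v.n_x for v in volumes)
    z_out = min(z_min, max_bscan[0])
    x_out = min(x_min, max_bscan[1])
    out = []
    for v in volumes:
        z0 = (v.n_z - z_out) // 2
        x0 = (v.n_x - x_out) // 2
        out.append(v.with_intensity(v.intensity[:, z0 : z0 + z_out, x0 : x0 + x_out]))
    return out
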