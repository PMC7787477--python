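"""Image-quality metrics for evaluating registration of cone-mosaic images.

A well-registered average sharpens the cone mosaic: power concentrates at
the mosaic's fundamental spatial frequency (the inverse cone spacing) and
the high-frequency noise floor drops.  The metrics here quantify that:
relative power spectral contrast between two en-face images, image
sharpness ratio (ISR), mean squared error (MSE), and the cone-mosaic
spectral signal-to-noise ratio, all built on circumferentially averaged
power spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .volume import Volume

__all__ = [
    "EnFaceImage",
    "enface_projection",
    "radial_power_profile",
    "relative_spectral_contrast",
    "isr",
    "mse",
    "mosaic_snr",
    "axis_power_spectrum",
    "axis_mosaic_snr",
    "db_percent",
]


@dataclass
class EnFaceImage:
    """A 2D en-face intensity image with its pixel pitch (x, y) in um/px."""

    data: np.ndarray
    pitch: tuple[float, float] = (1.0, 1.0)  # (x, y) um/px

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("en-face image must be 2D (y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("en-face image must be finite")
        if min(self.pitch) <= 0:
            raise ValueError("pixel pitch must be positive")


def enface_projection(volume: Volume, z_band: tuple[int, int] | None = None) -> EnFaceImage:
    """Mean-over-depth projection of a volume onto the (y, x) plane.

    ``z_band`` is a half-open depth index range; ``None`` projects the full
    depth extent.
    """
    if z_band is None:
        z_band = (0, volume.n_z)
    z0, z1 = z_band
    if not (0 <= z0 < z1 <= volume.n_z):
        raise ValueError("z_band must be a non-empty range within the depth extent")
    img = volume.intensity[:, z0:z1, :].mean(axis=1)
    return EnFaceImage(data=img, pitch=(volume.pitch[0], volume.pitch[1]))


def _power_spectrum(image: EnFaceImage) -> tuple[np.ndarray, np.ndarray]:
    """Windowed 2D power spectrum and the radial frequency of each bin.

    The image is mean-subtracted and Hann-windowed (leakage control) before
    the FFT; returns (power, radius) with radius in cycles/um.
    """
    img = image.data
    h, w = img.shape
    win = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    spec = sp_fft.fft2((img - img.mean()) * win)
    power = np.abs(spec) ** 2
    fy = sp_fft.fftfreq(h, d=image.pitch[1])
    fx = sp_fft.fftfreq(w, d=image.pitch[0])
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return power, radius


def radial_power_profile(image: EnFaceImage) -> tuple[np.ndarray, np.ndarray]:
    """Circumferential average of the 2D power spectrum.

    Returns ``(freqs, profile)``: annulus-center frequencies (cycles/um)
    and the mean power within each one-bin-wide annulus, DC excluded.
    """
    h, w = image.data.shape
    if min(h, w) < 16:
        raise ValueError("image too small for a meaningful radial profile")
    power, radius = _power_spectrum(image)
    df = 1.0 / min(h * image.pitch[1], w * image.pitch[0])
    bins = np.round(radius / df).astype(int)
    n_bins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=power.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    freqs = np.arange(n_bins) * df
    return freqs[1:], profile[1:]  # DC excluded


def _band_power(
    freqs: np.ndarray, profile: np.ndarray, f_c: float, band_bins: int = 1
) -> float:
    """Mean profile power over a ``band_bins``-wide band centered at ``f_c``."""
    if not (freqs[0] <= f_c <= freqs[-1]):
        raise ValueError("cone frequency outside the resolvable band")
    center = int(np.argmin(np.abs(freqs - f_c)))
    half = (band_bins - 1) // 2
    lo, hi = max(0, center - half), min(freqs.size, center + half + 1)
    return float(profile[lo:hi].mean())


def relative_spectral_contrast(
    avg: EnFaceImage, ref: EnFaceImage, cone_period_um: float, band_bins: int = 1
) -> float:
    """Power ratio (dB) between two images at the cone-spacing frequency.

    ``10 log10(P_avg(f_c) / P_ref(f_c))`` with ``f_c = 1/cone_period`` read
    from the radial power profile over a one-bin band.  Positive values
    mean the first image carries more cone-mosaic power.
    """
    if avg.data.shape != ref.data.shape:
        raise ValueError("images must share extents")
    f_c = 1.0 / cone_period_um
    fa, pa = radial_power_profile(avg)
    fr, pr = radial_power_profile(ref)
    p_avg = _band_power(fa, pa, f_c, band_bins)
    p_ref = _band_power(fr, pr, f_c, band_bins)
    if p_ref <= 0:
        raise ValueError("reference has zero power at the cone frequency")
    return 10.0 * np.log10(p_avg / p_ref)


def isr(avg: EnFaceImage, ref: EnFaceImage, mask: np.ndarray | None = None) -> float:
    """Image sharpness ratio: gradient-magnitude energy of ``avg`` over ``ref``.

    Central-difference gradients (one-sided at borders), summed over the
    pixels common to both images (``mask``, default all); blurring by
    residual misregistration reduces the numerator, so values below 1 mean
    the average is softer than the reference.
    """
    if avg.data.shape != ref.data.shape:
        raise ValueError("images must share extents")
    if mask is None:
        mask = np.ones(avg.data.shape, dtype=bool)

    def grad_energy(img: np.ndarray) -> float:
        gy, gx = np.gradient(img)
        return float(np.sqrt(gy**2 + gx**2)[mask].sum())

    denom = grad_energy(ref.data)
    if denom == 0:
        raise ValueError("reference image has zero gradient energy")
    return grad_energy(avg.data) / denom


def mse(avg: EnFaceImage, ref: EnFaceImage, mask: np.ndarray | None = None) -> float:
    """Mean squared intensity difference over the pixels common to both."""
    if avg.data.shape != ref.data.shape:
        raise ValueError("images must share extents")
    if mask is None:
        mask = np.ones(avg.data.shape, dtype=bool)
    return float(np.mean((avg.data - ref.data)[mask] ** 2))


def mosaic_snr(
    image: EnFaceImage,
    cone_period_um: float,
    noise_band: tuple[float, float] | None = None,
    band_bins: int = 1,
) -> float:
    """Cone-mosaic spectral SNR in dB.

    Ratio of radial-profile power at the cone-spacing frequency to the
    noise floor, taken as the median power over ``noise_band`` (cycles/um;
    default the top 20% of resolvable radial frequencies, which must lie
    above the cone frequency).
    """
    f_c = 1.0 / cone_period_um
    freqs, profile = radial_power_profile(image)
    f_nyq = freqs[-1]
    if noise_band is None:
        noise_band = (0.8 * f_nyq, f_nyq)
    lo, hi = noise_band
    if lo <= f_c:
        raise ValueError("noise band must lie strictly above the cone frequency")
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError("noise band is empty")
    signal = _band_power(freqs, profile, f_c, band_bins)
    floor = float(np.median(profile[sel]))
    if floor <= 0:
        raise ValueError("noise floor is zero; SNR undefined")
    return 10.0 * np.log10(signal / floor)


def axis_power_spectrum(
    image: EnFaceImage, axis: str
) -> tuple[np.ndarray, np.ndarray]:
    """1D power spectrum along one scan axis, averaged over lines.

    ``axis="fast"`` analyses each row (the fast-scan x direction),
    ``axis="slow"`` each column; lines are mean-subtracted and
    Hann-windowed.  Used to compare sampling regularity between the two
    scan directions, which registration affects very differently.
    """
    img = image.data
    if axis == "fast":
        lines, pitch = img, image.pitch[0]
    elif axis == "slow":
        lines, pitch = img.T, image.pitch[1]
    else:
        raise ValueError("axis must be 'fast' or 'slow'")
    n = lines.shape[1]
    win = np.hanning(n)[None, :]
    spec = sp_fft.rfft((lines - lines.mean(axis=1, keepdims=True)) * win, axis=1)
    power = (np.abs(spec) ** 2).mean(axis=0)
    freqs = sp_fft.rfftfreq(n, d=pitch)
    return freqs[1:], power[1:]


def axis_mosaic_snr(
    image: EnFaceImage,
    cone_period_um: float,
    axis: str,
    noise_band: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Per-axis cone SNR (dB) and noise floor (dB rel. total power).

    Returns ``(snr_db, floor_db)``; the floor is the median noise-band
    power relative to the spectrum's total power, so floors are comparable
    between axes and registration stages.
    """
    freqs, profile = axis_power_spectrum(image, axis)
    f_c = 1.0 / cone_period_um
    f_nyq = freqs[-1]
    if noise_band is None:
        noise_band = (0.8 * f_nyq, f_nyq)
    lo, hi = noise_band
    if lo <= f_c:
        raise ValueError("noise band must lie strictly above the cone frequency")
    sel = (freqs >= lo) & (freqs <= hi)
    signal = _band_power(freqs, profile, f_c)
    floor = float(np.median(profile[sel]))
    if floor <= 0 or signal <= 0:
        raise ValueError("degenerate spectrum; per-axis SNR undefined")
    total = float(profile.sum())
    return 10.0 * np.log10(signal / floor), 10.0 * np.log10(floor / total)


def db_percent(db: float, round_percent: bool = True) -> float:
    """Convert a power ratio in decibels to a percent increase.

    ``100 * (10^(dB/10) - 1)``, optionally rounded to the nearest integer
    percent (e.g. 1.37 dB -> 37%, 9.4 dB -> 771%).
    """
    if not np.isfinite(db):
        raise ValueError("dB value must be finite")
    pct = 100.0 * (10.0 ** (db / 10.0) - 1.0)
    return float(round(pct)) if round_percent else float(pct)
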