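"""Core in-memory containers shared by every pipeline stage.

Axis convention (fixed throughout the package): volume arrays are indexed
``(y, z, x)`` — slow-scan B-scan index first, then depth, then fast-scan
A-line index.  Displacement vectors are always ordered ``(dx, dy, dz)`` in
pixels.  Angles are degrees, pitches are micrometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Volume",
    "MotionTrace",
    "ScanParams",
    "Phantom",
]


@dataclass
class Volume:
    """A single AO-OCT volume: a stack of fast B-scans along the slow axis.

    Parameters
    ----------
    intensity
        Array of shape ``(n_y, n_z, n_x)``, single precision.
    pitch
        Pixel pitch ``(x, y, z)`` in micrometres per pixel.
    bscan_rate
        Fast B-scan acquisition rate in Hz (used to convert time windows
        into B-scan counts).
    video, index
        Acquisition identifiers: video number and volume number within the
        acquisition series.
    """

    intensity: np.ndarray
    pitch: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bscan_rate: float = 1100.0
    video: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 3:
            raise ValueError(
                f"volume intensity must be 3D (y, z, x); got {self.intensity.ndim}D"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("volume intensity must be finite")

    @property
    def n_y(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_z(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_x(self) -> int:
        return self.intensity.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def with_intensity(self, intensity: np.ndarray) -> "Volume":
        """Copy of this volume with new intensity data, metadata preserved."""
        return replace(self, intensity=np.asarray(intensity, dtype=np.float32))


@dataclass
class MotionTrace:
    """Eye/head pose over time, one translation sample per fast B-scan.

    ``t_ms`` are strictly increasing timestamps; ``xyz_um`` holds the eye
    position (x, y, z) in micrometres at each timestamp.  B-scans are rigid,
    so a single sample applies to every A-line of a B-scan.  Torsion (deg)
    and isotropic scale are drawn once per volume/video.
    """

    t_ms: np.ndarray
    xyz_um: np.ndarray  # shape (n, 3) ordered (x, y, z)
    torsion_deg: float = 0.0
    scale: float = 1.0
    saccade_intervals_ms: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float)
        if self.xyz_um.shape != (self.t_ms.size, 3):
            raise ValueError("xyz_um must have shape (len(t_ms), 3)")
        if self.t_ms.size > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t_ms.size

    def sample(self, t_ms: np.ndarray) -> np.ndarray:
        """Interpolate the (x, y, z) eye position at arbitrary times (ms)."""
        t_ms = np.atleast_1d(np.asarray(t_ms, dtype=float))
        if t_ms.min() < self.t_ms[0] - 1e-9 or t_ms.max() > self.t_ms[-1] + 1e-9:
            raise ValueError("requested times fall outside the motion trace span")
        out = np.empty((t_ms.size, 3))
        for k in range(3):
            out[:, k] = np.interp(t_ms, self.t_ms, self.xyz_um[:, k])
        return out


def _default_pattern() -> np.ndarray:
    return np.array([], dtype=float)


@dataclass
class ScanParams:
    """Raster-scan geometry and timing.

    ``scan_pattern`` maps A-line index to a unit-normalized fast-axis
    position; it must be strictly increasing.  An empty pattern means a
    perfectly linear scanner.
    """

    n_x: int = 96
    n_z: int = 96
    n_y: int = 64
    bscan_rate: float = 1100.0
    pitch: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z) um/px
    scan_pattern: np.ndarray = field(default_factory=_default_pattern)
    volume_rate: float = 2.4

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.bscan_rate <= 0:
            raise ValueError("bscan_rate must be positive")
        self.scan_pattern = np.asarray(self.scan_pattern, dtype=float)
        if self.scan_pattern.size:
            if self.scan_pattern.size != self.n_x:
                raise ValueError("scan_pattern must have one entry per A-line")
            if not np.all(np.diff(self.scan_pattern) > 0):
                raise ValueError("scan_pattern must be strictly monotone increasing")

    def fast_positions(self) -> np.ndarray:
        """Fast-axis positions of the A-lines in pixels (uniform if no pattern)."""
        if self.scan_pattern.size == 0:
            return np.arange(self.n_x, dtype=float)
        p = self.scan_pattern
        return (p - p[0]) / (p[-1] - p[0]) * (self.n_x - 1)

    @property
    def bscan_period_ms(self) -> float:
        return 1000.0 / self.bscan_rate

    @property
    def volume_span_ms(self) -> float:
        return self.n_y * self.bscan_period_ms


@dataclass
class Phantom:
    """Continuous cone-mosaic reflectance field sampled on a fine grid.

    ``reflectance`` is stored on a regular grid with ``grid_pitch`` um per
    voxel, axes ordered (y, z, x) like volumes; trilinear interpolation
    defines the field at any real-valued coordinate (um).  ``layers`` are
    (depth-center um, thickness um, brightness) reflective bands emulating
    the outer-retinal complex (IS/OS, COST, ROST, RPE).
    """

    reflectance: np.ndarray
    grid_pitch: float
    size_um: tuple[float, float, float]  # (x, y, z) extent
    layers: list[tuple[float, float, float]]
    cone_spacing: float
    mosaic_jitter: float = 0.0
    cone_centers: np.ndarray | None = None  # (n, 2) array of (x, y) um

    def __post_init__(self) -> None:
        if self.cone_spacing <= 0:
            raise ValueError("cone_spacing must be positive")
        if np.any(self.reflectance < 0):
            raise ValueError("reflectance must be non-negative")

    def sample(self, x_um: np.ndarray, y_um: np.ndarray, z_um: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the reflectance field at (x, y, z) um.

        Coordinates outside the phantom extent read as zero.
        """
        from scipy import ndimage

        coords = np.stack(
            [
                np.asarray(y_um, dtype=float) / self.grid_pitch,
                np.asarray(z_um, dtype=float) / self.grid_pitch,
                np.asarray(x_um, dtype=float) / self.grid_pitch,
            ]
        )
        return ndimage.map_coordinates(
            self.reflectance, coords, order=1, mode="constant", cval=0.0
        )
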