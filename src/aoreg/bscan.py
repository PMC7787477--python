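"""Coarse-to-fine 3D registration of fast B-scans to a reference volume.

The coarse stage applies 3D phase-only correlation (POC) to sub-volume
samples to sketch the slow-axis displacement trend; a linear interpolator
upsamples that trend into a per-B-scan position prediction; the fine stage
then registers each fast B-scan by overlap-normalized cross-correlation
(NCC) against the few reference B-scans inside the predicted search
window.  Displacements are pixel-level (no sub-pixel refinement), in the
target-minus-reference sign convention: a B-scan matched to reference
index ``j`` has ``dy = i - j`` and is placed at slot ``i - dy`` shifted
in-plane by ``(-dx, -dz)`` when a registered volume is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .volume import Volume

__all__ = [
    "CoarseSampling",
    "CoarseTrace",
    "BScanDisplacementSet",
    "CoarseRegistrationError",
    "ConstructionReport",
    "poc3d",
    "pad_for_poc",
    "coarse_trace",
    "predict_positions",
    "ncc_fine",
    "filter_outliers",
    "register_volume",
    "construct_registered",
    "average_registered",
]


class CoarseRegistrationError(RuntimeError):
    """Raised when too few coarse samples survive to predict B-scan positions."""


@dataclass
class CoarseSampling:
    """Coarse sub-volume sampling: interval ``s`` and half-width ``d`` (B-scans).

    Useful ranges are ``5 <= s <= 30`` and ``8 <= 2d <= 16``; halving ``s``
    (overlapping samples) increases robustness to large rapid movements.
    """

    s: int = 15
    d: int = 6
    overlap_mode: bool = False

    def __post_init__(self) -> None:
        if self.s <= 0 or self.d <= 0:
            raise ValueError("sampling interval s and half-width d must be positive")

    @property
    def effective_s(self) -> int:
        return max(1, self.s // 2) if self.overlap_mode else self.s


@dataclass
class CoarseTrace:
    """Per-sample coarse displacements from POC.

    ``centers`` are sample centers (B-scan index ``N*s``); ``disp`` holds
    (dx, dy, dz) per sample; ``valid`` marks samples retained for
    interpolation (POC succeeded, window not truncated, consistent with the
    displacement trend).
    """

    centers: np.ndarray
    disp: np.ndarray
    peak: np.ndarray
    valid: np.ndarray
    truncated: np.ndarray
    s: int


@dataclass
class BScanDisplacementSet:
    """Per-B-scan displacement estimates for one (target, reference) pair."""

    disp: np.ndarray          # (n_y, 3) float, (dx, dy, dz) px
    ncc: np.ndarray           # (n_y,) max NCC coefficient in [-1, 1]
    y_pred: np.ndarray        # (n_y,) predicted reference position
    matched: np.ndarray       # (n_y,) bool: a candidate window existed
    included: np.ndarray      # (n_y,) bool: survives outlier filtering
    bscan_rate: float = 1100.0
    sigma_delta: np.ndarray | None = None
    target_id: tuple[int, int] = (0, 0)
    reference_id: tuple[int, int] = (0, 0)

    @property
    def n_y(self) -> int:
        return self.disp.shape[0]


@dataclass
class ConstructionReport:
    """Slot bookkeeping of a constructed registered volume."""

    placed: int
    gaps: int
    excluded: int
    collided: int
    dropped: int
    n_y: int


# ---------------------------------------------------------------------------
# coarse stage: 3D phase-only correlation
# ---------------------------------------------------------------------------

def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def pad_for_poc(reference: np.ndarray, d: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Zero-pad a (y, z, x) reference volume for POC.

    z and x grow to the next greater power of two; y grows to the next
    greater multiple of the sample width ``2d`` (padding eliminates the
    wrap-around boundary effects of the circular correlation).
    """
    n_y, n_z, n_x = reference.shape
    width = 2 * d
    p_y = int(np.ceil((n_y + 1) / width)) * width
    p_z = _next_pow2(n_z + 1)
    p_x = _next_pow2(n_x + 1)
    out = np.zeros((p_y, p_z, p_x), dtype=np.float32)
    out[:n_y, :n_z, :n_x] = reference
    return out, (p_y, p_z, p_x)


def poc3d(
    target_padded: np.ndarray, reference_padded: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """3D phase-only correlation between equally padded volumes.

    The cross-power spectrum is normalized element-wise to unit magnitude
    (bins of zero magnitude map to zero), inverted, and the integer argmax
    decoded to signed shifts in ``[-dim/2, dim/2)`` per axis.  Argmax ties
    break by first occurrence in (z, x, y) scan order.

    Returns ``((dx, dy, dz), peak, valid)``; an all-zero input yields an
    invalid sample rather than an exception.
    """
    if target_padded.shape != reference_padded.shape:
        raise ValueError("POC inputs must have identical (padded) shapes")
    if not np.any(target_padded) or not np.any(reference_padded):
        return np.zeros(3), 0.0, False
    fa = sp_fft.fftn(target_padded)
    fb = sp_fft.fftn(reference_padded)
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(mag > 0, cross / mag, 0.0)
    corr = sp_fft.ifftn(r).real  # (y, z, x)
    zxy = np.transpose(corr, (1, 2, 0))  # tie-break in (z, x, y) scan order
    flat = int(np.argmax(zxy))
    iz, ix, iy = np.unravel_index(flat, zxy.shape)
    peak = float(zxy[iz, ix, iy])
    dims = target_padded.shape  # (y, z, x)
    dy = iy - dims[0] if iy >= dims[0] // 2 else iy
    dz = iz - dims[1] if iz >= dims[1] // 2 else iz
    dx = ix - dims[2] if ix >= dims[2] // 2 else ix
    return np.array([dx, dy, dz], dtype=float), peak, True


def _trend_filter(centers: np.ndarray, dy: np.ndarray, valid: np.ndarray, s: int) -> np.ndarray:
    """Drop coarse samples whose dy deviates from the local trend.

    A sample is an outlier when its dy differs by more than ``s`` from both
    of its nearest retained neighbors (a single neighbor at the edges);
    outliers are removed iteratively, worst first.  Genuine displacement
    steps (e.g. a microsaccade between samples) survive, because the
    samples on either side each agree with their outer neighbor.
    """
    valid = valid.copy()
    while True:
        idx = np.flatnonzero(valid)
        if idx.size < 3:
            break
        worst, worst_dev = -1, 0.0
        for k, i in enumerate(idx):
            devs = []
            if k > 0:
                devs.append(abs(dy[i] - dy[idx[k - 1]]))
            if k + 1 < idx.size:
                devs.append(abs(dy[i] - dy[idx[k + 1]]))
            if devs and min(devs) > s and max(devs) > worst_dev:
                worst, worst_dev = i, max(devs)
        if worst < 0:
            break
        valid[worst] = False
    return valid


def coarse_trace(
    target: Volume, reference: Volume, sampling: CoarseSampling | None = None
) -> CoarseTrace:
    """Coarse POC displacement trace of evenly spaced target sub-volumes.

    Sub-volumes of width ``2d`` centered at ``N*s`` are cut from the target,
    embedded at their native slow-axis offset in a zero canvas of the padded
    reference size, and phase-correlated against the padded reference.
    Samples whose window is clipped by a volume edge are computed but
    flagged invalid, as are samples deviating from the displacement trend.
    """
    sampling = sampling or CoarseSampling()
    if target.shape[1:] != reference.shape[1:]:
        raise ValueError("target and reference must share B-scan shape")
    s, d = sampling.effective_s, sampling.d
    ref_padded, padded_shape = pad_for_poc(reference.intensity, d)
    n_y = target.n_y
    centers = np.arange(s, n_y, s)
    if centers.size == 0:
        raise CoarseRegistrationError("volume too short for the sampling interval")
    disp = np.zeros((centers.size, 3))
    peaks = np.zeros(centers.size)
    ok = np.zeros(centers.size, dtype=bool)
    truncated = np.zeros(centers.size, dtype=bool)
    for k, c in enumerate(centers):
        lo, hi = c - d, c + d
        lo_c, hi_c = max(0, lo), min(n_y, hi)
        # clipped edge windows are retained while at least half the sample
        # width survives; narrower ones are flagged and excluded
        truncated[k] = (hi_c - lo_c) < d
        canvas = np.zeros(padded_shape, dtype=np.float32)
        canvas[lo_c:hi_c, : target.n_z, : target.n_x] = target.intensity[lo_c:hi_c]
        disp[k], peaks[k], ok[k] = poc3d(canvas, ref_padded)
    valid = ok & ~truncated
    valid = _trend_filter(centers, disp[:, 1], valid, s)
    if valid.sum() < 2:
        raise CoarseRegistrationError(
            "fewer than 2 valid coarse samples; volume unregistrable to this reference"
        )
    return CoarseTrace(
        centers=centers, disp=disp, peak=peaks, valid=valid, truncated=truncated, s=s
    )


def predict_positions(trace: CoarseTrace, n_bscans: int) -> tuple[np.ndarray, np.ndarray]:
    """Upsample the coarse dy trend to every B-scan by linear interpolation.

    Returns ``(y_pred, dy_pred)`` with ``y_pred[i] = i - dy_pred[i]``;
    positions beyond the outermost valid samples are linearly extrapolated
    from the nearest pair.
    """
    idx = np.flatnonzero(trace.valid)
    if idx.size < 2:
        raise CoarseRegistrationError("need at least 2 valid coarse samples")
    xs = trace.centers[idx].astype(float)
    ys = trace.disp[idx, 1]
    i = np.arange(n_bscans, dtype=float)
    dy = np.interp(i, xs, ys)
    # linear extrapolation at both ends from the nearest pair of samples
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    left = i < xs[0]
    right = i > xs[-1]
    dy[left] = ys[0] + lo_slope * (i[left] - xs[0])
    dy[right] = ys[-1] + hi_slope * (i[right] - xs[-1])
    y_pred = i - dy
    return y_pred, dy


# ---------------------------------------------------------------------------
# fine stage: overlap-normalized cross-correlation of individual B-scans
# ---------------------------------------------------------------------------

def _integral(img: np.ndarray) -> np.ndarray:
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _rect_sums(ii: np.ndarray, r0, r1, c0, c1) -> np.ndarray:
    """Rectangle sums from an integral image for row range r0:r1, col c0:c1."""
    return (
        ii[r1[:, None], c1[None, :]]
        - ii[r0[:, None], c1[None, :]]
        - ii[r1[:, None], c0[None, :]]
        + ii[r0[:, None], c0[None, :]]
    )


class _NccEngine:
    """FFT cross terms + integral-image normalization for full-extent NCC.

    Computes, for two equal-shape images, the normalized correlation
    coefficient at every integer shift with means and variances taken over
    the overlap region only, so zero padding never biases the coefficient.
    """

    def __init__(self, shape: tuple[int, int], min_overlap_frac: float = 0.5):
        h, w = shape
        self.h, self.w = h, w
        self.fshape = (sp_fft.next_fast_len(2 * h - 1), sp_fft.next_fast_len(2 * w - 1))
        u = np.concatenate([np.arange(0, h), np.arange(-(h - 1), 0)])
        v = np.concatenate([np.arange(0, w), np.arange(-(w - 1), 0)])
        self.u, self.v = u, v
        # overlap rectangle bounds in each image as a function of shift
        self.t_r0, self.t_r1 = np.maximum(0, u), np.minimum(h, h + u)
        self.t_c0, self.t_c1 = np.maximum(0, v), np.minimum(w, w + v)
        self.r_r0, self.r_r1 = np.maximum(0, -u), np.minimum(h, h - u)
        self.r_c0, self.r_c1 = np.maximum(0, -v), np.minimum(w, w - v)
        n = ((h - np.abs(u))[:, None] * (w - np.abs(v))[None, :]).astype(np.float64)
        self.n = n
        self.overlap_ok = n >= max(1.0, min_overlap_frac * h * w)
        self._gather = np.ix_(u % self.fshape[0], v % self.fshape[1])

    def prepare(self, img: np.ndarray) -> dict:
        img = np.asarray(img, dtype=np.float64)
        return {
            "fft": sp_fft.rfft2(img, self.fshape),
            "ii": _integral(img),
            "ii2": _integral(img * img),
        }

    def _target_sums(self, t: dict) -> tuple[np.ndarray, np.ndarray]:
        if "sums" not in t:
            st = _rect_sums(t["ii"], self.t_r0, self.t_r1, self.t_c0, self.t_c1)
            st2 = _rect_sums(t["ii2"], self.t_r0, self.t_r1, self.t_c0, self.t_c1)
            var_t = np.maximum(st2 - st * st / self.n, 0.0)
            t["sums"] = (st, var_t)
        return t["sums"]

    def _ref_sums(self, r: dict) -> tuple[np.ndarray, np.ndarray]:
        if "rsums" not in r:
            sr = _rect_sums(r["ii"], self.r_r0, self.r_r1, self.r_c0, self.r_c1)
            sr2 = _rect_sums(r["ii2"], self.r_r0, self.r_r1, self.r_c0, self.r_c1)
            var_r = np.maximum(sr2 - sr * sr / self.n, 0.0)
            r["rsums"] = (sr, var_r)
        return r["rsums"]

    def correlate(self, t: dict, r: dict) -> np.ndarray:
        """NCC coefficient surface indexed by wrapped shifts (u, v).

        Entry ``[a, b]`` is the coefficient at shift ``(self.u[a], self.v[b])``
        meaning the target equals the reference translated by that amount.
        """
        cc_full = sp_fft.irfft2(t["fft"] * np.conj(r["fft"]), self.fshape)
        # gather the (2h-1, 2w-1) valid shifts from the circular correlation
        cc = cc_full[self._gather]
        st, var_t = self._target_sums(t)
        sr, var_r = self._ref_sums(r)
        n = self.n
        num = cc - st * sr / n
        denom = np.sqrt(var_t * var_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 1e-12, num / denom, -np.inf)
        rho = np.where(self.overlap_ok, rho, -np.inf)
        finite = np.isfinite(rho)
        rho[finite] = np.clip(rho[finite], -1.0, 1.0)
        return rho


def ncc_fine(
    target: Volume,
    reference: Volume,
    y_pred: np.ndarray,
    w_y: int = 8,
    min_overlap_frac: float = 0.5,
    ref_cache: dict | None = None,
) -> BScanDisplacementSet:
    """Pixel-level fine registration of each target B-scan by full-extent NCC.

    Target B-scan ``i`` is correlated against every reference B-scan ``j``
    with ``round(y_pred[i]) - w_y <= j <= round(y_pred[i]) + w_y``; the
    global argmax of the coefficient over candidates and in-plane shifts
    gives ``(dx, dz, j*)`` and ``dy = i - j*``.  B-scans whose search
    window misses the reference entirely are marked unmatched.
    """
    if w_y < 1:
        raise ValueError("w_y must be >= 1")
    if target.shape[1:] != reference.shape[1:]:
        raise ValueError("target and reference must share B-scan shape")
    n_y = target.n_y
    y_pred = np.asarray(y_pred, dtype=float)
    if y_pred.size != n_y:
        raise ValueError("y_pred must supply one prediction per target B-scan")
    if ref_cache is None:
        ref_cache = {}
    engine = ref_cache.setdefault("engine", _NccEngine(target.shape[1:], min_overlap_frac))
    ref_prep: dict[int, dict] = ref_cache.setdefault("prep", {})
    disp = np.zeros((n_y, 3))
    ncc = np.full(n_y, -np.inf)
    matched = np.zeros(n_y, dtype=bool)
    for i in range(n_y):
        center = int(round(y_pred[i]))
        if center < 0 or center >= reference.n_y:
            continue  # predicted position outside the reference: unmatched
        j_lo, j_hi = max(0, center - w_y), min(reference.n_y - 1, center + w_y)
        t_prep = engine.prepare(target.intensity[i])
        best = (-np.inf, 0, 0, 0)
        for j in range(j_lo, j_hi + 1):
            if j not in ref_prep:
                ref_prep[j] = engine.prepare(reference.intensity[j])
            rho = engine.correlate(t_prep, ref_prep[j])
            a, b = np.unravel_index(int(np.argmax(rho)), rho.shape)
            val = float(rho[a, b])
            if val > best[0]:
                best = (val, int(engine.u[a]), int(engine.v[b]), j)
        if np.isfinite(best[0]):
            val, dz, dx, j_star = best
            # an argmax pinned to an interior search-window boundary means
            # the prediction likely missed the true match, which lies
            # beyond the window; such forced matches are confidently
            # wrong, so treat the B-scan as unmatched.  A window clipped
            # by the reference edge may legitimately peak at that edge.
            if j_hi > j_lo and (
                (j_star == j_lo and j_lo > 0)
                or (j_star == j_hi and j_hi < reference.n_y - 1)
            ):
                continue
            disp[i] = (dx, i - j_star, dz)
            ncc[i] = val
            matched[i] = True
    ncc = np.where(matched, ncc, np.nan)
    return BScanDisplacementSet(
        disp=disp,
        ncc=ncc,
        y_pred=y_pred,
        matched=matched,
        included=matched.copy(),
        bscan_rate=target.bscan_rate,
        target_id=(target.video, target.index),
        reference_id=(reference.video, reference.index),
    )


# ---------------------------------------------------------------------------
# outlier filtering, volume construction, averaging
# ---------------------------------------------------------------------------

def filter_outliers(
    disp: BScanDisplacementSet,
    window_ms: float = 20.0,
    sigma_max_px: float = 4.0,
    ncc_min: float = 0.3,
) -> BScanDisplacementSet:
    """Exclude B-scans with locally erratic displacements or weak correlation.

    For each matched B-scan the per-axis standard deviation of displacement
    over a centered ~``window_ms`` window (converted to B-scans via the
    B-scan rate, at least 5) is computed; the B-scan is excluded when the
    maximum over axes exceeds ``sigma_max_px`` (typical range 3-5 px) or
    its NCC coefficient falls below ``ncc_min``.
    """
    n = disp.n_y
    win = max(5, int(round(window_ms / 1000.0 * disp.bscan_rate)))
    half = win // 2
    sigma = np.full(n, np.nan)
    included = np.zeros(n, dtype=bool)
    for i in range(n):
        if not disp.matched[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = disp.matched[lo:hi]
        if sel.sum() >= 2:
            local = disp.disp[lo:hi][sel]
            sigma[i] = float(local.std(axis=0).max())
        else:
            sigma[i] = 0.0
        included[i] = (sigma[i] <= sigma_max_px) and (disp.ncc[i] >= ncc_min)
    return BScanDisplacementSet(
        disp=disp.disp,
        ncc=disp.ncc,
        y_pred=disp.y_pred,
        matched=disp.matched,
        included=included,
        bscan_rate=disp.bscan_rate,
        sigma_delta=sigma,
        target_id=disp.target_id,
        reference_id=disp.reference_id,
    )


def register_volume(
    target: Volume,
    reference: Volume,
    sampling: CoarseSampling | None = None,
    w_y: int = 8,
    window_ms: float = 20.0,
    sigma_max_px: float = 4.0,
    ncc_min: float = 0.3,
    ref_cache: dict | None = None,
) -> BScanDisplacementSet:
    """Full coarse-to-fine registration of one target to one reference.

    ``ref_cache`` (a plain dict) may be shared between calls that use the
    same reference volume to reuse its per-B-scan FFTs and integral images.
    """
    trace = coarse_trace(target, reference, sampling)
    y_pred, _ = predict_positions(trace, target.n_y)
    disp = ncc_fine(target, reference, y_pred, w_y=w_y, ref_cache=ref_cache)
    return filter_outliers(disp, window_ms, sigma_max_px, ncc_min)


def _shift2d(img: np.ndarray, dz: int, dx: int) -> np.ndarray:
    """Integer shift with zero fill; new[z, x] = old[z - dz, x - dx]."""
    out = np.zeros_like(img)
    h, w = img.shape
    z0, z1 = max(0, dz), min(h, h + dz)
    x0, x1 = max(0, dx), min(w, w + dx)
    out[z0:z1, x0:x1] = img[z0 - dz : z1 - dz, x0 - dx : x1 - dx]
    return out


def construct_registered(
    target: Volume, disp: BScanDisplacementSet
) -> tuple[Volume, np.ndarray, ConstructionReport]:
    """Place displaced B-scans into a registered volume with a gap mask.

    Included B-scan ``i`` lands at slow-axis slot ``i - dy_i``, shifted
    in-plane by ``(-dx_i, -dz_i)`` (integer, zero fill).  When several
    B-scans collide on one slot the last acquired (highest ``i``) wins;
    slots receiving nothing are flagged in the gap mask.  Slots falling
    outside the canvas are dropped and counted.
    """
    n_y = target.n_y
    out = np.zeros_like(target.intensity)
    filled = np.zeros(n_y, dtype=bool)
    collided = dropped = 0
    placed_any = False
    for i in range(n_y):
        if not disp.included[i]:
            continue
        placed_any = True
        dx, dy, dz = disp.disp[i]
        slot = int(round(i - dy))
        if slot < 0 or slot >= n_y:
            dropped += 1
            continue
        if filled[slot]:
            collided += 1
        out[slot] = _shift2d(target.intensity[i], -int(round(dz)), -int(round(dx)))
        filled[slot] = True
    if not placed_any:
        raise ValueError("all B-scans excluded; cannot construct a registered volume")
    gap_mask = ~filled
    report = ConstructionReport(
        placed=int(filled.sum()),
        gaps=int(gap_mask.sum()),
        excluded=int((~disp.included).sum()),
        collided=collided,
        dropped=dropped,
        n_y=n_y,
    )
    vol = target.with_intensity(out)
    return vol, gap_mask, report


def average_registered(
    volumes: list[tuple[Volume, np.ndarray]]
) -> tuple[Volume, np.ndarray]:
    """Per-voxel mean of registered volumes, skipping gap slots.

    Returns the averaged volume and the per-slot count map; slots covered
    by no volume stay zero and show count 0.
    """
    if not volumes:
        raise ValueError("nothing to average")
    shape = volumes[0][0].shape
    acc = np.zeros(shape, dtype=np.float64)
    count = np.zeros(shape[0], dtype=np.int64)
    for vol, gap_mask in volumes:
        if vol.shape != shape:
            raise ValueError("averaged volumes must share a common shape")
        keep = ~np.asarray(gap_mask, dtype=bool)
        acc[keep] += vol.intensity[keep]
        count[keep] += 1
    out = np.zeros(shape, dtype=np.float32)
    nz = count > 0
    out[nz] = (acc[nz] / count[nz, None, None]).astype(np.float32)
    avg = volumes[0][0].with_intensity(out)
    return avg, count
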