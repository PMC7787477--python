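"""Multi-reference global registration: one motion-free coordinate frame for
every B-scan and A-line.

Registering targets to a single reference leaves the reference's own
distortion in every result.  Averaging the displacements that many targets
report against each reference B-scan estimates that reference's motion
(the fixating eye has zero-mean displacement), and a least-squares solve
over the reference-overlap graph reconciles the per-reference constant
offsets into one global frame.  A per-video similarity transform (rotation
+ isotropic scale + translation, fitted by Mattes mutual information) then
removes torsion and scale differences, yielding a 3D global coordinate for
every A-line.

Displacement sign convention: the tables here store the *correction*
displacement ``δ = -(measured target-minus-reference displacement)`` —
exactly the shift applied when constructing a registered volume (slot
``i - Δy = i + δ_y``).  With this convention the global coordinates come
out as content positions, so rendering at the solved coordinates aligns
volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bscan import (
    BScanDisplacementSet,
    CoarseRegistrationError,
    CoarseSampling,
    register_volume,
)
from .preprocess import reference_quality_metric
from .volume import Volume

logger = logging.getLogger(__name__)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest with halves up: keeps half-integer-centered rasters
    (even dimensions) on a uniform grid, unlike banker's rounding."""
    return np.floor(np.asarray(x) + 0.5).astype(int)

__all__ = [
    "MultiRefDisplacements",
    "ReferenceMotion",
    "GlobalBScanCoords",
    "AffineTransform",
    "ALineCoords",
    "multi_reference_register",
    "reference_motion",
    "compute_p",
    "solve_reference_offsets",
    "global_bscan_coords",
    "solve_global",
    "render_video_subsets",
    "lowest_variance_video",
    "estimate_affine",
    "estimate_affine_pipeline",
    "aline_global_coords",
    "render_global",
    "pairwise_cost",
]


@dataclass
class MultiRefDisplacements:
    """Per-B-scan correction displacements against every reference.

    ``table`` columns: ``T`` (target volume position in the batch), ``R``
    (reference volume position), ``i`` (target B-scan), ``j`` (matched
    reference B-scan), ``dx, dy, dz`` (correction convention), ``ncc``.
    Only B-scans that passed the outlier filters appear.
    """

    table: pd.DataFrame
    n_y: int
    n_volumes: int
    references: list[int]
    registrable: dict[tuple[int, int], bool]
    video_of: np.ndarray
    fraction_registered: float

    def volume_is_registered(self, t: int) -> bool:
        return any(self.registrable.get((t, r), False) for r in self.references)


@dataclass
class ReferenceMotion:
    """Estimated motion of one reference volume's B-scans.

    ``a[j]`` is the mean correction displacement of all target B-scans
    matched to reference B-scan ``j``; ``c`` its mean over ``j`` and
    ``b = a - c`` the zero-mean part.  ``interpolated`` flags reference
    B-scans that received no matches and were filled by linear
    interpolation from their neighbors.
    """

    a: np.ndarray  # (n_y, 3)
    b: np.ndarray  # (n_y, 3)
    c: np.ndarray  # (3,)
    counts: np.ndarray  # (n_y,)
    interpolated: np.ndarray  # (n_y,) bool


@dataclass
class GlobalBScanCoords:
    """Global 3D coordinates τ of every B-scan, with solver byproducts."""

    tau: np.ndarray        # (n_volumes, n_y, 3), NaN where undefined
    defined: np.ndarray    # (n_volumes, n_y) bool
    eps: dict[int, np.ndarray]
    o_mean: np.ndarray     # (3,) the subtracted grand mean
    n_components: int = 1


@dataclass
class AffineTransform:
    """Per-volume en-face similarity transform in homogeneous coordinates.

    ``matrix`` is 3x3 acting on (x, y, 1) in the global B-scan coordinate
    frame; depth passes through unchanged in the 4x4 augmentation.
    """

    matrix: np.ndarray
    converged: bool = True
    video: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3")
        if np.linalg.det(self.matrix[:2, :2]) <= 0:
            raise ValueError("en-face linear block must preserve orientation")

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    @property
    def scale(self) -> float:
        return float(np.sqrt(np.linalg.det(self.matrix[:2, :2])))

    def as_4x4(self) -> np.ndarray:
        m = np.eye(4)
        m[0, 0], m[0, 1], m[0, 3] = self.matrix[0, 0], self.matrix[0, 1], self.matrix[0, 2]
        m[1, 0], m[1, 1], m[1, 3] = self.matrix[1, 0], self.matrix[1, 1], self.matrix[1, 2]
        return m

    @classmethod
    def identity(cls, video: int = 0) -> "AffineTransform":
        return cls(matrix=np.eye(3), video=video)


@dataclass
class ALineCoords:
    """Global 3D coordinate of every A-line: χ = A_T · (τ + ς_α)."""

    chi: np.ndarray       # (n_volumes, n_y, n_x, 3)
    defined: np.ndarray   # (n_volumes, n_y) bool


# ---------------------------------------------------------------------------
# step 1: register everything to every reference
# ---------------------------------------------------------------------------

def _identity_displacements(volume: Volume) -> BScanDisplacementSet:
    n = volume.n_y
    return BScanDisplacementSet(
        disp=np.zeros((n, 3)),
        ncc=np.ones(n),
        y_pred=np.arange(n, dtype=float),
        matched=np.ones(n, dtype=bool),
        included=np.ones(n, dtype=bool),
        bscan_rate=volume.bscan_rate,
        target_id=(volume.video, volume.index),
        reference_id=(volume.video, volume.index),
    )


def multi_reference_register(
    volumes: list[Volume],
    references: list[int] | None = None,
    sampling: CoarseSampling | None = None,
    w_y: int = 8,
    window_ms: float = 20.0,
    sigma_max_px: float = 4.0,
    ncc_min: float = 0.3,
    min_registered_frac: float = 0.5,
    target_frac: float = 0.8,
    auto_add: bool = True,
    max_references: int | None = None,
) -> MultiRefDisplacements:
    """Register every volume to every reference volume.

    References default to the best quality-metric volume of each video.  A
    volume counts as registered to a reference when at least
    ``min_registered_frac`` of its B-scans survive the displacement
    filters.  When ``auto_add`` is set, additional references (next-best
    metric among the videos still containing unregistered volumes) are
    appended until at least ``target_frac`` of volumes register or
    candidates run out.
    """
    if not volumes:
        raise ValueError("no volumes to register")
    n_y = volumes[0].n_y
    video_of = np.array([v.video for v in volumes])
    scores = [reference_quality_metric(v).m for v in volumes]

    if references is None:
        references = []
        for vid in np.unique(video_of):
            members = np.flatnonzero(video_of == vid)
            references.append(int(members[np.argmax([scores[t] for t in members])]))
    references = list(references)

    rows: list[dict] = []
    registrable: dict[tuple[int, int], bool] = {}

    def run_reference(r: int) -> None:
        ref_cache: dict = {}
        for t, target in enumerate(volumes):
            if t == r:
                disp = _identity_displacements(target)
            else:
                try:
                    disp = register_volume(
                        target,
                        volumes[r],
                        sampling=sampling,
                        w_y=w_y,
                        window_ms=window_ms,
                        sigma_max_px=sigma_max_px,
                        ncc_min=ncc_min,
                        ref_cache=ref_cache,
                    )
                except CoarseRegistrationError:
                    registrable[(t, r)] = False
                    continue
            frac = disp.included.mean()
            ok = frac >= min_registered_frac
            registrable[(t, r)] = bool(ok)
            if not ok:
                continue
            for i in np.flatnonzero(disp.included):
                dx, dy, dz = -disp.disp[i]  # correction convention
                rows.append(
                    {
                        "T": t,
                        "R": r,
                        "i": int(i),
                        "j": int(round(i + dy)),
                        "dx": dx,
                        "dy": dy,
                        "dz": dz,
                        "ncc": float(disp.ncc[i]),
                    }
                )

    for r in references:
        run_reference(r)

    def frac_registered() -> float:
        return float(
            np.mean(
                [
                    any(registrable.get((t, r), False) for r in references)
                    for t in range(len(volumes))
                ]
            )
        )

    frac = frac_registered()
    if auto_add:
        limit = max_references or len(volumes)
        while frac < target_frac and len(references) < limit:
            unregistered = [
                t
                for t in range(len(volumes))
                if not any(registrable.get((t, r), False) for r in references)
            ]
            if not unregistered:
                break
            candidate_videos = set(video_of[unregistered])
            candidates = [
                t
                for t in range(len(volumes))
                if video_of[t] in candidate_videos and t not in references
            ]
            if not candidates:
                break
            new_ref = max(candidates, key=lambda t: scores[t])
            references.append(new_ref)
            run_reference(new_ref)
            frac = frac_registered()

    if not rows:
        raise RuntimeError(
            "no volume could be registered to any reference; "
            "check volume overlap and quality"
        )
    table = pd.DataFrame(rows)
    return MultiRefDisplacements(
        table=table,
        n_y=n_y,
        n_volumes=len(volumes),
        references=references,
        registrable=registrable,
        video_of=video_of,
        fraction_registered=frac,
    )


# ---------------------------------------------------------------------------
# step 2: reference motion, p-values, offset solve, global B-scan coordinates
# ---------------------------------------------------------------------------

def reference_motion(
    disp: MultiRefDisplacements,
    r: int,
    smooth_window: int = 7,
    center_targets: bool = True,
) -> ReferenceMotion:
    """Estimate reference ``r``'s per-B-scan motion by averaging matches.

    Averages the correction displacements of every target B-scan matched
    to each reference B-scan ``j``; unmatched ``j`` are filled by linear
    interpolation (edge hold) and flagged.  Two refinements of the plain
    per-``j`` mean (both disable to recover it exactly):

    - ``center_targets``: each target's contributions are first centered
      by that target's own mean displacement.  Near the volume edges only
      targets shifted inward can contribute, so their between-target
      offsets would otherwise leak a selection bias into the edge
      ``a_j``; per-target constants are pure gauge (absorbed by the
      reference-offset solve and the global zero-mean), so removing them
      changes the estimand not at all.
    - ``smooth_window``: the underlying motion is band-limited (tremor
      period ~11 ms, many B-scan intervals) while the per-``j`` sample
      mean is shot-noise-limited at small target counts, so the trace is
      smoothed along ``j`` with a short Savitzky-Golay filter
      (``smooth_window`` B-scans, quadratic; 0 disables).
    """
    sub = disp.table[disp.table["R"] == r]
    if sub.empty:
        raise ValueError(f"no targets registered to reference {r}")
    sub = sub.copy()
    if center_targets:
        per_target_mean = sub.groupby("T")[["dx", "dy", "dz"]].transform("mean")
        sub[["dx", "dy", "dz"]] = sub[["dx", "dy", "dz"]] - per_target_mean
    n_y = disp.n_y
    a = np.full((n_y, 3), np.nan)
    counts = np.zeros(n_y, dtype=int)
    grouped = sub.groupby("j")[["dx", "dy", "dz"]].mean()
    for j, row in grouped.iterrows():
        if 0 <= j < n_y:
            a[int(j)] = row.to_numpy()
    counts_series = sub.groupby("j").size()
    for j, n in counts_series.items():
        if 0 <= j < n_y:
            counts[int(j)] = int(n)
    interpolated = np.isnan(a[:, 0])
    if interpolated.all():
        raise ValueError("no in-range matches for this reference")
    jj = np.arange(n_y, dtype=float)
    good = ~interpolated
    for k in range(3):
        a[interpolated, k] = np.interp(jj[interpolated], jj[good], a[good, k])
    if smooth_window and smooth_window >= 3 and n_y > smooth_window:
        from scipy.signal import savgol_filter

        a = savgol_filter(a, smooth_window, 2, axis=0)
    c = a.mean(axis=0)
    b = a - c
    return ReferenceMotion(a=a, b=b, c=c, counts=counts, interpolated=interpolated)


def compute_p(
    disp: MultiRefDisplacements, motions: dict[int, ReferenceMotion]
) -> pd.DataFrame:
    """Reference-frame-free coordinates ``p = δ - a_j;R + s_i`` per table row.

    ``s_i = (0, i - <i>, 0)`` is the explicit scanner raster position
    (centered); subtracting the reference's own estimated motion ``a``
    leaves each B-scan's position free of that reference's distortion, up
    to a per-reference constant.
    """
    table = disp.table.copy()
    i_center = (disp.n_y - 1) / 2.0
    r_arr = table["R"].to_numpy(dtype=int)
    j_arr = table["j"].to_numpy(dtype=int)
    i_arr = table["i"].to_numpy(dtype=float)
    delta = table[["dx", "dy", "dz"]].to_numpy()
    a_rows = np.empty((len(table), 3))
    for r in np.unique(r_arr):
        mask = r_arr == r
        a_rows[mask] = motions[int(r)].a[j_arr[mask]]
    p = delta - a_rows
    p[:, 1] += i_arr - i_center
    table["px"], table["py"], table["pz"] = p[:, 0], p[:, 1], p[:, 2]
    return table


def pairwise_cost(
    ptable: pd.DataFrame, eps: dict[int, np.ndarray], axis: int
) -> float:
    """Sum of squared cross-reference disagreements of ``p + ε`` (one axis).

    The quantity the reference-offset solve minimizes: for every pair of
    references and every B-scan registered to both, the squared difference
    of ``p + ε`` between the two references.
    """
    col = ["px", "py", "pz"][axis]
    refs = sorted(ptable["R"].unique())
    total = 0.0
    for ia, ra in enumerate(refs):
        sub_a = ptable[ptable["R"] == ra][["T", "i", col]]
        for rb in refs[ia + 1 :]:
            sub_b = ptable[ptable["R"] == rb][["T", "i", col]]
            merged = sub_a.merge(sub_b, on=["T", "i"], suffixes=("_a", "_b"))
            if merged.empty:
                continue
            diff = (
                merged[f"{col}_a"].to_numpy()
                + eps[ra][axis]
                - merged[f"{col}_b"].to_numpy()
                - eps[rb][axis]
            )
            total += float((diff**2).sum())
    return total


def solve_reference_offsets(
    ptable: pd.DataFrame, references: list[int] | None = None
) -> tuple[dict[int, np.ndarray], int]:
    """Solve the per-reference constant offsets ε̂ by linear least squares.

    Minimizes, per axis, the sum over reference pairs of squared
    differences of ``p + ε`` on shared B-scans (a weighted graph-Laplacian
    system whose exact minimizer coincides with the iteratively minimized
    quadratic), with the gauge ``ε = 0`` on the first reference.
    Disconnected overlap components are solved independently, each with
    its own gauge, and reported in the second return value.
    """
    refs = references if references is not None else sorted(ptable["R"].unique())
    n = len(refs)
    idx = {r: k for k, r in enumerate(refs)}
    lap = np.zeros((n, n))
    rhs = np.zeros((n, 3))
    for ia in range(n):
        sub_a = ptable[ptable["R"] == refs[ia]][["T", "i", "px", "py", "pz"]]
        for ib in range(ia + 1, n):
            sub_b = ptable[ptable["R"] == refs[ib]][["T", "i", "px", "py", "pz"]]
            merged = sub_a.merge(sub_b, on=["T", "i"], suffixes=("_a", "_b"))
            m = len(merged)
            if m == 0:
                continue
            lap[ia, ia] += m
            lap[ib, ib] += m
            lap[ia, ib] -= m
            lap[ib, ia] -= m
            for axis, col in enumerate(("px", "py", "pz")):
                d = float(
                    (merged[f"{col}_b"] - merged[f"{col}_a"]).sum()
                )  # sum of (p_b - p_a)
                rhs[ia, axis] += d
                rhs[ib, axis] -= d

    # connected components of the overlap graph
    adjacency = lap != 0
    comp = np.full(n, -1)
    n_comp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            u = stack.pop()
            for v in range(n):
                if v != u and adjacency[u, v] and comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1
    if n_comp > 1:
        logger.warning(
            "reference overlap graph has %d disconnected components; "
            "each solved with its own gauge",
            n_comp,
        )

    eps_arr = np.zeros((n, 3))
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        gauge = members[0]
        free = members[members != gauge]
        if free.size == 0:
            continue
        sub_lap = lap[np.ix_(free, free)]
        sub_rhs = rhs[free]
        eps_arr[free] = np.linalg.solve(sub_lap, sub_rhs)
    return {r: eps_arr[idx[r]] for r in refs}, n_comp


def global_bscan_coords(
    ptable: pd.DataFrame,
    eps: dict[int, np.ndarray],
    n_volumes: int,
    n_y: int,
    n_components: int = 1,
) -> GlobalBScanCoords:
    """Average ``p + ε̂`` across references and re-center to zero mean.

    Each registered (B-scan, volume) receives the mean of ``p + ε̂`` over
    the references it registered to; the residual per-reference error
    averages out.  The grand mean over all defined B-scans is subtracted
    (global coordinates are referenced to the ensemble average of eye
    motion); B-scans registered to no reference stay NaN and unflagged.
    """
    o = np.zeros((n_volumes, n_y, 3))
    cnt = np.zeros((n_volumes, n_y), dtype=int)
    t_idx = ptable["T"].to_numpy(dtype=int)
    i_idx = ptable["i"].to_numpy(dtype=int)
    r_idx = ptable["R"].to_numpy(dtype=int)
    p = ptable[["px", "py", "pz"]].to_numpy()
    eps_per_row = np.stack([eps[r] for r in r_idx])
    np.add.at(o, (t_idx, i_idx), p + eps_per_row)
    np.add.at(cnt, (t_idx, i_idx), 1)
    defined = cnt > 0
    tau = np.full((n_volumes, n_y, 3), np.nan)
    tau[defined] = o[defined] / cnt[defined][:, None]
    o_mean = tau[defined].mean(axis=0)
    tau[defined] -= o_mean
    return GlobalBScanCoords(
        tau=tau, defined=defined, eps=eps, o_mean=o_mean, n_components=n_components
    )


def solve_global(
    disp: MultiRefDisplacements, smooth_window: int = 7
) -> GlobalBScanCoords:
    """Convenience chain: reference motions -> p -> ε̂ -> τ."""
    motions = {
        r: reference_motion(disp, r, smooth_window=smooth_window)
        for r in disp.references
    }
    ptable = compute_p(disp, motions)
    eps, n_comp = solve_reference_offsets(ptable, disp.references)
    return global_bscan_coords(
        ptable, eps, disp.n_volumes, disp.n_y, n_components=n_comp
    )


# ---------------------------------------------------------------------------
# step 3: per-video affine (torsion/scale) and A-line coordinates
# ---------------------------------------------------------------------------

def lowest_variance_video(volumes: list[Volume], coords: GlobalBScanCoords) -> int:
    """Video containing the volume with the lowest variance in τ."""
    variances: dict[int, float] = {}
    for t in range(len(volumes)):
        sel = coords.defined[t]
        if sel.any():
            variances[t] = float(np.nanvar(coords.tau[t, sel], axis=0).sum())
    if not variances:
        raise ValueError("no volume has defined global coordinates")
    return int(volumes[min(variances, key=variances.get)].video)


def render_video_subsets(
    volumes: list[Volume],
    coords: GlobalBScanCoords,
    affines: dict[int, "AffineTransform"] | None = None,
    z_band: tuple[int, int] | None = None,
) -> tuple[dict[int, np.ndarray], tuple[int, int], int]:
    """Average each video's volumes into an en-face image on the τ grid.

    All of a video's registered volumes are splatted (nearest pixel) onto
    one common grid covering every video, which fills the between-B-scan
    gaps of any single volume.  When per-video affines are given, A-line
    positions include the fast-axis affine correction (as in the final
    A-line coordinates).  Returns ``(subsets, grid origin (x0, y0),
    reference video)`` where the reference video is the one containing the
    volume with the lowest τ variance.
    """
    n_x = volumes[0].n_x
    defined = coords.defined
    tau = coords.tau
    x_half = (n_x - 1) / 2.0
    alpha = np.arange(n_x) - x_half
    videos = np.unique([v.video for v in volumes])
    if affines is None:
        affines = {int(v): AffineTransform.identity(video=int(v)) for v in videos}
    ref_video = lowest_variance_video(volumes, coords)

    # A-line en-face positions per (volume, B-scan): x varies along the
    # fast axis, y is constant within the rigid B-scan plus the affine's
    # fast-axis shear
    def positions(t: int, i: int) -> tuple[np.ndarray, np.ndarray]:
        m = affines[int(volumes[t].video)].matrix
        tx, ty, _ = tau[t, i]
        xs = tx + m[0, 0] * alpha + m[0, 2]
        ys = ty + m[1, 0] * alpha + m[1, 2]
        return xs, ys

    all_x, all_y = [], []
    for t in range(len(volumes)):
        for i in np.flatnonzero(defined[t]):
            xs, ys = positions(t, i)
            all_x.append((xs.min(), xs.max()))
            all_y.append((ys.min(), ys.max()))
    if not all_x:
        raise ValueError("no volume has defined global coordinates")
    x0 = int(np.floor(min(a for a, _ in all_x)))
    x1 = int(np.ceil(max(b for _, b in all_x))) + 1
    y0 = int(np.floor(min(a for a, _ in all_y)))
    y1 = int(np.ceil(max(b for _, b in all_y))) + 1
    h, w = y1 - y0, x1 - x0

    subsets: dict[int, np.ndarray] = {}
    for vid in videos:
        acc = np.zeros((h, w))
        cnt = np.zeros((h, w))
        for t, vol in enumerate(volumes):
            if vol.video != vid:
                continue
            if z_band is None:
                enface = vol.intensity.mean(axis=1)  # (n_y, n_x)
            else:
                enface = vol.intensity[:, z_band[0] : z_band[1], :].mean(axis=1)
            for i in np.flatnonzero(defined[t]):
                xs, ys = positions(t, i)
                # bilinear splat: smoother subsets give the similarity fit
                # a less biased metric surface than nearest-pixel rounding
                fx, fy = xs - x0, ys - y0
                ix, iy = np.floor(fx).astype(int), np.floor(fy).astype(int)
                wx, wy_ = fx - ix, fy - iy
                for ddy, ddx, wgt in (
                    (0, 0, (1 - wy_) * (1 - wx)),
                    (0, 1, (1 - wy_) * wx),
                    (1, 0, wy_ * (1 - wx)),
                    (1, 1, wy_ * wx),
                ):
                    gy, gx = iy + ddy, ix + ddx
                    ok = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
                    np.add.at(acc, (gy[ok], gx[ok]), wgt[ok] * enface[i, ok])
                    np.add.at(cnt, (gy[ok], gx[ok]), wgt[ok])
        img = np.zeros((h, w))
        nz = cnt > 0
        img[nz] = acc[nz] / cnt[nz]
        subsets[int(vid)] = img
    return subsets, (x0, y0), ref_video


def _fit_similarity_sitk(fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Similarity transform (moving -> fixed frame) via Mattes MI.

    Returns the 3x3 homogeneous matrix mapping moving-image coordinates
    into fixed-image coordinates.  Raises on optimizer failure.
    """
    import SimpleITK as sitk

    fimg = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float32))
    mimg = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float32))
    initial = sitk.Similarity2DTransform()
    initial.SetCenter([(fixed.shape[1] - 1) / 2.0, (fixed.shape[0] - 1) / 2.0])
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.NONE)  # all pixels: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.2,
        minStep=1e-7,
        numberOfIterations=1000,
        gradientMagnitudeTolerance=1e-9,
        relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SetInitialTransform(initial, inPlace=True)
    reg.Execute(fimg, mimg)
    m = np.asarray(initial.GetMatrix()).reshape(2, 2)
    c = np.asarray(initial.GetCenter())
    t = np.asarray(initial.GetTranslation())
    # fixed point p -> moving point: M (p - c) + c + t
    fwd = np.eye(3)
    fwd[:2, :2] = m
    fwd[:2, 2] = c + t - m @ c
    return np.linalg.inv(fwd)  # moving -> fixed


def _joint_coverage_crop(
    fixed: np.ndarray, moving: np.ndarray, margin: int = 2
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Crop both images to the bounding box where both have coverage."""
    both = (fixed > 0) & (moving > 0)
    rows = np.flatnonzero(both.any(axis=1))
    cols = np.flatnonzero(both.any(axis=0))
    if rows.size < 16 or cols.size < 16:
        raise ValueError("videos share too little coverage for an affine fit")
    r0, r1 = rows[0] + margin, rows[-1] + 1 - margin
    c0, c1 = cols[0] + margin, cols[-1] + 1 - margin
    return fixed[r0:r1, c0:c1], moving[r0:r1, c0:c1], (c0, r0)


def estimate_affine(
    subsets: dict[int, np.ndarray],
    reference_video: int,
    origin: tuple[int, int] = (0, 0),
) -> dict[int, AffineTransform]:
    """Per-video similarity transform onto the reference video's subset.

    The fit maximizes Mattes mutual information between each video's
    averaged en-face subset and the reference subset, over the region both
    cover (unfilled canvas would otherwise dominate the metric).  Matrices
    act in the global B-scan coordinate frame (grid origin conjugated
    away); the reference video maps to the identity.  Non-convergence
    yields an identity transform flagged as failed.
    """
    out: dict[int, AffineTransform] = {}
    fixed_full = subsets[reference_video]
    for vid, img in subsets.items():
        if vid == reference_video:
            out[vid] = AffineTransform.identity(video=vid)
            continue
        try:
            fixed, moving, (cx, cy) = _joint_coverage_crop(fixed_full, img)
            m_idx = _fit_similarity_sitk(fixed, moving)
            ox, oy = origin[0] + cx, origin[1] + cy
            shift = np.eye(3)
            shift[0, 2], shift[1, 2] = ox, oy
            unshift = np.eye(3)
            unshift[0, 2], unshift[1, 2] = -ox, -oy
            out[vid] = AffineTransform(matrix=shift @ m_idx @ unshift, video=vid)
        except Exception as exc:  # optimizer failure -> identity, flagged
            logger.warning("affine estimation failed for video %s: %s", vid, exc)
            out[vid] = AffineTransform(matrix=np.eye(3), converged=False, video=vid)
    return out


def estimate_affine_pipeline(
    volumes: list[Volume],
    coords: GlobalBScanCoords,
    z_band: tuple[int, int] | None = None,
    max_iter: int = 8,
    tol_deg: float = 0.01,
    tol_scale: float = 2e-4,
) -> dict[int, AffineTransform]:
    """Iteratively estimate per-video affines by fit-then-re-render.

    The τ solve already removes the between-B-scan part of each video's
    torsion/scale, so a single similarity fit on τ-rendered subsets sees
    only the within-B-scan residual and recovers roughly half of the
    distortion.  Re-rendering with the current estimate and fitting the
    remaining residual converges geometrically to the full transform.
    """
    videos = sorted({int(v.video) for v in volumes})
    affines = {v: AffineTransform.identity(video=v) for v in videos}
    for _ in range(max_iter):
        subsets, origin, ref_video = render_video_subsets(
            volumes, coords, affines=affines, z_band=z_band
        )
        update = estimate_affine(subsets, ref_video, origin)
        max_rot = max_scale = 0.0
        for vid in videos:
            if not update[vid].converged:
                affines[vid] = AffineTransform(
                    matrix=affines[vid].matrix, converged=False, video=vid
                )
                continue
            max_rot = max(max_rot, abs(update[vid].rotation_deg))
            max_scale = max(max_scale, abs(update[vid].scale - 1.0))
            affines[vid] = AffineTransform(
                matrix=update[vid].matrix @ affines[vid].matrix,
                converged=affines[vid].converged,
                video=vid,
            )
        if max_rot < tol_deg and max_scale < tol_scale:
            break
    return affines


def aline_global_coords(
    coords: GlobalBScanCoords,
    affines: dict[int, AffineTransform],
    volumes: list[Volume],
) -> ALineCoords:
    """Global 3D coordinates of every A-line.

    ``ς_α = (α - <α>, 0, 0)`` is the centered fast-scan raster position.
    The volume's (video's) similarity matrix acts on ``ς_α`` in
    homogeneous coordinates — the between-B-scan part of torsion/scale is
    already contained in τ, so the affine corrects the within-B-scan
    (fast-axis) residual and contributes its translation once:
    ``χ = τ + A_T ς_α``.  With ``A_T = I`` this is exactly ``τ + ς_α``.
    Depth passes through unchanged.  Volumes whose affine failed to
    converge are marked undefined.
    """
    n_volumes, n_y, _ = coords.tau.shape
    n_x = volumes[0].n_x
    alpha = np.arange(n_x) - (n_x - 1) / 2.0
    chi = np.full((n_volumes, n_y, n_x, 3), np.nan)
    defined = coords.defined.copy()
    for t in range(n_volumes):
        aff = affines[int(volumes[t].video)]
        if not aff.converged:
            defined[t] = False
            continue
        m = aff.matrix
        dx = m[0, 0] * alpha + m[0, 2]
        dy = m[1, 0] * alpha + m[1, 2]
        for i in np.flatnonzero(coords.defined[t]):
            tx, ty, tz = coords.tau[t, i]
            chi[t, i, :, 0] = tx + dx
            chi[t, i, :, 1] = ty + dy
            chi[t, i, :, 2] = tz
    return ALineCoords(chi=chi, defined=defined)


# ---------------------------------------------------------------------------
# rendering: mosaics, global averages, focus stacks
# ---------------------------------------------------------------------------

def render_global(
    volumes: list[Volume],
    coords: ALineCoords,
    grid: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None,
) -> tuple[Volume, np.ndarray]:
    """Splat every A-line to the nearest global grid column and average.

    ``grid`` is ``((y_lo, y_hi), (z_lo, z_hi), (x_lo, x_hi))`` in global
    coordinates (half-open); ``None`` auto-fits the χ bounding box, which
    is what extends the field of view beyond a single volume.  Returns the
    averaged volume (sum/count per voxel) and the 2D per-column A-line
    count map; its total equals the number of placed A-lines.  Averaging
    on collisions makes the same routine serve mosaicking and focus
    stacking alike.
    """
    if not np.any(coords.defined):
        raise ValueError("no defined A-line coordinates to render")
    n_z = volumes[0].n_z
    chi = coords.chi
    sel = np.broadcast_to(coords.defined[:, :, None], chi.shape[:3])
    pts = chi[sel]
    if grid is None:
        rounded = _round_half_up(pts)
        x_lo, y_lo, z_lo = rounded.min(axis=0)
        x_hi, y_hi, z_hi = rounded.max(axis=0) + 1
        grid = ((int(y_lo), int(y_hi)), (int(z_lo), int(z_hi)), (int(x_lo), int(x_hi)))
    (y_lo, y_hi), (z_lo, z_hi), (x_lo, x_hi) = grid
    h = y_hi - y_lo
    w = x_hi - x_lo
    depth = (z_hi - z_lo) + n_z - 1
    acc = np.zeros((h, depth, w))
    cnt = np.zeros((h, depth, w))
    count2d = np.zeros((h, w), dtype=np.int64)
    z_cols = np.arange(n_z)
    for t, vol in enumerate(volumes):
        for i in np.flatnonzero(coords.defined[t]):
            gx = _round_half_up(chi[t, i, :, 0]) - x_lo
            gy = _round_half_up(chi[t, i, :, 1]) - y_lo
            gz = _round_half_up(chi[t, i, :, 2]) - z_lo
            ok = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h) & (gz >= 0) & (gz + n_z <= depth)
            if not ok.any():
                continue
            data = vol.intensity[i]  # (n_z, n_x)
            for a in np.flatnonzero(ok):
                zz = gz[a] + z_cols
                acc[gy[a], zz, gx[a]] += data[:, a]
                cnt[gy[a], zz, gx[a]] += 1.0
                count2d[gy[a], gx[a]] += 1
    out = np.zeros_like(acc, dtype=np.float32)
    nz = cnt > 0
    out[nz] = (acc[nz] / cnt[nz]).astype(np.float32)
    rendered = Volume(
        intensity=out,
        pitch=volumes[0].pitch,
        bscan_rate=volumes[0].bscan_rate,
    )
    return rendered, count2d
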