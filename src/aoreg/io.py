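"""Volume readers/writers, pipeline configuration, and the end-to-end run.

HDF5 is the canonical container (dataset ``intensity`` with axis-order and
pitch attributes); multi-page TIFF is supported for interchange with pages
as B-scans.  ``run_pipeline`` chains preprocessing, 3D B-scan
registration, multi-reference global registration, affine correction,
rendering, and metrics, writing every table and a resolved copy of the
configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import bscan, globalreg, metrics, preprocess
from .volume import MotionTrace, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "write_volume",
    "read_scan_pattern",
    "write_trace_csv",
    "read_trace_csv",
    "displacements_to_frame",
    "PipelineConfig",
    "run_pipeline",
]

AXIS_ORDER = "y,z,x"


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume to HDF5 (``.h5``/``.hdf5``) or multi-page TIFF.

    HDF5 stores dataset ``intensity`` plus axis order, pitch, B-scan rate,
    and acquisition-id attributes; TIFF stores one page per B-scan (page =
    z rows by x columns) and carries metadata in the software tag only.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("intensity", data=volume.intensity)
            dset.attrs["axis_order"] = AXIS_ORDER
            dset.attrs["pitch_um"] = np.asarray(volume.pitch, dtype=float)
            dset.attrs["bscan_rate_hz"] = float(volume.bscan_rate)
            dset.attrs["video"] = int(volume.video)
            dset.attrs["index"] = int(volume.index)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.intensity, metadata={"axes": "QYX"})
    else:
        raise ValueError(f"unknown volume format: {path.name}")


def read_volume(path: str | Path) -> Volume:
    """Read a volume from HDF5 or multi-page TIFF.

    Round-trips written volumes bit-exactly (single precision).  Missing
    pitch metadata defaults to 1.0 um/px with a logged warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "intensity" not in f:
                raise ValueError(f"{path.name}: missing 'intensity' dataset")
            dset = f["intensity"]
            data = dset[()]
            if "pitch_um" in dset.attrs:
                pitch = tuple(float(v) for v in dset.attrs["pitch_um"])
            else:
                logger.warning("%s: no pitch metadata; defaulting to 1.0 um/px", path.name)
                pitch = (1.0, 1.0, 1.0)
            rate = float(dset.attrs.get("bscan_rate_hz", 1100.0))
            video = int(dset.attrs.get("video", 0))
            index = int(dset.attrs.get("index", 0))
        return Volume(
            intensity=data, pitch=pitch, bscan_rate=rate, video=video, index=index
        )
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        logger.warning("%s: TIFF carries no pitch metadata; defaulting to 1.0 um/px", path.name)
        return Volume(intensity=np.asarray(data, dtype=np.float32))
    raise ValueError(f"unknown volume format: {path.name}")


def read_scan_pattern(path: str | Path) -> np.ndarray:
    """Read a fast-axis scan-pattern lookup: 1-column CSV, one position per
    A-line index, strictly increasing."""
    values = np.loadtxt(path, delimiter=",", ndmin=1, dtype=float)
    if values.ndim != 1:
        raise ValueError(f"{Path(path).name}: scan pattern must be a single column")
    if not np.all(np.diff(values) > 0):
        raise ValueError(f"{Path(path).name}: scan pattern must be strictly increasing")
    return values


def write_trace_csv(trace: MotionTrace, path: str | Path, pitch=(1.0, 1.0, 1.0)) -> None:
    """Write a motion trace as CSV plus a JSON sidecar for torsion/scale."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "bscan_index": np.arange(len(trace)),
            "t_ms": trace.t_ms,
            "dx_px": trace.xyz_um[:, 0] / pitch[0],
            "dy_px": trace.xyz_um[:, 1] / pitch[1],
            "dz_px": trace.xyz_um[:, 2] / pitch[2],
        }
    )
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"torsion_deg": trace.torsion_deg, "scale": trace.scale})
    )


def read_trace_csv(path: str | Path, pitch=(1.0, 1.0, 1.0)) -> MotionTrace:
    path = Path(path)
    df = pd.read_csv(path)
    xyz = np.stack(
        [df["dx_px"] * pitch[0], df["dy_px"] * pitch[1], df["dz_px"] * pitch[2]], axis=1
    )
    meta = {"torsion_deg": 0.0, "scale": 1.0}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return MotionTrace(
        t_ms=df["t_ms"].to_numpy(),
        xyz_um=xyz,
        torsion_deg=meta["torsion_deg"],
        scale=meta["scale"],
    )


def displacements_to_frame(disp: bscan.BScanDisplacementSet) -> pd.DataFrame:
    """Displacement table: i, dx, dy, dz, ncc, included, y_pred."""
    return pd.DataFrame(
        {
            "i": np.arange(disp.n_y),
            "dx": disp.disp[:, 0],
            "dy": disp.disp[:, 1],
            "dz": disp.disp[:, 2],
            "ncc": disp.ncc,
            "included": disp.included,
            "y_pred": disp.y_pred,
        }
    )


@dataclass
class PipelineConfig:
    """All registration tunables with their validated defaults."""

    s: int = 15
    d: int = 6
    w_y: int = 8
    ncc_min: float = 0.3
    sigma_max_px: float = 4.0
    window_ms: float = 20.0
    vitreous_fraction: float = 0.1
    m_db_above_n: float = 37.5
    crop_cap: tuple[int, int] = (512, 512)
    min_registered_frac: float = 0.5
    target_frac: float = 0.8
    normalize: bool = True
    tilt: float | str | None = None
    cone_period_um: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ncc_min", "sigma_max_px", "window_ms", "vitreous_fraction",
            "m_db_above_n", "min_registered_frac", "target_frac", "cone_period_um",
        ):
            setattr(self, name, float(getattr(self, name)))
        self.s, self.d, self.w_y, self.seed = (
            int(self.s), int(self.d), int(self.w_y), int(self.seed)
        )
        if not (1 <= self.s):
            raise ValueError("s must be positive")
        if not (1 <= self.d):
            raise ValueError("d must be positive")
        if self.w_y < 1:
            raise ValueError("w_y must be >= 1")
        if not (0.0 <= self.ncc_min <= 1.0):
            raise ValueError("ncc_min must lie in [0, 1]")
        if self.sigma_max_px <= 0:
            raise ValueError("sigma_max_px must be positive")
        if not (0.0 < self.vitreous_fraction < 1.0):
            raise ValueError("vitreous_fraction must lie in (0, 1)")
        if not (0.0 < self.min_registered_frac <= 1.0):
            raise ValueError("min_registered_frac must lie in (0, 1]")
        if not (0.0 < self.target_frac <= 1.0):
            raise ValueError("target_frac must lie in (0, 1]")
        if self.cone_period_um <= 0:
            raise ValueError("cone_period_um must be positive")
        self.crop_cap = (int(self.crop_cap[0]), int(self.crop_cap[1]))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ValueError(f"{path.name}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path.name}: unknown config keys {sorted(unknown)}")
        if "crop_cap" in data:
            data["crop_cap"] = tuple(data["crop_cap"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["crop_cap"] = list(data["crop_cap"])
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, out_dir: str | Path
) -> dict:
    """Execute the full cascade on a directory of volumes.

    Stages: preprocessing (optional rectification, normalization, crop) ->
    multi-reference 3D B-scan registration -> global B-scan coordinates ->
    per-video affine -> A-line coordinates -> global rendering -> metrics.
    All tables, the rendered volume, and the resolved config are written
    to ``out_dir``; the run is deterministic given config and inputs.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in (".h5", ".hdf5", ".tif", ".tiff")
    )
    if not paths:
        raise ValueError(f"no volumes found in {input_dir}")
    volumes = [read_volume(p) for p in paths]

    # --- preprocess ---------------------------------------------------
    if config.tilt is not None:
        volumes = [preprocess.rectify_fast_axis(v, tilt=config.tilt) for v in volumes]
    if config.normalize:
        volumes = [
            preprocess.normalize_intensity(
                v, "auto", config.vitreous_fraction, config.m_db_above_n
            )
            for v in volumes
        ]
    volumes = preprocess.crop_batch(volumes, config.crop_cap)

    # --- multi-reference 3D B-scan registration -----------------------
    sampling = bscan.CoarseSampling(s=config.s, d=config.d)
    mrd = globalreg.multi_reference_register(
        volumes,
        sampling=sampling,
        w_y=config.w_y,
        window_ms=config.window_ms,
        sigma_max_px=config.sigma_max_px,
        ncc_min=config.ncc_min,
        min_registered_frac=config.min_registered_frac,
        target_frac=config.target_frac,
    )
    mrd.table.to_csv(out_dir / "displacements.csv", index=False)

    # --- global coordinates, affine, A-lines --------------------------
    coords = globalreg.solve_global(mrd)
    tau_rows = []
    for t in range(mrd.n_volumes):
        for i in range(mrd.n_y):
            tau_rows.append(
                {
                    "T": t,
                    "i": i,
                    "x": coords.tau[t, i, 0],
                    "y": coords.tau[t, i, 1],
                    "z": coords.tau[t, i, 2],
                    "defined": bool(coords.defined[t, i]),
                }
            )
    pd.DataFrame(tau_rows).to_csv(out_dir / "tau.csv", index=False)

    ref_video = globalreg.lowest_variance_video(volumes, coords)
    affines = globalreg.estimate_affine_pipeline(volumes, coords)
    with open(out_dir / "affines.json", "w") as f:
        json.dump(
            {
                str(vid): {
                    "matrix_4x4_row_major": aff.as_4x4().ravel().tolist(),
                    "rotation_deg": aff.rotation_deg,
                    "scale": aff.scale,
                    "converged": aff.converged,
                }
                for vid, aff in affines.items()
            },
            f,
            indent=2,
        )
    aline = globalreg.aline_global_coords(coords, affines, volumes)
    rendered, count2d = globalreg.render_global(volumes, aline)
    write_volume(rendered, out_dir / "rendered.h5")
    np.savetxt(out_dir / "count_map.csv", count2d, fmt="%d", delimiter=",")

    # --- metrics -------------------------------------------------------
    ref_index = mrd.references[0]
    report: dict = {
        "n_volumes": mrd.n_volumes,
        "references": mrd.references,
        "fraction_registered": mrd.fraction_registered,
        "reference_video": ref_video,
    }
    try:
        enface_ref = metrics.enface_projection(volumes[ref_index])
        enface_avg = metrics.EnFaceImage(
            data=rendered.intensity.mean(axis=1), pitch=enface_ref.pitch
        )
        report["mosaic_snr_db"] = metrics.mosaic_snr(enface_avg, config.cone_period_um)
    except ValueError as exc:
        logger.warning("metrics stage skipped: %s", exc)
    with open(out_dir / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    config.to_file(out_dir / "config_resolved.yaml")
    return report
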