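"""Readers and writers: NIfTI volumes, acquisition-time tables, summaries."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bbbo import BBBoResult, DceSeries, ParamMaps, VoxelDims
from .kinetics import AcquisitionTimes

__all__ = [
    "load_times",
    "save_times",
    "load_series",
    "save_series",
    "load_mask",
    "save_mask",
    "save_param_maps",
    "save_bbbo_result",
]


def load_times(path: str | Path) -> AcquisitionTimes:
    """Read acquisition times from CSV (`frame,minutes`) or a JSON list."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            times = np.asarray(json.loads(path.read_text()), dtype=float)
        else:
            df = pd.read_csv(path)
            if "minutes" not in df.columns:
                raise ValueError(f"{path}: times CSV needs a 'minutes' column")
            if "frame" in df.columns:
                df = df.sort_values("frame")
            times = df["minutes"].to_numpy(dtype=float)
        return AcquisitionTimes(times)
    except ValueError as exc:
        raise ValueError(f"malformed acquisition-time table {path}: {exc}") from exc


def save_times(times: AcquisitionTimes, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(times)), "minutes": times.times}
    ).to_csv(path, index=False)


def _affine(dims: VoxelDims) -> np.ndarray:
    return np.diag([dims.dx, dims.dy, dims.dz, 1.0])


def _dims_from_header(img: nib.Nifti1Image) -> VoxelDims:
    z = img.header.get_zooms()[:3]
    return VoxelDims(float(z[0]), float(z[1]), float(z[2]))


def load_series(volume_path: str | Path, times_path: str | Path) -> DceSeries:
    """Load a 4D NIfTI series; voxel dims come from the header zooms."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 4D volume, got {data.ndim}D")
    return DceSeries(
        volumes=data,
        times=load_times(times_path),
        voxel_dims=_dims_from_header(img),
    )


def save_series(series: DceSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.volumes.astype(np.float32), _affine(series.voxel_dims))
    img.header.set_zooms(
        (series.voxel_dims.dx, series.voxel_dims.dy, series.voxel_dims.dz, 1.0)
    )
    nib.save(img, str(path))


def load_mask(path: str | Path, expected_shape=None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0.5
    if mask.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D")
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} != series shape {tuple(expected_shape)}"
        )
    return mask


def save_mask(mask: np.ndarray, dims: VoxelDims, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(dims)), str(path))


def save_param_maps(maps: ParamMaps, dims: VoxelDims, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("dyn", maps.dyn_map), ("tt", maps.tt_map),
        ("aot", maps.aot_map), ("r2", maps.r2_map),
    ):
        nib.save(
            nib.Nifti1Image(arr.astype(np.float32), _affine(dims)),
            str(outdir / f"{name}_map.nii.gz"),
        )
    save_mask(maps.fitted_mask, dims, outdir / "fitted_mask.nii.gz")


def save_bbbo_result(result: BBBoResult, dims: VoxelDims, outdir: str | Path) -> dict:
    """Write the label map + JSON summary; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(result.label_map.astype(np.int16), _affine(dims)),
        str(outdir / "bbbo_labels.nii.gz"),
    )
    summary = {
        "n_voxels": result.n_voxels,
        "volume_mm3": result.volume_mm3,
        "n_clusters": len(result.clusters),
        "clusters": [{"label": int(l), "n_voxels": int(c)} for l, c in result.clusters],
    }
    (outdir / "bbbo_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
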