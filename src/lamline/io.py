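"""File formats: NIfTI-1 series/images with JSON sidecars, TSV tables,
JSON/YAML configuration.

A :class:`~lamline.core.LineScanSeries` is stored as a NIfTI-1 volume of
shape ``(depth, 1, 1, time)`` — depth on the first spatial axis, surface
first — with voxel size set from the depth resolution and TR.  Metadata
that NIfTI cannot carry faithfully (exact TR in ms, depth resolution,
seed, the provenance chain) lives in a JSON sidecar next to the image
(``foo.nii`` + ``foo.json``).  2D line images are stored as two volumes
(data, ROI mask).  TSV tables are tab-delimited with a header row and '.'
decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import LineImage2D, LineScanSeries

__all__ = [
    "write_series",
    "read_series",
    "write_image2d",
    "read_image2d",
    "write_profile_tsv",
    "read_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(series: LineScanSeries, path) -> Path:
    """Write a series as NIfTI-1 (depth x 1 x 1 x time) plus JSON sidecar."""
    path = Path(path)
    data = series.data[:, None, None, :]
    res_mm = series.depth_res_um / 1000.0
    affine = np.diag([res_mm, 1.0, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((res_mm, 1.0, 1.0, series.tr_ms / 1000.0))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    sidecar = {
        "tr_ms": series.tr_ms,
        "depth_res_um": series.depth_res_um,
        **series.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=_json_default))
    return path


def read_series(path) -> LineScanSeries:
    """Read a series written by :func:`write_series`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path.name} next to {path.name}: the "
            "sidecar carries tr_ms/depth_res_um and is written by "
            "write_series; re-export the series or restore the JSON file"
        )
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[1] != 1 or data.shape[2] != 1:
        raise ValueError(
            f"expected a line-scan series of shape (depth, 1, 1, time), got "
            f"{data.shape}"
        )
    meta = json.loads(sidecar_path.read_text())
    tr_ms = meta.pop("tr_ms")
    depth_res_um = meta.pop("depth_res_um")
    return LineScanSeries(
        data=data[:, 0, 0, :], tr_ms=tr_ms, depth_res_um=depth_res_um, meta=meta
    )


def write_image2d(img2d: LineImage2D, path) -> Path:
    """Write a 2D line image as a 2-volume NIfTI (data, ROI mask)."""
    path = Path(path)
    n_read, n_phase = img2d.data.shape
    stack = np.stack([img2d.data, img2d.roi_mask.astype(float)], axis=-1)
    stack = stack[:, :, None, :]  # (read, phase, 1, volume)
    dx = img2d.fov_mm[0] / n_read
    dy = img2d.fov_mm[1] / n_phase
    nii = nib.Nifti1Image(stack, np.diag([dx, dy, 1.0, 1.0]))
    nii.header.set_xyzt_units(xyz="mm")
    nib.save(nii, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"fov_mm": list(img2d.fov_mm), "volumes": ["data", "roi_mask"]},
                   indent=2)
    )
    return path


def read_image2d(path) -> LineImage2D:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path.name} next to {path.name}"
        )
    meta = json.loads(sidecar_path.read_text())
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if arr.ndim != 4 or arr.shape[3] != 2:
        raise ValueError(
            f"expected a 2-volume (data, mask) image, got shape {arr.shape}"
        )
    return LineImage2D(
        data=arr[:, :, 0, 0],
        fov_mm=tuple(meta["fov_mm"]),
        roi_mask=arr[:, :, 0, 1] > 0.5,
    )


def write_profile_tsv(path, columns: dict) -> Path:
    """Write named columns as a TSV table (tab delimiter, header row)."""
    path = Path(path)
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_config(path) -> dict:
    """Load a JSON (or YAML) configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return cfg


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
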