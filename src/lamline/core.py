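"""Core data containers for depth-resolved line-scanning fMRI.

Line-scanning fMRI acquires a single k-space line per repetition (phase
encoding off), so the raw data are 1D depth profiles sampled at a high rate.
The containers here carry the two central objects of the analysis — a
depth x time signal matrix (:class:`LineScanSeries`) and a per-depth scalar
profile (:class:`LaminarProfile`) — plus the 2D in-plane image used for
slice-profile quality metrics and a cortical layer scheme.

Depth convention: index 0 is the cortical surface; the depth of bin ``i`` is
``(i + 0.5) * depth_res`` (bin centres), increasing into the cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LineScanSeries",
    "LaminarProfile",
    "LineImage2D",
    "LayerScheme",
    "DEFAULT_LAYERS",
]


@dataclass
class LineScanSeries:
    """A depth x time line-scanning signal matrix.

    Parameters
    ----------
    data:
        2D array, shape ``(n_depth, n_time)``, arbitrary signal units.
    tr_ms:
        Sampling interval (repetition time) in milliseconds.
    depth_res_um:
        Depth bin size in micrometres.
    meta:
        Free-form metadata / provenance chain (serialised to the sidecar).
    """

    data: np.ndarray
    tr_ms: float
    depth_res_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"series data must be 2D (depth x time), got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series data contains non-finite values")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.depth_res_um <= 0:
            raise ValueError("depth_res_um must be positive")

    @property
    def n_depth(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def fs_hz(self) -> float:
        """Sampling frequency in Hz."""
        return 1000.0 / self.tr_ms

    @property
    def depths_mm(self) -> np.ndarray:
        """Bin-centre depths in mm, surface first."""
        res_mm = self.depth_res_um / 1000.0
        return (np.arange(self.n_depth) + 0.5) * res_mm

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_time) * self.tr_ms / 1000.0

    def copy_with(self, data: np.ndarray, **meta) -> "LineScanSeries":
        """New series with replaced data and merged metadata."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return LineScanSeries(
            data=np.asarray(data, dtype=float),
            tr_ms=self.tr_ms,
            depth_res_um=self.depth_res_um,
            meta=new_meta,
        )


@dataclass
class LaminarProfile:
    """Per-depth scalar values (tSNR, percent change, normalised BOLD...)."""

    values: np.ndarray
    depths_mm: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        if self.values.shape != self.depths_mm.shape:
            raise ValueError("values and depth grid must have the same shape")
        if self.depths_mm.size >= 2 and not np.all(np.diff(self.depths_mm) > 0):
            raise ValueError("depth grid must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    def interp(self, depth_mm: float) -> float:
        """Linear interpolation of the profile at an arbitrary depth."""
        return float(np.interp(depth_mm, self.depths_mm, self.values))


@dataclass
class LineImage2D:
    """2D in-plane image (readout x phase) with an ROI mask.

    Used for slice-profile quality metrics: the FWHM of the 1D profile
    (average over readout) and the background signal fraction outside the
    nominal ROI strip.
    """

    data: np.ndarray
    fov_mm: tuple
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("image must be 2D (readout x phase)")
        if self.roi_mask.shape != self.data.shape:
            raise ValueError("roi_mask must match the image shape")
        if not self.roi_mask.any():
            raise ValueError("ROI mask is empty")
        if len(self.fov_mm) != 2 or any(f <= 0 for f in self.fov_mm):
            raise ValueError("fov_mm must be a positive (readout, phase) pair")

    @property
    def phase_spacing_mm(self) -> float:
        return self.fov_mm[1] / self.data.shape[1]

    def profile_1d(self) -> np.ndarray:
        """1D slice profile along phase: mean over all readout voxels."""
        return self.data.mean(axis=0)


# Rat S1 histology ranges; configuration, not constants — the layer
# boundaries are not fixed by the acquisition.
DEFAULT_LAYERS: tuple = (
    ("L1", 0.0, 0.15),
    ("L2/3", 0.15, 0.70),
    ("L4", 0.70, 1.10),
    ("L5", 1.10, 1.60),
    ("L6", 1.60, 2.00),
)


@dataclass
class LayerScheme:
    """Ordered cortical layer labels with contiguous depth intervals (mm)."""

    layers: Sequence[tuple] = DEFAULT_LAYERS

    def __post_init__(self) -> None:
        layers = [(str(name), float(lo), float(hi)) for name, lo, hi in self.layers]
        if not layers:
            raise ValueError("layer scheme is empty")
        for (_, lo, hi) in layers:
            if hi <= lo:
                raise ValueError("layer intervals must have positive extent")
        for (_, _, hi_prev), (_, lo, _) in zip(layers, layers[1:]):
            if abs(hi_prev - lo) > 1e-9:
                raise ValueError("layer intervals must be contiguous and ordered")
        self.layers = tuple(layers)

    @property
    def labels(self) -> list:
        return [name for name, _, _ in self.layers]

    @property
    def depth_range_mm(self) -> tuple:
        return (self.layers[0][1], self.layers[-1][2])

    def label_at(self, depth_mm: float) -> str:
        """Layer label containing a depth; boundaries belong to the deeper layer's
        start (half-open intervals), the final boundary to the last layer."""
        lo0, hi_last = self.depth_range_mm
        if depth_mm < lo0 or depth_mm > hi_last:
            raise ValueError(
                f"depth {depth_mm} mm outside the scheme range {lo0}-{hi_last} mm"
            )
        for name, lo, hi in self.layers:
            if lo <= depth_mm < hi:
                return name
        return self.layers[-1][0]

    def midpoint(self, label: str) -> float:
        """Representative (interval-midpoint) depth of a layer, mm."""
        for name, lo, hi in self.layers:
            if name == label:
                return 0.5 * (lo + hi)
        raise KeyError(f"unknown layer label {label!r}; have {self.labels}")
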