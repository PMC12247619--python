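"""Depth-resolved functional metrics for line-scanning BOLD series.

Percent-change maps against a pre-stimulation baseline, epoch averaging,
the two normalisation conventions used for laminar profiles, peak-layer
detection, the laminar slope between layer midpoints, 1D-profile FWHM,
background signal fraction of 2D line images, and cortical-surface
detection from intensity profiles.

All argmax-style operations break ties deterministically toward the
shallower depth / earlier time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LaminarProfile, LayerScheme, LineImage2D, LineScanSeries
from .paradigm import StimParadigm

__all__ = [
    "percent_change",
    "epoch_average",
    "normalize_map",
    "normalize_profiles_meansd",
    "PeakResult",
    "peak_layer",
    "laminar_slope",
    "profile_fwhm",
    "BackgroundMetrics",
    "background_fraction",
    "detect_cortical_surface",
]


def percent_change(series: LineScanSeries, p: StimParadigm) -> np.ndarray:
    """Depth x time percent-change map: (S - S0) / S0 * 100.

    S0 per depth is the mean over the union of all 1-s-style pre-stimulation
    windows across every epoch of the whole series, so the pre-stimulation
    samples of the output average to ~0 per depth by construction.
    """
    if series.n_time != p.n_timepoints:
        raise ValueError(
            f"paradigm length ({p.n_timepoints} samples) does not tile the "
            f"series ({series.n_time} samples)"
        )
    pre = p.pre_window_mask()
    s0 = series.data[:, pre].mean(axis=1, keepdims=True)
    if np.any(s0 == 0):
        raise ValueError("zero pre-stimulation baseline at some depth")
    return (series.data - s0) / s0 * 100.0


def epoch_average(matrix: np.ndarray, p: StimParadigm) -> np.ndarray:
    """Arithmetic mean across epochs: depth x time -> depth x epoch_samples."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n_depth, n_time = matrix.shape
    if n_time != p.n_timepoints:
        raise ValueError(
            f"matrix time length {n_time} != paradigm length {p.n_timepoints}"
        )
    return matrix.reshape(n_depth, p.n_epochs, p.epoch_samples).mean(axis=1)


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Divide by the maximum intensity so the map peaks at 1."""
    m = np.asarray(m, dtype=float)
    peak = m.max()
    if peak == 0:
        raise ValueError("cannot normalise a map whose maximum is 0")
    return m / peak


def normalize_profiles_meansd(
    mean_profile: LaminarProfile, sd_profile: LaminarProfile
) -> LaminarProfile:
    """Normalise a mean laminar profile by max over depth of (mean + SD).

    This convention bounds the normalised mean by 1 even in the presence of
    trial-to-trial variability (the normaliser is the top of the error bar).
    """
    if mean_profile.values.shape != sd_profile.values.shape:
        raise ValueError("mean and SD profiles must have the same length")
    denom = (mean_profile.values + sd_profile.values).max()
    if denom <= 0:
        raise ValueError("non-positive normaliser max(mean + SD)")
    return LaminarProfile(
        mean_profile.values / denom, mean_profile.depths_mm, units="normalized"
    )


@dataclass(frozen=True)
class PeakResult:
    depth_mm: float
    layer: str
    peak_pct: float
    depth_index: int


def peak_layer(
    avg_pct: np.ndarray,
    scheme: LayerScheme,
    depths_mm: np.ndarray,
    statistic: str = "max",
    window: slice | None = None,
) -> PeakResult:
    """Locate the peak BOLD response across depth on an epoch-averaged
    percent-change map.

    Per depth the temporal ``max`` (default) or temporal ``mean`` over an
    optional sample window is taken; the depth maximising that statistic is
    mapped to its cortical layer.  Ties break toward the shallower depth.
    """
    avg_pct = np.atleast_2d(np.asarray(avg_pct, dtype=float))
    depths_mm = np.asarray(depths_mm, dtype=float)
    if avg_pct.shape[0] != depths_mm.size:
        raise ValueError("depth grid length must match the map's depth axis")
    sub = avg_pct if window is None else avg_pct[:, window]
    if statistic == "max":
        per_depth = sub.max(axis=1)
    elif statistic == "mean":
        per_depth = sub.mean(axis=1)
    else:
        raise ValueError("statistic must be 'max' or 'mean'")
    idx = int(np.argmax(per_depth))  # first max = shallowest on ties
    depth = float(depths_mm[idx])
    return PeakResult(
        depth_mm=depth,
        layer=scheme.label_at(depth),
        peak_pct=float(per_depth[idx]),
        depth_index=idx,
    )


def laminar_slope(
    norm: LaminarProfile,
    scheme: LayerScheme,
    frm: str = "L1",
    to: str = "L2/3",
) -> float:
    """Change of a normalised profile between two layers' representative
    (midpoint) depths, in normalised units per layer step."""
    d_from = scheme.midpoint(frm)
    d_to = scheme.midpoint(to)
    return norm.interp(d_to) - norm.interp(d_from)


def profile_fwhm(profile: np.ndarray, spacing_mm: float) -> float:
    """Full width at half maximum of a 1D profile, mm.

    Half maximum is half the global peak value; the crossings are found by
    walking outward from the peak and linearly interpolating, so for a
    multimodal profile the width of the lobe containing the global maximum
    is returned.  Ties in the maximum break toward the first sample.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("profile must be 1D with at least two samples")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    k = int(np.argmax(y))
    half = y[k] / 2.0
    if y[k] <= 0:
        raise ValueError("profile peak must be positive for an FWHM")

    def _cross(idx_from: int, step: int) -> float:
        i = idx_from
        while 0 <= i + step < y.size and y[i + step] >= half:
            i += step
        j = i + step
        if j < 0 or j >= y.size:
            return float(i)  # no crossing before the edge: clamp
        # linear interpolation between samples i (>= half) and j (< half)
        frac = (y[i] - half) / (y[i] - y[j])
        return i + step * frac

    left = _cross(k, -1)
    right = _cross(k, +1)
    return (right - left) * spacing_mm


@dataclass(frozen=True)
class BackgroundMetrics:
    """Residual background outside the ROI of a 2D line image."""

    s_roi: float
    n_bkg: float
    fraction_pct: float


def background_fraction(img: LineImage2D) -> BackgroundMetrics:
    """Mean outside-ROI signal over mean in-ROI signal, as a percentage."""
    inside = img.data[img.roi_mask]
    outside = img.data[~img.roi_mask]
    if outside.size == 0:
        raise ValueError("ROI covers the whole image; no background to measure")
    s_roi = float(inside.mean())
    if s_roi <= 0:
        raise ValueError("mean in-ROI signal must be positive")
    n_bkg = float(outside.mean())
    return BackgroundMetrics(
        s_roi=s_roi, n_bkg=n_bkg, fraction_pct=n_bkg / s_roi * 100.0
    )


def detect_cortical_surface(
    intensity: LaminarProfile,
    frac: float = 0.5,
    robust_pctl: float = 95.0,
) -> tuple[int, float]:
    """First depth index (from the shallow end) whose intensity reaches
    ``frac`` of the robust maximum (the ``robust_pctl`` percentile).

    Returns ``(index, threshold)``.  This half-of-robust-maximum rule is a
    documented, configurable stand-in for surface detection on line-profile
    intensities; the robust maximum guards against single hot voxels.
    """
    y = intensity.values
    thr = frac * float(np.percentile(y, robust_pctl))
    above = np.nonzero(y >= thr)[0]
    if above.size == 0:
        raise ValueError("no sample reaches the surface-detection threshold")
    return int(above[0]), thr
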