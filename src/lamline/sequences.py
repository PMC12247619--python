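"""Closed-form steady-state signal models for line-scanning MRI sequences.

Two protocols are modelled:

* a spin-echo (SE) line-scanning sequence in which the refocusing pulse is
  applied perpendicular to the excitation slice (an "alpha-180" scheme), and
* a spoiled gradient-echo (GRE) line-scanning sequence.

For a train of identical excitations the longitudinal magnetisation reaches a
steady state, and the transverse signal at the echo time follows a closed
form of the Bloch equations.  With ``E1 = exp(-TR/T1)`` and
``E1p = exp(-(TR - TE/2)/T1)``:

SE (excitation angle alpha, refocusing angle beta)::

    S(alpha, beta) = sin(alpha) * (1 - cos(beta)*E1 - (1 - cos(beta))*E1p)
                     / (1 - cos(alpha)*cos(beta)*E1) * exp(-TE/T2)

GRE (excitation angle theta)::

    S(theta) = sin(theta) * (1 - E1) / (1 - cos(theta)*E1) * exp(-TE/T2*)

The SE expression reduces to the GRE one at ``beta = 0`` (``cos(beta) = 1``).
The excitation angle maximising the signal has the closed forms
``alpha* = arccos(-E1)`` (SE with a 180 deg refocusing pulse) and the Ernst
angle ``theta* = arccos(E1)`` (GRE).

The module also predicts the *relative* temporal SNR of a protocol, assuming
tSNR scales linearly with SNR and that voxel SNR is proportional to voxel
size (here the readout FOV, with a fixed matrix) and inversely proportional
to the square root of the readout bandwidth:

    relative tSNR = S_steady_state * readout_fov[m] / sqrt(readout_bw[Hz])

This is a comparative figure of merit between protocols on the same
hardware, not an absolute SNR prediction; noise-source differences
(thermal, physiological, residual background) are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SequenceParams",
    "se_steady_state",
    "gre_steady_state",
    "optimal_flip_angle",
    "grid_search_flip_angle",
    "flip_angle_curve",
    "predicted_relative_tsnr",
    "tsnr_ratio",
    "tsnr_efficiency",
    "PROTOCOL_PRESETS",
]

# Cortical grey-matter relaxation constants (ms) measured in rat
# somatosensory cortex at high field; package-wide defaults.
T1_CORTEX_MS = 2211.0
T2_CORTEX_MS = 24.0
T2STAR_CORTEX_MS = 20.0


@dataclass(frozen=True)
class SequenceParams:
    """One line-scanning protocol: timing, angles, relaxation and readout.

    ``t2_ms`` holds the transverse constant appropriate to the sequence:
    T2 for spin echo, T2* for gradient echo.  ``readout_fov_m`` is the
    readout field of view in metres; angles are degrees at the interface.
    """

    kind: str  # "SE" or "GRE"
    tr_ms: float
    te_ms: float
    exc_fa_deg: float  # alpha (SE) or theta (GRE)
    refocus_fa_deg: float = 180.0  # beta; SE only
    t1_ms: float = T1_CORTEX_MS
    t2_ms: float = T2_CORTEX_MS
    readout_bw_hz: float = 5000.0
    readout_fov_m: float = 0.0032
    readout_matrix: int = 64

    def __post_init__(self) -> None:
        if self.kind not in ("SE", "GRE"):
            raise ValueError(f"kind must be 'SE' or 'GRE', got {self.kind!r}")
        if not (self.tr_ms > self.te_ms > 0):
            raise ValueError("require tr > te > 0")
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation constants must be positive")
        _check_angle(self.exc_fa_deg, "excitation flip angle")
        if self.kind == "SE":
            _check_angle(self.refocus_fa_deg, "refocusing flip angle")
        if self.readout_bw_hz <= 0:
            raise ValueError("readout bandwidth must be positive")
        if self.readout_fov_m <= 0:
            raise ValueError("readout FOV must be positive")
        if self.readout_matrix < 1:
            raise ValueError("readout matrix must be >= 1")

    def with_exc_fa(self, fa_deg: float) -> "SequenceParams":
        return replace(self, exc_fa_deg=fa_deg)

    @classmethod
    def from_config(cls, cfg: dict) -> "SequenceParams":
        """Build from a JSON-style mapping (FOV given in mm)."""
        known = {
            "kind", "tr_ms", "te_ms", "exc_fa_deg", "refocus_fa_deg",
            "t1_ms", "t2_ms", "readout_bw_hz", "readout_fov_mm",
            "readout_matrix",
        }
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown protocol config keys: {sorted(unknown)}")
        kw = {k: v for k, v in cfg.items() if k != "readout_fov_mm"}
        if "readout_fov_mm" in cfg:
            kw["readout_fov_m"] = float(cfg["readout_fov_mm"]) / 1000.0
        return cls(**kw)

    def to_config(self) -> dict:
        return {
            "kind": self.kind,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "exc_fa_deg": self.exc_fa_deg,
            "refocus_fa_deg": self.refocus_fa_deg,
            "t1_ms": self.t1_ms,
            "t2_ms": self.t2_ms,
            "readout_bw_hz": self.readout_bw_hz,
            "readout_fov_mm": self.readout_fov_m * 1000.0,
            "readout_matrix": self.readout_matrix,
        }


def _check_angle(fa_deg: float, name: str, allow_zero: bool = False) -> None:
    fa = np.asarray(fa_deg, dtype=float)
    lo_bad = np.any(fa < 0.0) if allow_zero else np.any(fa <= 0.0)
    if lo_bad or np.any(fa > 180.0):
        lo = "[0" if allow_zero else "(0"
        raise ValueError(f"{name} must lie in {lo}, 180] degrees, got {fa_deg}")


def _check_se_timing(p: SequenceParams) -> None:
    # the recovery interval TR - TE/2 between the echo and the next
    # excitation must be positive
    if p.te_ms >= 2.0 * p.tr_ms:
        raise ValueError("spin-echo model requires TE < 2*TR")


def se_steady_state(
    p: SequenceParams,
    alpha_deg: Optional[float] = None,
    beta_deg: Optional[float] = None,
):
    """Steady-state spin-echo signal, dimensionless in [0, 1].

    ``alpha_deg``/``beta_deg`` override the protocol's excitation and
    refocusing angles; both accept arrays for flip-angle sweeps.
    """
    if p.kind != "SE":
        raise ValueError("se_steady_state requires kind='SE'")
    _check_se_timing(p)
    alpha = p.exc_fa_deg if alpha_deg is None else alpha_deg
    beta = p.refocus_fa_deg if beta_deg is None else beta_deg
    # alpha = 0 (no excitation, zero signal) and beta = 0 (degenerate into
    # the gradient-echo form) are admitted as limits of the closed form
    _check_angle(alpha, "alpha", allow_zero=True)
    _check_angle(beta, "beta", allow_zero=True)
    a = np.deg2rad(alpha)
    b = np.deg2rad(beta)
    e1 = math.exp(-p.tr_ms / p.t1_ms)
    e1p = math.exp(-(p.tr_ms - p.te_ms / 2.0) / p.t1_ms)
    num = np.sin(a) * (1.0 - np.cos(b) * e1 - (1.0 - np.cos(b)) * e1p)
    den = 1.0 - np.cos(a) * np.cos(b) * e1
    s = num / den * math.exp(-p.te_ms / p.t2_ms)
    return s if np.ndim(s) else float(s)


def gre_steady_state(p: SequenceParams, theta_deg: Optional[float] = None):
    """Steady-state spoiled gradient-echo signal, dimensionless in [0, 1].

    ``p.t2_ms`` is interpreted as T2*.
    """
    if p.kind != "GRE":
        raise ValueError("gre_steady_state requires kind='GRE'")
    theta = p.exc_fa_deg if theta_deg is None else theta_deg
    _check_angle(theta, "theta", allow_zero=True)
    th = np.deg2rad(theta)
    e1 = math.exp(-p.tr_ms / p.t1_ms)
    s = np.sin(th) * (1.0 - e1) / (1.0 - np.cos(th) * e1) * math.exp(
        -p.te_ms / p.t2_ms
    )
    return s if np.ndim(s) else float(s)


def steady_state_signal(p: SequenceParams, exc_fa_deg: Optional[float] = None):
    """Dispatch to the SE or GRE model according to ``p.kind``."""
    if p.kind == "SE":
        return se_steady_state(p, alpha_deg=exc_fa_deg)
    return gre_steady_state(p, theta_deg=exc_fa_deg)


def optimal_flip_angle(p: SequenceParams) -> float:
    """Excitation angle (degrees) maximising the steady-state signal.

    Analytic where a closed form exists — ``arccos(-E1)`` for SE with a
    180 deg refocusing pulse, the Ernst angle ``arccos(E1)`` for GRE —
    otherwise a fine grid search over (0, 180].
    """
    e1 = math.exp(-p.tr_ms / p.t1_ms)
    if p.kind == "GRE":
        return math.degrees(math.acos(e1))
    if abs(p.refocus_fa_deg - 180.0) < 1e-9:
        return math.degrees(math.acos(-e1))
    return grid_search_flip_angle(p)


def grid_search_flip_angle(p: SequenceParams, step_deg: float = 0.1) -> float:
    """Brute-force argmax of the steady-state signal over (0, 180].

    Deterministic: ties break toward the smaller angle.
    """
    angles = np.arange(step_deg, 180.0 + step_deg / 2.0, step_deg)
    signal = steady_state_signal(p, angles)
    return float(angles[int(np.argmax(signal))])


def flip_angle_curve(p: SequenceParams, step_deg: float = 1.0):
    """(angles_deg, signal) arrays of the steady-state signal sweep."""
    angles = np.arange(step_deg, 180.0 + step_deg / 2.0, step_deg)
    return angles, np.asarray(steady_state_signal(p, angles))


def predicted_relative_tsnr(p: SequenceParams) -> float:
    """Model-predicted relative tSNR of a protocol (arbitrary units).

    ``steady-state signal x readout_fov[m] / sqrt(readout_bw[Hz])``: linear
    in FOV, proportional to 1/sqrt(bandwidth).  Comparable only between
    protocols evaluated with the same convention.
    """
    s = steady_state_signal(p)
    return float(s) * p.readout_fov_m / math.sqrt(p.readout_bw_hz)


def tsnr_ratio(a: SequenceParams, b: SequenceParams) -> float:
    """Ratio of model-predicted relative tSNRs, protocol a over protocol b."""
    return predicted_relative_tsnr(a) / predicted_relative_tsnr(b)


def tsnr_efficiency(tsnr: float, tr_ms: float) -> float:
    """tSNR per square-root second of sampling time: ``tsnr / sqrt(TR[s])``.

    Normalises measured tSNR for the acquisition rate so protocols with
    different TRs can be compared per unit scan time.
    """
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    return tsnr / math.sqrt(tr_ms / 1000.0)


# Acquisition parameter sets of the three line-scanning protocols modelled
# here (readout FOV in metres; t2_ms holds T2* for the GRE protocol).
PROTOCOL_PRESETS: dict = {
    "geline": SequenceParams(
        kind="GRE", tr_ms=100.0, te_ms=12.5, exc_fa_deg=50.0,
        t1_ms=T1_CORTEX_MS, t2_ms=T2STAR_CORTEX_MS,
        readout_bw_hz=9014.0, readout_fov_m=0.0064, readout_matrix=128,
    ),
    "seline": SequenceParams(
        kind="SE", tr_ms=1000.0, te_ms=20.0, exc_fa_deg=90.0,
        refocus_fa_deg=180.0, t1_ms=T1_CORTEX_MS, t2_ms=T2_CORTEX_MS,
        readout_bw_hz=5000.0, readout_fov_m=0.0032, readout_matrix=64,
    ),
    "seline-fast": SequenceParams(
        kind="SE", tr_ms=200.0, te_ms=10.0, exc_fa_deg=150.0,
        refocus_fa_deg=180.0, t1_ms=T1_CORTEX_MS, t2_ms=T2_CORTEX_MS,
        readout_bw_hz=9014.0, readout_fov_m=0.0064, readout_matrix=64,
    ),
}
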