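"""Block stimulation paradigm, gamma-variate block HRF and GLM amplitude fit.

The stimulation paradigm is a block design: each epoch is
``pre_s`` seconds of baseline, ``stim_s`` seconds of stimulation and
``post_s`` seconds of recovery, repeated ``n_epochs`` times and sampled
every ``tr_ms`` milliseconds.

The haemodynamic response to a block of duration L is modelled as the
convolution of the stimulus square wave with the gamma-variate kernel

    g(t) = t^4 e^(-t) / (4^4 e^(-4)),

which peaks at 1 at t = 4 s.  Equivalently, the response to a block that
started at t = 0 is the running integral ``HRF(t) = int_0^min(t, L) g(s) ds``.
The design regressor is peak-normalised so that a fitted amplitude ("beta")
reads directly as the peak height of the block response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .core import LineScanSeries

__all__ = [
    "StimParadigm",
    "HRFModel",
    "build_boxcar",
    "gamma_kernel",
    "block_hrf",
    "build_design_regressor",
    "glm_beta",
]

# g's normaliser: peak value t^4 e^-t at t=4
_G_NORM = 4.0 ** 4 * math.exp(-4.0)


def _segment_samples(duration_s: float, tr_s: float, name: str) -> int:
    n = duration_s / tr_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"{name} ({duration_s} s) is not an integer multiple of TR ({tr_s} s)"
        )
    return int(round(n))


@dataclass(frozen=True)
class StimParadigm:
    """Block-design timing: pre / stim / post durations (s), epoch count, TR."""

    pre_s: float = 1.0
    stim_s: float = 4.0
    post_s: float = 15.0
    n_epochs: int = 32
    tr_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if min(self.pre_s, self.stim_s, self.post_s) < 0 or self.stim_s == 0:
            raise ValueError("segment durations must be non-negative, stim_s > 0")
        # all three segments must tile the sampling grid exactly
        self.pre_samples, self.stim_samples, self.post_samples  # noqa: B018

    @property
    def tr_s(self) -> float:
        return self.tr_ms / 1000.0

    @property
    def epoch_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def pre_samples(self) -> int:
        return _segment_samples(self.pre_s, self.tr_s, "pre_s")

    @property
    def stim_samples(self) -> int:
        return _segment_samples(self.stim_s, self.tr_s, "stim_s")

    @property
    def post_samples(self) -> int:
        return _segment_samples(self.post_s, self.tr_s, "post_s")

    @property
    def epoch_samples(self) -> int:
        return self.pre_samples + self.stim_samples + self.post_samples

    @property
    def n_timepoints(self) -> int:
        return self.n_epochs * self.epoch_samples

    def pre_window_mask(self) -> np.ndarray:
        """Boolean mask over the whole series marking every pre-stimulation
        window (the per-epoch baseline samples)."""
        epoch = np.zeros(self.epoch_samples, dtype=bool)
        epoch[: self.pre_samples] = True
        return np.tile(epoch, self.n_epochs)

    @classmethod
    def from_config(cls, cfg: dict) -> "StimParadigm":
        known = {"pre_s", "stim_s", "post_s", "n_epochs", "tr_ms"}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown paradigm config keys: {sorted(unknown)}")
        return cls(**cfg)

    def to_config(self) -> dict:
        return {
            "pre_s": self.pre_s, "stim_s": self.stim_s, "post_s": self.post_s,
            "n_epochs": self.n_epochs, "tr_ms": self.tr_ms,
        }


@dataclass(frozen=True)
class HRFModel:
    """Gamma-variate block response model.

    ``duration_L_s`` is the stimulus block duration L; ``dt_s`` the sampling
    step used when the model is evaluated on its own grid; ``normalize_peak``
    selects the convention in which the block response has peak amplitude 1.
    """

    duration_L_s: float = 4.0
    dt_s: float = 0.1
    normalize_peak: bool = True

    def __post_init__(self) -> None:
        if self.duration_L_s <= 0:
            raise ValueError("duration_L_s must be positive")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")


def build_boxcar(p: StimParadigm) -> np.ndarray:
    """Binary stimulus indicator over the full series (1 during stimulation)."""
    epoch = np.zeros(p.epoch_samples)
    epoch[p.pre_samples : p.pre_samples + p.stim_samples] = 1.0
    return np.tile(epoch, p.n_epochs)


def gamma_kernel(t):
    """Gamma-variate impulse kernel g(t) = t^4 e^(-t) / (4^4 e^(-4)).

    Unimodal, g(0) = 0, peak value 1 at t = 4 s; zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, t ** 4 * np.exp(-np.minimum(t, 700.0)) / _G_NORM, 0.0)
    return out if out.ndim else float(out)


def _gamma_integral(x):
    """int_0^x g(s) ds in closed form via the regularised lower incomplete
    gamma function: Gamma(5) P(5, x) / (4^4 e^-4)."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    return 24.0 * special.gammainc(5, x) / _G_NORM


def block_hrf(m: HRFModel, t):
    """Response at time t to a stimulus block of duration L starting at t = 0.

    Raw form: ``HRF(t) = int_0^min(t, L) g(s) ds`` — non-decreasing, 0 at
    t = 0, constant for t >= L.  With ``normalize_peak`` the curve is scaled
    so its maximum is exactly 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("block_hrf requires t >= 0")
    h = _gamma_integral(np.minimum(t, m.duration_L_s))
    if m.normalize_peak:
        h = h / _gamma_integral(m.duration_L_s)
    return h if h.ndim else float(h)


def build_design_regressor(
    p: StimParadigm,
    m: HRFModel | None = None,
    per_epoch: bool = True,
    kernel_support_s: float = 32.0,
) -> np.ndarray:
    """Expected BOLD regressor: stimulus boxcar convolved with g, sampled at
    the series TR and peak-normalised (when the model requests it).

    With ``per_epoch`` (default) the convolution is computed for a single
    epoch and tiled, so every epoch's expected response is identical and the
    pre-stimulation window of each epoch is exactly at baseline; response
    carry-over past an epoch boundary (< 0.4 % of peak for 20-s epochs) is
    discarded.  With ``per_epoch=False`` the full-series boxcar is convolved
    with a kernel truncated at ``kernel_support_s`` and the first epoch may
    differ slightly from the rest.
    """
    if m is None:
        m = HRFModel(duration_L_s=p.stim_s, dt_s=p.tr_s)
    dt = p.tr_s
    if per_epoch:
        epoch_box = np.zeros(p.epoch_samples)
        epoch_box[p.pre_samples : p.pre_samples + p.stim_samples] = 1.0
        kernel = gamma_kernel(np.arange(p.epoch_samples) * dt) * dt
        epoch_resp = np.convolve(epoch_box, kernel)[: p.epoch_samples]
        reg = np.tile(epoch_resp, p.n_epochs)
    else:
        box = build_boxcar(p)
        n_kernel = int(round(kernel_support_s / dt)) + 1
        kernel = gamma_kernel(np.arange(n_kernel) * dt) * dt
        reg = np.convolve(box, kernel)[: box.size]
    peak = reg.max()
    if m.normalize_peak and peak > 0:
        reg = reg / peak
    return reg


def glm_beta(series: LineScanSeries, regressor: np.ndarray) -> np.ndarray:
    """Per-depth response amplitude by ordinary least squares.

    Design: intercept, linear drift, regressor.  The returned coefficient is
    the regressor weight per depth; with a peak-normalised regressor it is
    the peak height of the fitted block response, in the units of the series.
    """
    regressor = np.asarray(regressor, dtype=float)
    if regressor.ndim != 1 or regressor.size != series.n_time:
        raise ValueError(
            f"regressor length {regressor.size} does not match series "
            f"time length {series.n_time}"
        )
    n = series.n_time
    drift = np.linspace(-1.0, 1.0, n)
    design = np.column_stack([np.ones(n), drift, regressor])
    _check_design_rank(design, ["intercept", "linear drift", "regressor"])
    beta, *_ = np.linalg.lstsq(design, series.data.T, rcond=None)
    return beta[2]


def _check_design_rank(design: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return
    # identify the offending column for the error message: the first one
    # linearly dependent on those before it
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(
            design[:, :j]
        ):
            raise np.linalg.LinAlgError(
                f"rank-deficient GLM design: column '{names[j]}' is collinear "
                "with the preceding columns"
            )
    raise np.linalg.LinAlgError("rank-deficient GLM design")
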