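"""Optional noise reduction and resampling before fitting.

Breath-by-breath V̇O₂ is irregularly sampled (~0.5 Hz) and noisy.  Two
optional steps condition it for fitting: a Savitzky–Golay polynomial filter
(default 5-point window, order 2) that reduces breath-to-breath scatter while
preserving peaks and slopes, and cubic-spline resampling onto a uniform grid
(default 1 s step over a 15-min window).  When both are requested the filter
runs first, so the spline interpolates the smoothed breaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .errors import InsufficientDataError
from .io import BreathSeries


@dataclass(frozen=True)
class PreprocessConfig:
    smooth: bool = False
    sg_window: int = 5
    sg_order: int = 2
    interpolate: bool = False
    grid_step: float = 1.0
    window_s: float = 900.0

    def __post_init__(self) -> None:
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 5")
        if not (0 < self.sg_order < self.sg_window):
            raise ValueError("sg_order must satisfy 0 < order < window")
        if self.grid_step <= 0 or self.window_s <= 0:
            raise ValueError("grid_step and window_s must be positive")


def smooth_series(series: BreathSeries, cfg: PreprocessConfig | None = None) -> BreathSeries:
    """Savitzky–Golay filter over the V̇O₂ samples (timestamps unchanged).

    Interior points use the standard convolution; the first and last
    half-window points are re-fit with a polynomial over the available
    (shrunk) window instead of padded data, so no pre-recovery values are
    fabricated.  The filter operates in sample-index space, the usual
    convention for near-uniform breath spacing.
    """
    cfg = cfg or PreprocessConfig(smooth=True)
    n = len(series)
    if n < cfg.sg_window:
        raise InsufficientDataError(
            f"series of length {n} shorter than filter window {cfg.sg_window}"
        )
    y = savgol_filter(series.vo2, cfg.sg_window, cfg.sg_order, mode="interp")
    h = cfg.sg_window // 2
    for i in list(range(h)) + list(range(n - h, n)):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        idx = np.arange(lo, hi)
        order = min(cfg.sg_order, len(idx) - 1)
        coef = np.polyfit(idx - i, series.vo2[lo:hi], order)
        y[i] = np.polyval(coef, 0.0)
    meta = dict(series.meta, smoothed=True, sg_window=cfg.sg_window, sg_order=cfg.sg_order)
    return series.replace(vo2=y, meta=meta)


def resample_series(series: BreathSeries, cfg: PreprocessConfig | None = None) -> BreathSeries:
    """Cubic-spline resampling onto a uniform grid over [0, window_s].

    A natural cubic interpolating spline (zero second derivative at the ends)
    passes through every input breath; the uniform grid uses ``grid_step``
    seconds and is truncated to the observed time range — no extrapolation.
    """
    cfg = cfg or PreprocessConfig(interpolate=True)
    if len(series) < 4:
        raise InsufficientDataError("cubic spline needs at least 4 samples")
    spline = CubicSpline(series.t, series.vo2, bc_type="natural")
    n_steps = int(np.floor(cfg.window_s / cfg.grid_step + 1e-9))
    grid = np.arange(n_steps + 1) * cfg.grid_step
    truncated = bool(grid[-1] > series.t[-1] + 1e-12)
    grid = grid[(grid >= series.t[0] - 1e-12) & (grid <= series.t[-1] + 1e-12)]
    if len(grid) < 2:
        raise InsufficientDataError("resampling grid has fewer than 2 points")
    meta = dict(
        series.meta,
        interpolated=True,
        grid_step=cfg.grid_step,
        spline_bc="natural",
        window_truncated_to_data=truncated,
    )
    return series.replace(t=grid, vo2=np.asarray(spline(grid)), meta=meta)


def clip_window(series: BreathSeries, t_max: float) -> BreathSeries:
    """Retain samples with t <= t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    keep = series.t <= t_max
    if not np.any(keep):
        raise InsufficientDataError(f"no samples at or before t={t_max}")
    return series.replace(t=series.t[keep], vo2=series.vo2[keep],
                          meta=dict(series.meta, clipped_at=t_max))


def apply_preprocessing(series: BreathSeries, cfg: PreprocessConfig | None) -> BreathSeries:
    """Run the configured steps in canonical order: smooth, then resample."""
    if cfg is None:
        return series
    out = series
    if cfg.smooth:
        out = smooth_series(out, cfg)
    if cfg.interpolate:
        out = resample_series(out, cfg)
    return out
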