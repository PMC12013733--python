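"""Fit-quality and model-selection statistics.

R² is reported over the full fitted window and over the first minutes of
recovery only ("fast-phase R²", default 300 s window) — the fast phase is
what alactic-energy estimation depends on, so a model can look good overall
yet misrepresent the part that matters.  Model selection uses the
least-squares AIC and the small-sample corrected AICc:

    AIC  = n·ln(RSS/n) + 2k
    AICc = AIC + 2k(k+1)/(n − k − 1)

``k`` counts only free parameters (a measured, user-fixed baseline is not
estimated and is not counted); ``n`` is the post-preprocessing sample count
actually fitted, so AICc values are comparable only within one pipeline
configuration.  The Gaussian error-variance parameter is not counted in k
(pure least-squares convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .fitting import FitResult
from .io import BreathSeries


@dataclass(frozen=True)
class FitStats:
    r2: float
    r2_fast: float
    aic: float
    aicc: float
    n: int
    k: int
    rss: float

    def to_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2, "r2_fast": self.r2_fast,
            "aic": self.aic, "aicc": self.aicc,
            "n": self.n, "k": self.k, "rss": self.rss,
        }


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − SSres/SStot.

    SStot is taken about the mean of the evaluated subset of observations.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise UndefinedStatisticError("need equal-length arrays of >= 3 samples")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("R² undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared_fast(series: BreathSeries, fit: FitResult, fast_window: float = 300.0) -> float:
    """R² restricted to t <= fast_window, using the full-window fitted
    parameters (no refit); SStot uses the subset mean."""
    mask = series.t <= fast_window
    if mask.sum() < 3:
        raise UndefinedStatisticError(
            f"fewer than 3 samples at or before t={fast_window}"
        )
    return r_squared(series.vo2[mask], fit.predict(series.t[mask]))


def aic_aicc(rss: float, n: int, k: int) -> tuple[float, float]:
    """Least-squares AIC and small-sample corrected AICc."""
    if n <= k + 1:
        raise UndefinedStatisticError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if rss <= 0:
        raise UndefinedStatisticError("AIC undefined for rss <= 0")
    aic = n * np.log(rss / n) + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    return float(aic), float(aicc)


def compute_stats(series: BreathSeries, fit: FitResult, fast_window: float = 300.0) -> FitStats:
    """All fit statistics for one FitResult evaluated on ``series``.

    ``series`` must be the (preprocessed) series the model was fitted to, so
    that n and rss are mutually consistent.
    """
    r2 = r_squared(series.vo2, fit.predict(series.t))
    r2f = r_squared_fast(series, fit, fast_window)
    aic, aicc = aic_aicc(fit.rss, fit.n, fit.k)
    return FitStats(r2=r2, r2_fast=r2f, aic=aic, aicc=aicc, n=fit.n, k=fit.k, rss=fit.rss)
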