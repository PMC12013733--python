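"""Bounded nonlinear least-squares estimation of recovery kinetics.

The estimators follow the scikit-learn API: ``X`` is a single column of
recovery times in seconds, ``y`` the V̇O₂ samples.  The headline feature is
a *user-fixed measured baseline*: when the resting V̇O₂ is supplied it is
removed from the free-parameter set, anchoring the asymptote at the
physiological recovery target instead of letting the optimizer auto-calibrate
it (which inflates baseline, amplitude, and tau on 15-min windows where V̇O₂
has not yet returned to rest).  Free-baseline fitting is retained to
demonstrate exactly that distortion.

Bounds are physiologically informed and adaptive: amplitudes scale with the
observed peak, the fast time constant stays below ~2 min and the slow one
above it, which keeps the problem box-constrained while enforcing the
fast/slow phase ordering structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ConfigError, DegenerateSeriesError, InsufficientDataError
from .io import BreathSeries
from .models import BiParams, MonoParams, Params, eval_bi, eval_mono, eval_params
from .preprocess import PreprocessConfig, apply_preprocessing

ModelName = Literal["mono", "bi"]

MONO_PARAM_NAMES = ("baseline", "A", "td", "tau")
BI_PARAM_NAMES = ("baseline", "A1", "td", "tau1", "A2", "tau2")

#: Optimizer stopping rules: relative rss change, parameter step, iteration cap.
FTOL = 1e-10
XTOL = 1e-8
MAX_NFEV = 2000

#: Minimum recovery coverage (s) required before fitting is attempted.
MIN_COVERAGE_S = 120.0


@dataclass(frozen=True)
class FitBounds:
    """Per-parameter (lower, upper) box bounds."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigError(f"bounds for {name!r}: lower {lo} must be < upper {hi}")

    def with_overrides(self, overrides: dict[str, tuple[float, float]] | None) -> "FitBounds":
        if not overrides:
            return self
        merged = dict(self.bounds)
        for name, pair in overrides.items():
            if name not in merged:
                raise ConfigError(f"unknown bound parameter {name!r}")
            merged[name] = (float(pair[0]), float(pair[1]))
        return FitBounds(merged)

    def arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]


@dataclass
class FitResult:
    """One model fitted to one series: parameters plus everything downstream
    metrics need (rss, n, k, convergence, unit provenance)."""

    params: Params
    model: ModelName
    baseline_fixed: bool
    rss: float
    n: int
    k: int
    converged: bool
    n_iterations: int
    bounds: FitBounds
    unit_mode: str = "absolute"
    body_mass_kg: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def predict(self, t) -> np.ndarray:
        return eval_params(self.params, t)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "baseline_fixed": self.baseline_fixed,
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "unit_mode": self.unit_mode,
            "bounds": {k: list(v) for k, v in self.bounds.bounds.items()},
            "meta": self.meta,
        }


def default_bounds(
    model: ModelName,
    unit_mode: str = "absolute",
    series: BreathSeries | None = None,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> FitBounds:
    """Physiologically informed default box bounds.

    Absolute mode: baseline 100–1000 mL/min (used only when the baseline is a
    free parameter), amplitudes 0–max(8000, 1.5·peak) mL/min, delay 0–30 s,
    mono tau 10–600 s, fast tau 5–120 s, slow tau 120–2000 s.  Relative mode
    rescales the amplitude ceiling to 100 mL/kg/min and the baseline window
    to 1–15 mL/kg/min.  Everything is overridable.
    """
    peak = float(np.max(series.vo2)) if series is not None and len(series) else 0.0
    if unit_mode == "relative":
        amp_hi = 100.0
        base_lo, base_hi = 1.0, 15.0
    else:
        amp_hi = max(8000.0, 1.5 * peak)
        base_lo, base_hi = 100.0, 1000.0
    common = {"baseline": (base_lo, base_hi), "td": (0.0, 30.0)}
    if model == "mono":
        b = {**common, "A": (0.0, amp_hi), "tau": (10.0, 600.0)}
    elif model == "bi":
        b = {
            **common,
            "A1": (0.0, amp_hi),
            "tau1": (5.0, 120.0),
            "A2": (0.0, amp_hi),
            "tau2": (120.0, 2000.0),
        }
    else:
        raise ConfigError(f"unknown model {model!r}")
    return FitBounds(b).with_overrides(overrides)


def initial_guess(model: ModelName, series: BreathSeries, baseline: float) -> dict[str, float]:
    """Deterministic starting point.

    Mono: A₀ = peak − baseline, td₀ = 3 s, tau₀ = 150 s.  Bi: the amplitude is
    split 75/25 between fast and slow phases with tau₁₀ = 60 s, tau₂₀ = 600 s.
    """
    peak = float(np.max(series.vo2))
    if peak <= baseline:
        raise DegenerateSeriesError(
            f"series peak {peak:.1f} does not exceed baseline {baseline:.1f}"
        )
    amp = peak - baseline
    if model == "mono":
        return {"baseline": baseline, "A": amp, "td": 3.0, "tau": 150.0}
    return {
        "baseline": baseline,
        "A1": 0.75 * amp,
        "td": 3.0,
        "tau1": 60.0,
        "A2": 0.25 * amp,
        "tau2": 600.0,
    }


def _clip_into(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lo), hi)


class _ExponentialRegressorBase(RegressorMixin, BaseEstimator):
    """Shared machinery for the mono/bi recovery regressors."""

    _model: ModelName = "mono"
    _param_names: tuple[str, ...] = MONO_PARAM_NAMES

    def __init__(
        self,
        baseline: float | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        unit_mode: str = "absolute",
        multistart: bool = False,
        exclude_pre_td: bool = False,
    ) -> None:
        self.baseline = baseline
        self.bounds = bounds
        self.unit_mode = unit_mode
        self.multistart = multistart
        self.exclude_pre_td = exclude_pre_td

    # -- model plumbing -------------------------------------------------
    def _free_names(self) -> list[str]:
        names = list(self._param_names)
        if self.baseline is not None:
            names.remove("baseline")
        return names

    def _make_params(self, free: np.ndarray, free_names: Sequence[str]) -> Params:
        d = dict(zip(free_names, (float(v) for v in free)))
        if self.baseline is not None:
            d["baseline"] = float(self.baseline)
        cls = MonoParams if self._model == "mono" else BiParams
        return cls.from_dict(d)

    def _tau_starts(self, fb: FitBounds) -> list[dict[str, float]]:
        """Deterministic tau grid for multi-start (geometric, in-bounds)."""
        def grid(name: str) -> np.ndarray:
            lo, hi = fb[name]
            return np.geomspace(max(lo, 1e-3) * 1.25, hi * 0.8, 3)

        if self._model == "mono":
            return [{"tau": float(v)} for v in grid("tau")]
        return [
            {"tau1": float(a), "tau2": float(b)}
            for a in grid("tau1")
            for b in grid("tau2")
        ]

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2, y_numeric=True)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of recovery times (s)")
        t = X[:, 0].astype(float)
        order = np.argsort(t, kind="stable")
        t, y = t[order], np.asarray(y, dtype=float)[order]
        if float(t[-1] - t[0]) < MIN_COVERAGE_S:
            raise InsufficientDataError(
                f"series covers {t[-1] - t[0]:.0f} s; need >= {MIN_COVERAGE_S:.0f} s"
            )
        if np.ptp(y) == 0:
            raise DegenerateSeriesError("all V̇O₂ samples are equal")

        series_like = BreathSeries(t=t, vo2=y, unit_mode=self.unit_mode)
        fb = default_bounds(self._model, self.unit_mode, series_like,
                            overrides=self.bounds)
        free_names = self._free_names()
        k = len(free_names)
        if len(t) <= k + 1:
            raise InsufficientDataError(f"n={len(t)} too small for k={k} parameters")

        base0 = (
            float(self.baseline)
            if self.baseline is not None
            else float(np.clip(np.min(y), *fb["baseline"]))
        )
        guess = initial_guess(self._model, series_like, base0)

        starts = [guess]
        if self.multistart:
            starts += [dict(guess, **tw) for tw in self._tau_starts(fb)]
        starts += self._extra_starts(t, y, fb, guess)

        lo, hi = fb.arrays(free_names)
        best = None
        for s in starts:
            x0 = _clip_into(np.array([s[n] for n in free_names]), lo, hi)
            sol = least_squares(
                lambda v: self._residuals(v, free_names, t, y),
                x0, bounds=(lo, hi), method="trf",
                ftol=FTOL, xtol=XTOL, max_nfev=MAX_NFEV,
            )
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 0.0:  # strict: first-wins ties
                best = (rss, sol)
        rss, sol = best

        self.params_ = self._make_params(sol.x, free_names)
        if self.exclude_pre_td:
            mask = t >= self.params_.td
            if mask.sum() > k + 1:
                sol2 = least_squares(
                    lambda v: self._residuals(v, free_names, t[mask], y[mask]),
                    _clip_into(sol.x, lo, hi), bounds=(lo, hi), method="trf",
                    ftol=FTOL, xtol=XTOL, max_nfev=MAX_NFEV,
                )
                sol, rss = sol2, float(np.sum(sol2.fun**2))
                t, y = t[mask], y[mask]
                self.params_ = self._make_params(sol.x, free_names)

        self.rss_ = rss
        self.n_ = len(t)
        self.k_ = k
        self.converged_ = bool(sol.status > 0)
        self.n_iter_ = int(sol.nfev)
        self.bounds_ = fb
        self.n_features_in_ = 1
        return self

    def _extra_starts(self, t, y, fb: FitBounds, guess: dict[str, float]) -> list[dict[str, float]]:
        return []

    def _residuals(self, free, free_names, t, y):
        return eval_params(self._make_params(free, free_names), t) - y

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X)
        return eval_params(self.params_, X[:, 0].astype(float))

    def result_(self, meta: dict[str, Any] | None = None,
                body_mass_kg: float | None = None) -> FitResult:
        check_is_fitted(self, "params_")
        return FitResult(
            params=self.params_,
            model=self._model,
            baseline_fixed=self.baseline is not None,
            rss=self.rss_,
            n=self.n_,
            k=self.k_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            bounds=self.bounds_,
            unit_mode=self.unit_mode,
            body_mass_kg=body_mass_kg,
            meta=meta or {},
        )


class MonoExponentialRegressor(_ExponentialRegressorBase):
    """Mono-exponential recovery fit: baseline + A·e^{-(t-td)/tau}.

    ``baseline=None`` estimates the baseline (free mode); a float fixes it at
    the measured resting V̇O₂ and removes it from the free parameters (k=3).
    """

    _model: ModelName = "mono"
    _param_names = MONO_PARAM_NAMES


class BiExponentialRegressor(_ExponentialRegressorBase):
    """Bi-exponential recovery fit with a shared time delay (k=5 when the
    baseline is fixed).

    Besides the standard 75/25 amplitude-split start, a nested start seeded
    from an internal mono-exponential fit is always tried: the mono solution
    lies on the A2=0 (or A1=0) boundary of the bi model, so starting there
    guarantees the bi fit never ends worse than the mono fit.
    """

    _model: ModelName = "bi"
    _param_names = BI_PARAM_NAMES

    def _extra_starts(self, t, y, fb: FitBounds, guess: dict[str, float]) -> list[dict[str, float]]:
        mono = MonoExponentialRegressor(
            baseline=self.baseline, bounds=None, unit_mode=self.unit_mode
        )
        try:
            mono.fit(t.reshape(-1, 1), y)
        except (DegenerateSeriesError, InsufficientDataError):
            return []
        mp = mono.params_
        t1_lo, t1_hi = fb["tau1"]
        t2_lo, t2_hi = fb["tau2"]
        start = {
            "baseline": mp.baseline,
            "td": mp.td,
            "A1": mp.A if mp.tau <= t1_hi else 0.0,
            "tau1": float(np.clip(mp.tau, t1_lo, t1_hi)),
            "A2": 0.0 if mp.tau <= t1_hi else mp.A,
            "tau2": float(np.clip(mp.tau, t2_lo, t2_hi)),
        }
        return [start]


def fit_model(
    series: BreathSeries,
    model: ModelName,
    baseline: float | None | str = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    cfg: PreprocessConfig | None = None,
    *,
    multistart: bool = False,
    exclude_pre_td: bool = False,
) -> FitResult:
    """Preprocess (per ``cfg``) and fit one model to one recovery series.

    ``baseline`` may be a measured value in the series' units (fixed mode,
    the primary workflow), or None/"free" to estimate it.
    """
    if isinstance(baseline, str):
        if baseline != "free":
            raise ConfigError(f"baseline must be numeric or 'free', got {baseline!r}")
        baseline = None
    prepped = apply_preprocessing(series, cfg)
    cls = MonoExponentialRegressor if model == "mono" else BiExponentialRegressor
    est = cls(
        baseline=baseline,
        bounds=bounds,
        unit_mode=series.unit_mode,
        multistart=multistart,
        exclude_pre_td=exclude_pre_td,
    )
    est.fit(prepped.t.reshape(-1, 1), prepped.vo2)
    return est.result_(meta=dict(prepped.meta), body_mass_kg=series.body_mass_kg)


def baseline_sweep(
    series: BreathSeries,
    model: ModelName,
    baselines: Sequence[float],
    bounds: dict[str, tuple[float, float]] | None = None,
    cfg: PreprocessConfig | None = None,
    *,
    fast_window: float = 300.0,
    integral_windows: tuple[float, float] = (300.0, 900.0),
    energy_factor: float | None = None,
):
    """Refit with the baseline fixed at each candidate value.

    Returns a DataFrame with one row per baseline: fitted parameters, R²,
    fast-phase R², AIC/AICc, fast-phase O₂ volume and alactic energy, and
    model-curve integrals over the short/long windows.  Rows where the fit
    fails are flagged rather than raised.
    """
    import pandas as pd

    from .energetics import alactic_energy, model_volume
    from .goodness import compute_stats

    if not len(baselines):
        raise ConfigError("baseline sweep needs at least one baseline value")
    rows = []
    for b in baselines:
        if b <= 0:
            raise ConfigError(f"baseline must be positive, got {b}")
        row: dict[str, Any] = {"baseline": float(b)}
        try:
            fr = fit_model(series, model, float(b), bounds=bounds, cfg=cfg)
            stats = compute_stats(apply_preprocessing(series, cfg), fr,
                                  fast_window=fast_window)
            energy = alactic_energy(
                fr, **({"factor_kj_per_l": energy_factor} if energy_factor else {})
            )
            row.update(fr.params.to_dict())
            row.update(
                r2=stats.r2, r2_fast=stats.r2_fast, aic=stats.aic, aicc=stats.aicc,
                rss=fr.rss, o2_fast_l=energy.o2_fast, alactic_kj=energy.energy_kj,
                converged=fr.converged,
            )
            for w in integral_windows:
                row[f"model_integral_{int(w)}s_l"] = model_volume(fr, 0.0, w)
            row["ok"] = True
        except Exception as exc:  # pragma: no cover - per-cell failure path
            row.update(ok=False, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
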