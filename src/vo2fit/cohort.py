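"""Cohort-level aggregation and comparative statistics.

One row per participant × model (parameters, fit statistics, energy, and
integral volumes), compared with paired t-tests, pooled-SD Cohen's d, and
one-way repeated-measures ANOVA with partial η² for the integral conditions
(observed data vs the two model curves).

Cohen's d uses the pooled SD of the two conditions,
|m_a − m_b| / sqrt((sd_a² + sd_b²)/2), not the SD of the paired differences.
The RM-ANOVA reports the plain F (no sphericity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .energetics import alactic_energy, integral_report
from .errors import UndefinedStatisticError
from .fitting import fit_model
from .goodness import compute_stats
from .io import BreathSeries
from .preprocess import PreprocessConfig, apply_preprocessing


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    cohens_d: float
    n: int

    def to_dict(self) -> dict[str, float]:
        return {
            "mean_a": self.mean_a, "sd_a": self.sd_a,
            "mean_b": self.mean_b, "sd_b": self.sd_b,
            "t": self.t_statistic, "p": self.p_value,
            "cohens_d": self.cohens_d, "n": self.n,
        }


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired-sample t-test: t = mean(a−b) / (sd(a−b)/√n), two-sided p with
    n−1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise UndefinedStatisticError("paired t needs equal-length vectors, n >= 2")
    if np.std(a - b, ddof=1) == 0:
        raise UndefinedStatisticError("paired t undefined: zero-variance differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def cohens_d_pooled(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Effect size from summary statistics with the pooled-SD convention."""
    if sd_a < 0 or sd_b < 0:
        raise UndefinedStatisticError("standard deviations must be nonnegative")
    pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0:
        raise UndefinedStatisticError("Cohen's d undefined: both SDs zero")
    return float(abs(mean_a - mean_b) / pooled)


def rm_anova(conditions: Sequence[Sequence[float]]) -> tuple[float, float, float]:
    """One-way repeated-measures ANOVA over >= 2 within-subject conditions.

    Returns (F, p, partial η²) from the standard two-way (condition × subject)
    decomposition: F = MS_condition / MS_(condition×subject), and
    partial η² = SS_condition / (SS_condition + SS_error).
    """
    X = np.asarray(conditions, dtype=float)  # shape (k conditions, n subjects)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise UndefinedStatisticError("need >= 2 conditions of >= 2 subjects each")
    k, n = X.shape
    grand = X.mean()
    ss_cond = n * float(np.sum((X.mean(axis=1) - grand) ** 2))
    ss_subj = k * float(np.sum((X.mean(axis=0) - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_err <= 0:
        if ss_cond == 0:
            return 0.0, 1.0, 0.0
        raise UndefinedStatisticError("degenerate variance decomposition")
    F = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_cond, df_err))
    eta_p2 = ss_cond / (ss_cond + ss_err)
    return float(F), p, float(eta_p2)


def run_cohort(
    entries: Sequence[tuple[BreathSeries, float]],
    models: Sequence[str] = ("mono", "bi"),
    cfg: PreprocessConfig | None = None,
    *,
    fast_window: float = 300.0,
    integral_windows: tuple[float, float] = (300.0, 900.0),
    energy_factor: float | None = None,
    participant_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit every participant with every model; one row per participant × model.

    ``entries`` pairs each recovery series with its measured baseline V̇O₂.
    Failures are collected as flagged rows (ok=False) rather than raised.
    """
    if participant_ids is None:
        participant_ids = [f"P{i + 1:02d}" for i in range(len(entries))]
    rows: list[dict[str, Any]] = []
    for pid, (series, baseline) in zip(participant_ids, entries):
        prepped = apply_preprocessing(series, cfg)
        for model in models:
            row: dict[str, Any] = {"participant": pid, "model": model,
                                   "baseline_input": baseline}
            try:
                fr = fit_model(series, model, baseline, cfg=cfg)
                st = compute_stats(prepped, fr, fast_window=fast_window)
                en = alactic_energy(
                    fr, **({"factor_kj_per_l": energy_factor} if energy_factor else {})
                )
                ir = integral_report(series, fr, windows=integral_windows)
                row.update(fr.params.to_dict())
                row.update(st.to_dict())
                row.update(en.to_dict())
                row.update(ir.to_dict())
                row.update(converged=fr.converged, ok=True)
            except Exception as exc:
                row.update(ok=False, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def _condition(table: pd.DataFrame, model: str, col: str) -> np.ndarray:
    sub = table[(table["model"] == model) & table["ok"]].sort_values("participant")
    return sub[col].to_numpy(dtype=float)


def summarize_cohort(table: pd.DataFrame) -> dict[str, Any]:
    """Mono-vs-bi comparisons (fit statistics, alactic energy) and the
    RM-ANOVA over observed/mono/bi integral volumes."""
    out: dict[str, Any] = {"comparisons": {}, "integrals": {}}
    for col in ("r2", "r2_fast", "aicc", "energy_kj"):
        a = _condition(table, "mono", col)
        b = _condition(table, "bi", col)
        t, p = paired_t(a, b)
        d = cohens_d_pooled(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))
        out["comparisons"][col] = ComparisonResult(
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
            t_statistic=t, p_value=p, cohens_d=d, n=len(a),
        ).to_dict()
    for win, real_col, model_col in (
        ("5min", "real_5min_l", "model_5min_l"),
        ("15min", "real_15min_l", "model_15min_l"),
    ):
        real = _condition(table, "bi", real_col)  # observed data, model-independent
        mono = _condition(table, "mono", model_col)
        bi = _condition(table, "bi", model_col)
        F, p, eta = rm_anova([real, mono, bi])
        out["integrals"][win] = {
            "real_mean": float(real.mean()), "real_sd": float(real.std(ddof=1)),
            "mono_mean": float(mono.mean()), "mono_sd": float(mono.std(ddof=1)),
            "bi_mean": float(bi.mean()), "bi_sd": float(bi.std(ddof=1)),
            "F": F, "p": p, "partial_eta_sq": eta,
            "posthoc": {
                "real_vs_mono": paired_t(real, mono),
                "real_vs_bi": paired_t(real, bi),
                "mono_vs_bi": paired_t(mono, bi),
            },
        }
    return out
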