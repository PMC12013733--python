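"""Synthetic breath-by-breath recovery series with known ground truth.

Emulates 15 minutes of post-sprint recovery as measured by a breath-by-breath
gas analyzer: irregular breath timestamps (lognormal inter-breath intervals,
mean 2.0 s, SD 0.5 s, i.e. ~0.5 Hz), a decaying mono- or bi-exponential mean
curve, and additive homoscedastic Gaussian breath-to-breath noise (default
SD 120 mL/min) floored at zero.  Cohort-style truths are drawn from uniform
windows (mean ± 2 SD) around typical values observed in trained adults after
a 30-s all-out sprint: baseline ≈ 384 mL/min, fast phase ≈ 2500 mL/min with
τ₁ ≈ 65 s, slow phase ≈ 840 mL/min with τ₂ ≈ 740 s, shared delay ≈ 3 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BreathSeries
from .models import BiParams, MonoParams, Params, eval_params

#: Cohort parameter windows: (center, SD). Draws are uniform on center ± 2 SD,
#: truncated to the default fitting bounds (and td >= 0).
COHORT_MONO = {
    "baseline": (384.4, 56.2),
    "A": (2760.6, 388.0),
    "td": (3.69, 1.16),
    "tau": (162.3, 36.6),
}
COHORT_BI = {
    "baseline": (384.4, 56.2),
    "A1": (2505.5, 466.9),
    "td": (2.70, 1.90),
    "tau1": (65.3, 12.8),
    "A2": (840.7, 270.3),
    "tau2": (742.9, 187.1),
}

#: Representative single-participant truth used by sweep/trend fixtures.
REPRESENTATIVE_TRUTH = BiParams(
    baseline=390.0, A1=2500.0, td=3.0, tau1=65.0, A2=840.0, tau2=743.0
)


@dataclass(frozen=True)
class SimSpec:
    """Generator settings: ground truth plus measurement-process parameters."""

    truth: Params = field(default_factory=lambda: REPRESENTATIVE_TRUTH)
    duration_s: float = 900.0
    interval_mean_s: float = 2.0
    interval_sd_s: float = 0.5
    noise_sd: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.interval_mean_s <= 0:
            raise ValueError("duration and mean interval must be positive")
        if self.noise_sd < 0 or self.interval_sd_s < 0:
            raise ValueError("noise_sd and interval_sd_s must be nonnegative")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_series(spec: SimSpec) -> tuple[BreathSeries, dict]:
    """One synthetic recovery series plus its ground-truth record.

    Breath times are cumulative lognormal intervals clipped to the duration;
    V̇O₂ is the truth curve plus Gaussian noise, floored at zero.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sigma = _lognormal_params(spec.interval_mean_s, spec.interval_sd_s)
    n_max = int(np.ceil(spec.duration_s / spec.interval_mean_s * 2)) + 20
    intervals = rng.lognormal(mu, sigma, size=n_max)
    t = np.cumsum(intervals)
    t = t[t <= spec.duration_s]
    clean = eval_params(spec.truth, t)
    noise = rng.normal(0.0, spec.noise_sd, size=len(t)) if spec.noise_sd > 0 else 0.0
    vo2 = np.maximum(clean + noise, 0.0)
    series = BreathSeries(
        t=t, vo2=vo2, unit_mode="absolute",
        meta={"synthetic": True, "seed": spec.seed, "noise_sd": spec.noise_sd,
              "truth_model": "mono" if isinstance(spec.truth, MonoParams) else "bi"},
    )
    truth = {"model": series.meta["truth_model"], "params": spec.truth.to_dict(),
             "noise_sd": spec.noise_sd, "seed": spec.seed,
             "duration_s": spec.duration_s}
    return series, truth


def sample_truth(model: str, seed: int) -> Params:
    """Draw one cohort-style truth parameter set.

    Each parameter is uniform on its center ± 2 SD window, truncated to the
    default fitting bounds; the fast/slow ordering tau1 < tau2 is guaranteed
    by the disjoint windows.
    """
    from .fitting import default_bounds

    rng = np.random.default_rng(seed)
    table = COHORT_MONO if model == "mono" else COHORT_BI
    fb = default_bounds(model, "absolute")
    draw: dict[str, float] = {}
    for name, (center, sd) in table.items():
        lo = max(center - 2 * sd, fb[name][0], 0.0)
        hi = min(center + 2 * sd, fb[name][1])
        draw[name] = float(rng.uniform(lo, hi))
    cls = MonoParams if model == "mono" else BiParams
    return cls.from_dict(draw)


def write_fixture(
    series: BreathSeries,
    path: str | Path,
    truth: dict | None = None,
    *,
    dialect: str = "csv",
    time_format: str = "seconds",
) -> Path:
    """Write a series in the dialects the loader reads, for round-trip tests.

    ``dialect``: "csv" (comma), "tsv", or "xlsx"; ``time_format``: "seconds"
    (numeric) or "clock" (MM:SS strings, whole-second resolution only).
    A truth sidecar JSON is written next to the file when supplied.
    """
    path = Path(path)
    if time_format == "clock":
        tcol = [f"{int(v) // 60:02d}:{int(v) % 60:02d}" for v in series.t]
    else:
        tcol = series.t
    df = pd.DataFrame({"time": tcol, "oxygen": series.vo2})
    if dialect == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif dialect == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if truth is not None:
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(truth, indent=2)
        )
    return path
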