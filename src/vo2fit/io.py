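"""Reading, validating, and normalizing breath-by-breath recovery files.

Accepts delimited text (comma/semicolon/tab, auto-sniffed) or spreadsheet
workbooks with one time column (numeric seconds or MM:SS / HH:MM:SS clock
strings) and one V̇O₂ column (mL/min absolute or mL/kg/min relative).  The
canonical in-memory form is :class:`BreathSeries`: strictly increasing times
in seconds since recovery onset plus finite, nonnegative V̇O₂ samples.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, InsufficientDataError, UnitError

#: Heuristic threshold separating mL/kg/min from mL/min magnitudes: relative
#: values in humans stay below ~100, absolute values rarely fall below 200.
RELATIVE_THRESHOLD = 150.0

MIN_ROWS = 10

_CLOCK_RE = re.compile(r"^\s*(?:(\d+):)?(\d{1,2}):(\d{1,2}(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class ColumnSpec:
    """Names of the time and V̇O₂ columns, plus optional dialect hints."""

    time_column: str
    vo2_column: str
    delimiter: str | None = None  # None => sniff
    decimal: str = "."

    def __post_init__(self) -> None:
        if not self.time_column or not self.vo2_column:
            raise ConfigError("time and vo2 column names must be nonempty")
        if self.time_column == self.vo2_column:
            raise ConfigError("time and vo2 columns must be distinct")


@dataclass
class BreathSeries:
    """Timestamped V̇O₂ recovery samples.

    t            : seconds since recovery onset, strictly increasing, t[0] >= 0
    vo2          : oxygen uptake per sample (mL/min or mL/kg/min)
    unit_mode    : "absolute" (mL/min) or "relative" (mL/kg/min)
    body_mass_kg : required before any absolute-unit computation in relative mode
    meta         : provenance (source file, columns, preprocessing flags, drops)
    """

    t: np.ndarray
    vo2: np.ndarray
    unit_mode: str = "absolute"
    body_mass_kg: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.vo2.shape:
            raise ValueError("t and vo2 must be 1-D arrays of equal length")
        if len(self.t) and self.t[0] < 0:
            raise ValueError("t[0] must be >= 0")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.vo2)):
            raise ValueError("vo2 must be finite")
        # nonnegativity is enforced at load/simulation time; filtered values
        # may dip below zero and are deliberately not clipped here
        if self.unit_mode not in ("absolute", "relative"):
            raise ValueError("unit_mode must be 'absolute' or 'relative'")
        if self.body_mass_kg is not None and self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def to_absolute(self) -> "BreathSeries":
        """Convert relative (mL/kg/min) samples to absolute mL/min."""
        if self.unit_mode == "absolute":
            return self
        if self.body_mass_kg is None:
            raise UnitError("relative series needs body_mass_kg for absolute units")
        return self.replace(vo2=self.vo2 * self.body_mass_kg, unit_mode="absolute")

    def replace(self, **kw: Any) -> "BreathSeries":
        d = dict(t=self.t, vo2=self.vo2, unit_mode=self.unit_mode,
                 body_mass_kg=self.body_mass_kg, meta=dict(self.meta))
        d.update(kw)
        return BreathSeries(**d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_seconds": self.t, "vo2": self.vo2})

    def to_csv(self, path: str | Path) -> None:
        """Export as canonical two-column CSV (t_seconds, vo2).

        Floats are written with 17 significant digits so a reload reproduces
        the arrays bit-exactly.
        """
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def parse_time_value(raw: Any) -> float:
    """Convert a time token to seconds.

    Numeric values pass through unchanged; "MM:SS" and "HH:MM:SS" clock
    strings (fractional seconds allowed) are converted arithmetically.
    """
    if isinstance(raw, (int, float, np.integer, np.floating)):
        v = float(raw)
        if not math.isfinite(v):
            raise FormatError(f"non-finite time value: {raw!r}")
        return v
    if isinstance(raw, str):
        s = raw.strip()
        try:
            return float(s)
        except ValueError:
            pass
        m = _CLOCK_RE.match(s)
        if m:
            h = float(m.group(1) or 0.0)
            return h * 3600.0 + float(m.group(2)) * 60.0 + float(m.group(3))
    raise FormatError(f"unparseable time token: {raw!r}")


def _read_table(path: Path, spec: ColumnSpec) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls", ".ods"):
        return pd.read_excel(path, sheet_name=0)
    sep = spec.delimiter
    if sep is None:
        import csv as _csv

        sample = path.read_text(errors="replace")[:4096]
        try:
            sep = _csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
        except _csv.Error:
            sep = ","
    # round_trip parsing so full-precision exports reload bit-exactly
    return pd.read_csv(path, sep=sep, decimal=spec.decimal,
                       float_precision="round_trip")


def load_series(
    path: str | Path,
    spec: ColumnSpec,
    *,
    unit_mode: str | None = None,
    body_mass_kg: float | None = None,
    rezero: bool = True,
) -> BreathSeries:
    """Load, validate, and normalize one breath-by-breath file.

    Times are converted to seconds, rows with unparseable or missing values
    are dropped (counted in ``meta``), duplicate timestamps keep the first
    occurrence, and — when ``rezero`` is set — the whole series is shifted so
    the first retained sample is t = 0.  ``unit_mode=None`` engages the
    magnitude heuristic of :func:`detect_unit_mode`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    df = _read_table(path, spec)
    for col in (spec.time_column, spec.vo2_column):
        if col not in df.columns:
            raise ConfigError(
                f"column {col!r} not found in {path.name}; has {list(df.columns)}"
            )

    n_input = len(df)
    t_list: list[float] = []
    v_list: list[float] = []
    n_bad = 0
    for i, (traw, vraw) in enumerate(
        zip(df[spec.time_column].to_numpy(), df[spec.vo2_column].to_numpy())
    ):
        try:
            tv = parse_time_value(traw)
            vv = float(vraw)
        except (FormatError, TypeError, ValueError):
            n_bad += 1
            continue
        if not (math.isfinite(tv) and math.isfinite(vv)) or vv < 0:
            n_bad += 1
            continue
        t_list.append(tv)
        v_list.append(vv)

    t = np.asarray(t_list)
    v = np.asarray(v_list)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > 0  # duplicate timestamps: keep first occurrence
    n_dup = int((~keep).sum())
    t, v = t[keep], v[keep]

    if len(t) < MIN_ROWS:
        raise InsufficientDataError(
            f"{path.name}: only {len(t)} valid rows (need >= {MIN_ROWS})"
        )
    if rezero:
        t = t - t[0]

    series = BreathSeries(
        t=t,
        vo2=v,
        unit_mode=unit_mode or "absolute",
        body_mass_kg=body_mass_kg,
        meta={
            "source": str(path),
            "time_column": spec.time_column,
            "vo2_column": spec.vo2_column,
            "n_input_rows": n_input,
            "n_dropped_unparseable": n_bad,
            "n_dropped_duplicate_time": n_dup,
            "rezeroed": rezero,
        },
    )
    if unit_mode is None:
        series.unit_mode = detect_unit_mode(series)
        series.meta["unit_mode_detected"] = True
    return series


def detect_unit_mode(series: BreathSeries) -> str:
    """Heuristic unit detection: max V̇O₂ below 150 reads as mL/kg/min.

    The boundary value itself is assigned to absolute.  A user-supplied
    ``unit_mode`` always overrides this.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot detect units of an empty series")
    return "relative" if float(np.max(series.vo2)) < RELATIVE_THRESHOLD else "absolute"
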