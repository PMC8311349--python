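"""Reading, calibrating and time-aligning temperature-logger records.

Body-temperature (T_B) loggers record hourly; ambient (T_A) loggers record
every 15 min.  Both are ingested from plain CSV exports with the dialect
``timestamp,temperature_c`` (ISO-8601 local clock time, timezone-naive) and
joined into the hourly analysis frame that every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TemperatureSeries",
    "CalibrationFit",
    "read_temperature_series",
    "write_series",
    "fit_calibration",
    "apply_calibration",
    "align_hourly",
    "read_metadata",
]

ALIGNED_COLUMNS = [
    "individual_id", "timestamp", "t_b", "t_a", "t_diff", "food",
    "daylength_h", "m_b", "delta_m_b", "week", "date",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """A timestamped temperature record from one logger.

    ``data`` is a float Series (°C) indexed by a strictly increasing,
    timezone-naive DatetimeIndex.  ``cadence_min`` is the nominal sampling
    interval; gaps relative to it are preserved, never imputed.
    """

    logger_id: str
    kind: Literal["body", "ambient"]
    data: pd.Series
    cadence_min: float

    def __post_init__(self) -> None:
        if self.kind not in ("body", "ambient"):
            raise ValueError(f"kind must be 'body' or 'ambient', got {self.kind!r}")
        if self.cadence_min <= 0:
            raise ValueError("cadence_min must be positive")
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("TemperatureSeries.data must be indexed by timestamps")
        if len(self.data) and not idx.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if idx.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        if len(self.data) and not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.data.index[-1]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS map from logger readings to reference (water-bath) temperature."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def read_temperature_series(
    path: str | Path,
    kind: Literal["body", "ambient"],
    cadence_min: float,
    max_bad_fraction: float = 0.01,
) -> TemperatureSeries:
    """Read a logger CSV export (``timestamp,temperature_c``).

    Rows that fail to parse are tolerated up to ``max_bad_fraction`` of the
    file; beyond that the first offending line is named in the error.
    Duplicate timestamps are collapsed by their mean.  Gaps are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise ValueError(f"{path}: no data rows")
    cols = [c.strip().lower() for c in raw.columns]
    try:
        ts_col = raw.columns[cols.index("timestamp")]
        temp_col = raw.columns[cols.index("temperature_c")]
    except ValueError:
        if len(raw.columns) < 2:
            raise ValueError(f"{path}: need timestamp and temperature columns") from None
        ts_col, temp_col = raw.columns[0], raw.columns[1]

    ts = pd.to_datetime(raw[ts_col], errors="coerce", format="ISO8601")
    temp = pd.to_numeric(raw[temp_col], errors="coerce")
    bad = ts.isna() | temp.isna() | ~np.isfinite(temp.fillna(np.nan))
    n_bad = int(bad.sum())
    if n_bad:
        frac = n_bad / len(raw)
        if frac > max_bad_fraction:
            first = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: {n_bad}/{len(raw)} unparseable rows "
                f"(> {max_bad_fraction:.1%}); first bad line is {first + 2}: "
                f"{raw.iloc[first].to_dict()}"
            )
    frame = pd.DataFrame({"timestamp": ts, "temperature_c": temp}).loc[~bad]
    if frame.empty:
        raise ValueError(f"{path}: no parseable rows")
    collapsed = frame.groupby("timestamp")["temperature_c"].mean().sort_index()
    return TemperatureSeries(
        logger_id=path.stem, kind=kind, data=collapsed, cadence_min=cadence_min
    )


def write_series(series: TemperatureSeries, path: str | Path) -> Path:
    """Write a series back out in the input CSV dialect (round-trips reads)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": series.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature_c": series.data.to_numpy(dtype=float),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def fit_calibration(
    logger_values: np.ndarray, reference_values: np.ndarray
) -> CalibrationFit:
    """OLS of reference (water) temperature on logger temperature."""
    x = np.asarray(logger_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("logger and reference values must be equal-length 1-d arrays")
    if len(x) < 2:
        raise ValueError("calibration needs at least 2 paired points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("calibration points must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate calibration: logger values have zero variance")
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def apply_calibration(series: TemperatureSeries, fit: CalibrationFit) -> TemperatureSeries:
    """Map every reading through ``slope * x + intercept``; metadata preserved."""
    return replace(series, data=series.data * fit.slope + fit.intercept)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the individual metadata table ``id,sex,food,week,mass_g``."""
    meta = pd.read_csv(path, dtype={"id": str, "sex": str, "food": str})
    required = {"id", "food", "week", "mass_g"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    bad_food = set(meta["food"].unique()) - {"restricted", "ad_libitum"}
    if bad_food:
        raise ValueError(f"unknown food levels: {sorted(bad_food)}")
    if (meta["mass_g"] <= 0).any():
        raise ValueError("mass_g must be positive")
    return meta


def _hourly_ambient_means(ambient: TemperatureSeries) -> pd.Series:
    # mean over [t, t+1h), left-labelled
    return ambient.data.groupby(ambient.data.index.floor("h")).mean()


def align_hourly(
    body: TemperatureSeries,
    ambient: TemperatureSeries,
    meta: pd.DataFrame,
    individual_id: str,
    latitude: float = -39.65,
) -> pd.DataFrame:
    """Join body and ambient loggers into the hourly analysis frame.

    T_A is aggregated to hourly means on the half-open hour [t, t+1h) and
    matched to the hourly T_B timestamps; records outside the overlap of the
    two loggers are dropped.  Daylength is attached from the solar
    declination formula at ``latitude``, and the weekly body mass from
    ``meta`` is carried forward within each week.
    """
    from .synth import daylength  # local import: synth depends on this module

    if body.kind != "body" or ambient.kind != "ambient":
        raise ValueError("pass body and ambient series in that order")
    # each sample covers one cadence interval, so a logger's coverage runs
    # from its first timestamp to its last timestamp + cadence
    start = max(body.start, ambient.start)
    end = min(
        body.end + pd.Timedelta(minutes=body.cadence_min),
        ambient.end + pd.Timedelta(minutes=ambient.cadence_min),
    )
    if end - start < pd.Timedelta(hours=1):
        raise ValueError("body and ambient series overlap by less than 1 h")

    sub = meta.loc[meta["id"].astype(str) == str(individual_id)]
    if sub.empty:
        raise ValueError(f"no metadata rows for individual {individual_id!r}")
    food_levels = sub["food"].unique()
    food = str(food_levels[0])

    tb = body.data.loc[start : end - pd.Timedelta(seconds=1)]
    ta_hourly = _hourly_ambient_means(ambient)
    hours = tb.index.floor("h")
    ta = ta_hourly.reindex(hours).to_numpy(dtype=float)

    doy = tb.index.dayofyear.to_numpy()
    dl = daylength(latitude, doy)

    first_date = tb.index[0].normalize()
    week = ((tb.index.normalize() - first_date).days // 7).astype(int)

    mass_by_week = sub.set_index("week")["mass_g"].sort_index()
    all_weeks = pd.RangeIndex(0, int(week.max()) + 1)
    mass_ff = mass_by_week.reindex(all_weeks).ffill().bfill()
    if mass_ff.isna().any():
        raise ValueError(f"no usable weekly masses for individual {individual_id!r}")
    m_b = mass_ff.to_numpy(dtype=float)[week]
    delta = mass_ff.diff().fillna(0.0).to_numpy(dtype=float)[week]

    out = pd.DataFrame(
        {
            "individual_id": str(individual_id),
            "timestamp": tb.index,
            "t_b": tb.to_numpy(dtype=float),
            "t_a": ta,
            "t_diff": tb.to_numpy(dtype=float) - ta,
            "food": food,
            "daylength_h": dl,
            "m_b": m_b,
            "delta_m_b": delta,
            "week": week,
            "date": tb.index.normalize(),
        }
    )
    return out.reset_index(drop=True)
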