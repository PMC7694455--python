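"""Thermal-time (growing degree day) accumulation from daily weather.

Thermal time is the physiological clock of the package: every downstream
model (emergence, growth, phenology) is expressed as a function of
cumulative degree days above a base temperature, accumulated from the
sowing date. Daily units are computed from min/max temperature as

    max(0, (tmax + tmin) / 2 - base)

with the default base temperature of 1 degree C appropriate for winter-annual
grasses and winter wheat. Days whose mean temperature is at or below the
base contribute nothing.

Two temperature sources are distinguished: soil temperature drives seedling
emergence, air temperature drives above-ground development (BBCH stages,
biomass). A :class:`ThermalTimeSeries` carries its source tag so downstream
fitters can check they are being fed the intended series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (ContiguityError, InvalidRecordError, SourceMixError)

AIR = "air"
SOIL = "soil"
SOURCES = (AIR, SOIL)

#: Default base temperature in degrees Celsius.
DEFAULT_BASE_C = 1.0

WEATHER_COLUMNS = ("date", "tmin_c", "tmax_c", "source")


def daily_thermal_units(tmin, tmax, base: float = DEFAULT_BASE_C):
    """Thermal units (degree days) contributed by one day.

    Parameters
    ----------
    tmin, tmax : float or array-like
        Daily minimum and maximum temperature in degrees C.
    base : float
        Base temperature in degrees C; default 1.

    Returns
    -------
    float or ndarray
        ``max(0, (tmax + tmin)/2 - base)``; zero whenever the daily mean is
        at or below the base temperature.
    """
    tmin_a = np.asarray(tmin, dtype=float)
    tmax_a = np.asarray(tmax, dtype=float)
    if np.any(tmin_a > tmax_a):
        raise InvalidRecordError("tmin exceeds tmax in at least one record")
    units = np.maximum(0.0, (tmax_a + tmin_a) / 2.0 - base)
    if np.isscalar(tmin) and np.isscalar(tmax):
        return float(units)
    return units


@dataclass
class ThermalTimeSeries:
    """Cumulative thermal time from a reference (sowing) date.

    Attributes
    ----------
    origin : pandas.Timestamp
        The sowing date; its own thermal units are included in the sum, so
        the cumulative value the day *before* the origin is zero.
    values : pandas.Series
        Cumulative degree days indexed by date, nondecreasing.
    source : str
        ``"air"`` or ``"soil"``.
    base : float
        Base temperature used for the accumulation.
    """

    origin: pd.Timestamp
    values: pd.Series = field(repr=False)
    source: str
    base: float = DEFAULT_BASE_C

    def __post_init__(self):
        if self.source not in SOURCES:
            raise InvalidRecordError(f"unknown temperature source {self.source!r}")
        diffs = np.diff(self.values.to_numpy())
        if np.any(diffs < -1e-9):
            raise InvalidRecordError("cumulative thermal time must be nondecreasing")

    def at(self, date) -> float:
        """Cumulative thermal time on ``date`` (must be covered)."""
        ts = pd.Timestamp(date)
        if ts < self.origin:
            return 0.0
        try:
            return float(self.values.loc[ts])
        except KeyError:
            raise KeyError(f"date {ts.date()} not covered by the series") from None

    def to_frame(self) -> pd.DataFrame:
        """Series as a two-column frame (``date``, ``cum_tt_c``)."""
        return pd.DataFrame({
            "date": self.values.index,
            "cum_tt_c": self.values.to_numpy(),
        })

    def __len__(self) -> int:
        return len(self.values)


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Validate a weather frame; returns a normalized (typed, sorted) copy.

    Checks column presence, tmin <= tmax, known source labels and per-source
    date uniqueness. Contiguity is checked at accumulation time because it
    depends on the window requested.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise InvalidRecordError(f"weather frame missing columns: {missing}")
    df = weather.loc[:, list(WEATHER_COLUMNS)].copy()
    df["date"] = pd.to_datetime(df["date"])
    df["tmin_c"] = df["tmin_c"].astype(float)
    df["tmax_c"] = df["tmax_c"].astype(float)
    bad_source = set(df["source"].unique()) - set(SOURCES)
    if bad_source:
        raise InvalidRecordError(f"unknown temperature source(s): {sorted(bad_source)}")
    if (df["tmin_c"] > df["tmax_c"]).any():
        rows = df.index[df["tmin_c"] > df["tmax_c"]].tolist()
        raise InvalidRecordError(f"tmin > tmax at rows {rows[:5]}")
    dup = df.duplicated(subset=["date", "source"])
    if dup.any():
        raise InvalidRecordError("duplicate dates within a temperature source")
    return df.sort_values(["source", "date"]).reset_index(drop=True)


def load_weather(path) -> pd.DataFrame:
    """Read and validate a weather CSV (columns date, tmin_c, tmax_c, source)."""
    return validate_weather(pd.read_csv(path))


def accumulate(weather: pd.DataFrame, origin, base: float = DEFAULT_BASE_C,
               source: str | None = None,
               allow_gap_fill: bool = False) -> ThermalTimeSeries:
    """Accumulate daily thermal units into a cumulative series from ``origin``.

    Parameters
    ----------
    weather : pandas.DataFrame
        Validated weather records (see :func:`validate_weather`); may hold
        both sources, in which case ``source`` selects one.
    origin : date-like
        Sowing date. The origin day's units are included in the sum.
    base : float
        Base temperature, degrees C.
    source : str, optional
        Select ``"air"`` or ``"soil"`` records. Required when the frame
        mixes sources.
    allow_gap_fill : bool
        If True, isolated single-day gaps are filled by linear interpolation
        of tmin/tmax; otherwise any gap raises :class:`ContiguityError`.

    Returns
    -------
    ThermalTimeSeries
    """
    df = validate_weather(weather)
    if source is not None:
        df = df[df["source"] == source]
        if df.empty:
            raise InvalidRecordError(f"no weather records with source {source!r}")
    elif df["source"].nunique() > 1:
        raise SourceMixError(
            "weather frame mixes air and soil records; pass source='air' or 'soil'")
    src = df["source"].iloc[0]

    origin_ts = pd.Timestamp(origin)
    df = df[df["date"] >= origin_ts].sort_values("date")
    if df.empty or df["date"].iloc[0] != origin_ts:
        raise ContiguityError(f"weather does not cover the origin date {origin_ts.date()}")

    full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
    if len(full) != len(df):
        missing = full.difference(pd.DatetimeIndex(df["date"]))
        # gap-fill is deliberately restricted to isolated single days
        runs = _gap_runs(missing)
        if not allow_gap_fill or max(runs, default=0) > 1:
            raise ContiguityError(
                f"{len(missing)} missing day(s) in weather series, e.g. "
                f"{missing[0].date()}")
        df = (df.set_index("date")
                .reindex(full)
                .assign(source=src))
        df[["tmin_c", "tmax_c"]] = df[["tmin_c", "tmax_c"]].interpolate("linear")
        df = df.rename_axis("date").reset_index()

    units = daily_thermal_units(df["tmin_c"].to_numpy(), df["tmax_c"].to_numpy(),
                                base=base)
    values = pd.Series(np.cumsum(units), index=pd.DatetimeIndex(df["date"]))
    return ThermalTimeSeries(origin=origin_ts, values=values, source=src, base=base)


def _gap_runs(missing: pd.DatetimeIndex) -> list[int]:
    """Lengths of consecutive-day runs within the missing-date index."""
    if len(missing) == 0:
        return []
    runs, current = [], 1
    for prev, cur in zip(missing[:-1], missing[1:]):
        if (cur - prev).days == 1:
            current += 1
        else:
            runs.append(current)
            current = 1
    runs.append(current)
    return runs
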