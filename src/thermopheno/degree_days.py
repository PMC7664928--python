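"""Growing degree days from daily min/max temperatures.

Two daily methods are provided:

* ``tavg`` — the simple-average method: the day's contribution is
  ``max(0, (tmin + tmax)/2 - base_temp)``.
* ``allen`` — the single-sine method: the day's temperature course is
  modelled as one sine wave with mean ``m = (tmin + tmax)/2`` and amplitude
  ``a = (tmax - tmin)/2``; the daily degree-days are the day-average of the
  degree-hours above the base temperature, with no upper cutoff.  Because
  the average is taken over a full sine period the phase of the wave (where
  in the day the maximum falls) does not affect the result.

Accumulation always starts on January 1 of each calendar year, and daily
contributions are never negative, so cumulative GDD is non-decreasing
within a year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATION = "station"
ERA5 = "era5"
SOURCES = (STATION, ERA5)

METHOD_TAVG = "tavg"
METHOD_ALLEN = "allen"
METHODS = (METHOD_TAVG, METHOD_ALLEN)

#: Columns of a daily weather table (one row per location/date/source).
WEATHER_COLUMNS = ("location_id", "date", "tmin", "tmax", "source")

#: Columns of a cumulative-GDD table.
GDD_COLUMNS = ("location_id", "date", "doy", "daily_dd", "cum_gdd", "source")


class InvalidRecordError(ValueError):
    """A weather record violates a physical invariant (e.g. tmax < tmin)."""


class MissingCoverageError(KeyError):
    """A requested (location, date) is not covered by the available series."""


@dataclass(frozen=True)
class GDDParams:
    """Parameters of a degree-day accumulation.

    Heat accumulation always starts on January 1 of each year; that start
    date is a fixed convention of the method, not a parameter.

    Parameters
    ----------
    base_temp:
        Base temperature in °C below which heat accumulation is considered
        irrelevant to phenological timing.  Must lie in [0, 45].
    method:
        ``"tavg"`` or ``"allen"``.
    """

    base_temp: float = 10.0
    method: str = METHOD_TAVG

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_temp <= 45.0):
            raise ValueError(
                f"base_temp must be in [0, 45] °C, got {self.base_temp}"
            )
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


def _check_tmax_ge_tmin(tmin: np.ndarray, tmax: np.ndarray,
                        context: pd.DataFrame | None = None) -> None:
    bad = tmax < tmin
    if np.any(bad):
        if context is not None:
            rows = context.loc[np.asarray(bad)]
            where = "; ".join(
                f"{r.location_id} {pd.Timestamp(r.date).date()}"
                for r in rows.head(5).itertuples()
            )
            raise InvalidRecordError(f"tmax < tmin at: {where}")
        raise InvalidRecordError("tmax < tmin")


def daily_dd_tavg(tmin, tmax, base_temp: float):
    """Simple-average daily degree-days: ``max(0, (tmin+tmax)/2 - base)``.

    Negative values are clamped to zero: below the base temperature
    vegetation is taken to be biologically inactive, and negative
    accumulation would break the monotonicity of cumulative GDD.

    Accepts scalars or arrays; returns the same shape.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    _check_tmax_ge_tmin(tmin, tmax)
    out = np.maximum(0.0, (tmin + tmax) / 2.0 - base_temp)
    return float(out) if out.ndim == 0 else out


def daily_dd_allen(tmin, tmax, base_temp: float):
    """Single-sine daily degree-days (no upper cutoff).

    With ``m = (tmin+tmax)/2`` and ``a = (tmax-tmin)/2``:

    * ``base <= tmin``: the whole day is above base → ``m - base``
      (identical to the simple-average method);
    * ``base >= tmax``: the whole day is below base → ``0``;
    * otherwise, with ``theta = arcsin((base - m)/a)``::

          dd = ((m - base) * (pi/2 - theta) + a * cos(theta)) / pi

    which is the closed form of the day-average of
    ``max(0, m + a*sin(t) - base)`` over one full period.

    A constant-temperature day (``a == 0``) degenerates to
    ``max(0, m - base)``.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    _check_tmax_ge_tmin(tmin, tmax)

    m = (tmin + tmax) / 2.0
    a = (tmax - tmin) / 2.0

    out = np.zeros(np.broadcast_shapes(m.shape, np.shape(base_temp)), dtype=float)
    m, a = np.broadcast_to(m, out.shape), np.broadcast_to(a, out.shape)
    base = np.broadcast_to(np.asarray(base_temp, dtype=float), out.shape)

    whole_day = base <= tmin  # includes a == 0 with m >= base
    out[whole_day] = (m - base)[whole_day]

    partial = ~whole_day & (base < tmax) & (a > 0)
    if np.any(partial):
        mp, ap, bp = m[partial], a[partial], base[partial]
        theta = np.arcsin(np.clip((bp - mp) / ap, -1.0, 1.0))
        out[partial] = ((mp - bp) * (np.pi / 2.0 - theta)
                        + ap * np.cos(theta)) / np.pi
    # base >= tmax stays 0
    return float(out) if out.ndim == 0 else out


_DAILY_FN = {METHOD_TAVG: daily_dd_tavg, METHOD_ALLEN: daily_dd_allen}


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily weather table and return it sorted.

    Checks the schema, ``tmax >= tmin`` per record, uniqueness of
    (location_id, date, source), and gap-free coverage from January 1
    through the last date present in every (location, source, year) group.
    """
    missing = set(WEATHER_COLUMNS) - set(weather.columns)
    if missing:
        raise InvalidRecordError(f"weather table missing columns: {sorted(missing)}")
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    bad_source = ~weather["source"].isin(SOURCES)
    if bad_source.any():
        raise InvalidRecordError(
            f"unknown source values: {sorted(weather.loc[bad_source, 'source'].unique())}"
        )
    _check_tmax_ge_tmin(
        weather["tmin"].to_numpy(float), weather["tmax"].to_numpy(float), weather
    )
    keys = ["location_id", "date", "source"]
    if weather.duplicated(keys).any():
        dup = weather[weather.duplicated(keys, keep=False)].head(4)
        raise InvalidRecordError(
            f"duplicate (location_id, date, source) records:\n{dup[keys]}"
        )
    weather = weather.sort_values(["location_id", "source", "date"],
                                  kind="mergesort").reset_index(drop=True)
    year = weather["date"].dt.year
    for (loc, src, yr), grp in weather.groupby(
            ["location_id", "source", year], sort=False, observed=True):
        dates = grp["date"]
        expected = pd.date_range(f"{yr}-01-01", dates.iloc[-1], freq="D")
        if len(dates) != len(expected) or not dates.reset_index(drop=True).equals(
                pd.Series(expected)):
            gaps = expected.difference(pd.DatetimeIndex(dates))
            raise MissingCoverageError(
                f"dates for {loc}/{src}/{yr} are not gap-free from Jan 1: "
                f"missing {[str(d.date()) for d in gaps[:5]]}"
                + ("..." if len(gaps) > 5 else "")
            )
    return weather


def accumulate_gdd(weather: pd.DataFrame, params: GDDParams,
                   validate: bool = True) -> pd.DataFrame:
    """Cumulative GDD per (location, source, year), accumulating from Jan 1.

    Returns a table with columns ``location_id, date, doy, daily_dd,
    cum_gdd, source``; the parameters used are stored in ``.attrs`` under
    ``"base_temp"`` and ``"method"``.  Day-of-year follows the standard
    calendar convention (Jan 1 → 1; Dec 31 → 366 in leap years).
    """
    if validate:
        weather = validate_weather(weather)
    daily_fn = _DAILY_FN[params.method]
    out = weather[["location_id", "date", "source"]].copy()
    out["doy"] = out["date"].dt.dayofyear
    out["daily_dd"] = daily_fn(
        weather["tmin"].to_numpy(float),
        weather["tmax"].to_numpy(float),
        params.base_temp,
    )
    out["cum_gdd"] = out.groupby(
        ["location_id", "source", out["date"].dt.year], observed=True
    )["daily_dd"].cumsum()
    out = out[list(GDD_COLUMNS)]
    out.attrs["base_temp"] = params.base_temp
    out.attrs["method"] = params.method
    return out


def gdd_at(gdd: pd.DataFrame, location_id, date) -> float:
    """Exact lookup of cumulative GDD for one (location, date).

    Raises :class:`MissingCoverageError` when the pair is not covered.
    """
    date = pd.Timestamp(date)
    hit = gdd[(gdd["location_id"] == location_id) & (gdd["date"] == date)]
    if hit.empty:
        raise MissingCoverageError(
            f"no GDD coverage for location {location_id!r} on {date.date()}"
        )
    return float(hit["cum_gdd"].iloc[0])
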