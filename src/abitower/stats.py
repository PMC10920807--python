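"""Validation and summary statistics for tower-aligned satellite series.

Implements the comparison machinery used to judge the satellite record
against in-situ tower measurements: a longwave-radiation estimate of land
surface temperature, the NIRvP-weighted diurnal centroid, fixed-clock and
solar-noon-centred midday aggregates, monthly composites, centred moving
averages, and squared Pearson correlation on pairwise-complete records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeodeticLocation
from .solar import solar_noon_utc

__all__ = [
    "TowerRadiation",
    "DiurnalProfile",
    "STEFAN_BOLTZMANN",
    "DEFAULT_EMISSIVITY",
    "tower_lst",
    "diurnal_centroid",
    "midday_median",
    "midday_mean_solar",
    "monthly_mean_sd",
    "moving_average",
    "r_squared",
]

STEFAN_BOLTZMANN = 5.67e-8  # W m^-2 K^-4
DEFAULT_EMISSIVITY = 0.98  # vegetation broadband emissivity


@dataclass(frozen=True)
class TowerRadiation:
    """Longwave radiation pair measured at a tower."""

    lw_in_w_m2: float
    lw_out_w_m2: float
    emissivity: float = DEFAULT_EMISSIVITY
    stefan_boltzmann: float = STEFAN_BOLTZMANN


@dataclass(frozen=True)
class DiurnalProfile:
    """Half-hourly (hour-of-day, value) pairs covering one day."""

    hours: np.ndarray
    values: np.ndarray


def tower_lst(rad=None, lw_in=None, lw_out=None,
              emissivity: float = DEFAULT_EMISSIVITY,
              sigma: float = STEFAN_BOLTZMANN):
    """Land surface temperature (K) from tower longwave radiation.

    LST = [ LW_IN/sigma - LW_IN/(eps sigma) + LW_OUT/(eps sigma) ]^(1/4),
    i.e. the emitted longwave is the measured outgoing minus the reflected
    (1 - eps) share of the incoming.  A nonpositive radicand (physically
    impossible radiation pair) yields NaN.

    Accepts either a :class:`TowerRadiation` or ``lw_in``/``lw_out``
    scalars/arrays in W m^-2.
    """
    if rad is not None and isinstance(rad, TowerRadiation):
        lw_in, lw_out = rad.lw_in_w_m2, rad.lw_out_w_m2
        emissivity, sigma = rad.emissivity, rad.stefan_boltzmann
    elif rad is not None:
        raise TypeError("pass a TowerRadiation or lw_in=/lw_out= arrays")
    lw_in = np.asarray(lw_in, dtype=float)
    lw_out = np.asarray(lw_out, dtype=float)
    radicand = lw_in / sigma - lw_in / (emissivity * sigma) + lw_out / (emissivity * sigma)
    with np.errstate(invalid="ignore"):
        out = np.where(radicand > 0.0, np.power(np.abs(radicand), 0.25), np.nan)
    return float(out) if out.ndim == 0 else out


def diurnal_centroid(profile) -> float:
    """Value-weighted mean hour of day; 12 = local noon.

    centroid = sum(v_t * t) / sum(v_t) over the available half-hours.
    NaN if the profile carries no positive mass.
    """
    if isinstance(profile, DiurnalProfile):
        t, v = np.asarray(profile.hours, float), np.asarray(profile.values, float)
    elif isinstance(profile, pd.Series):
        idx = profile.index
        if isinstance(idx, pd.DatetimeIndex):
            t = idx.hour + idx.minute / 60.0 + idx.second / 3600.0
        else:
            t = np.asarray(idx, float)
        t, v = np.asarray(t, float), profile.to_numpy(float)
    else:
        t, v = (np.asarray(a, float) for a in profile)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    total = v.sum()
    if total <= 0.0:
        return float("nan")
    return float((v * t).sum() / total)


def _hours_of(index: pd.DatetimeIndex) -> np.ndarray:
    return index.hour + index.minute / 60.0 + index.second / 3600.0


def midday_median(day: pd.Series, window: tuple[float, float] = (10.0, 14.0)) -> float:
    """Median over the local-clock midday window (endpoints inclusive).

    ``day`` is indexed by local-standard timestamps of one day.
    """
    h = _hours_of(day.index)
    sel = day[(h >= window[0]) & (h <= window[1])].dropna()
    return float(sel.median()) if len(sel) else float("nan")


def midday_mean_solar(
    day: pd.Series,
    loc: GeodeticLocation,
    half_width_min: float = 75.0,
    date=None,
) -> float:
    """Mean over a midday window centred on that day's solar noon.

    ``day`` is indexed by UTC timestamps; the default half-width of 75 min
    gives the 2.5-hour window used when comparing with once-daily
    polar-orbiter overpasses.
    """
    if date is None:
        if not len(day):
            return float("nan")
        date = day.index[0].normalize()
    noon = solar_noon_utc(loc, date)
    lo = noon - pd.Timedelta(minutes=half_width_min)
    hi = noon + pd.Timedelta(minutes=half_width_min)
    sel = day[(day.index >= lo) & (day.index <= hi)].dropna()
    return float(sel.mean()) if len(sel) else float("nan")


def monthly_mean_sd(daily: pd.Series) -> pd.DataFrame:
    """Monthly mean and standard deviation of daily (midday) values.

    The SD is across the days within each calendar month (sample SD); it is
    NaN for months with fewer than two daily values.
    """
    daily = daily.dropna()
    grouped = daily.groupby([daily.index.year, daily.index.month])
    out = pd.DataFrame({"mean": grouped.mean(), "sd": grouped.std(ddof=1)})
    out.index.names = ["year", "month"]
    return out


def moving_average(series: pd.Series, window_days: int = 14) -> pd.Series:
    """Centred moving average over a day window, ignoring missing values.

    Output is NaN only where the whole window is empty.  For an even
    window the span is [t - w/2 days, t + (w/2 - 1) days].
    """
    if not series.index.is_monotonic_increasing:
        series = series.sort_index()
    return series.rolling(f"{window_days}D", center=True, min_periods=1).mean()


def r_squared(x, y) -> float:
    """Squared Pearson correlation over pairwise-complete cases.

    NaN when fewer than three complete pairs remain or either side has
    zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
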