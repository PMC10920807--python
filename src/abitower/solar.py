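"""Solar position, solar noon, and day/night classification.

Implements the NOAA solar calculator equations (a condensed form of Meeus'
algorithms): geometric mean solar longitude/anomaly, equation of center,
apparent longitude, obliquity with nutation correction, declination,
equation of time, then hour angle -> zenith and azimuth.  Angular accuracy
is well under 0.1 degree for years 1950-2050, comfortably inside the 0.2
degree contract used here.  No atmospheric refraction is applied.

Timestamps are UTC.  Local standard time in this package is always UTC plus
a fixed site offset -- never daylight-saving -- matching the convention of
half-hourly flux-tower files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeodeticLocation

__all__ = [
    "SolarAngles",
    "solar_angles",
    "solar_noon_utc",
    "is_daytime",
    "earth_sun_distance_au",
    "DAYTIME_SZA_THRESHOLD_DEG",
]

# The surface-reflectance retrieval only runs in daylight, defined by this
# solar-zenith cut (strict "<"; configurable in all call sites).
DAYTIME_SZA_THRESHOLD_DEG = 67.0

_J2000_JD = 2451545.0


@dataclass(frozen=True)
class SolarAngles:
    """Solar zenith/azimuth (degrees) and their sum at a UTC timestamp."""

    sza_deg: float | np.ndarray
    saa_deg: float | np.ndarray
    timestamp_utc: object

    @property
    def solar_pos_deg(self) -> float | np.ndarray:
        # "Solar position" scalar: the SZA + SAA sum used in the record.
        return self.sza_deg + self.saa_deg


def _julian_day(t) -> np.ndarray:
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(t, dtype="datetime64[ns]")))
    epoch = pd.Timestamp("2000-01-01T12:00:00")
    return _J2000_JD + (ts - epoch) / pd.Timedelta(days=1)


def _sun_ephemeris(jd: np.ndarray):
    """Declination (deg), equation of time (minutes), distance (AU)."""
    jc = (jd - _J2000_JD) / 36525.0
    gmls = np.remainder(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m = np.radians(gmas)
    eqctr = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    truelong = gmls + eqctr
    trueanom = gmas + eqctr
    dist_au = 1.000001018 * (1 - ecc**2) / (1 + ecc * np.cos(np.radians(trueanom)))
    omega = np.radians(125.04 - 1934.136 * jc)
    applong = truelong - 0.00569 - 0.00478 * np.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    decl = np.degrees(np.arcsin(np.sin(np.radians(obliq)) * np.sin(np.radians(applong))))
    vary = np.tan(np.radians(obliq / 2.0)) ** 2
    l2 = np.radians(2.0 * gmls)
    eqtime_min = 4.0 * np.degrees(
        vary * np.sin(l2)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * vary * np.sin(m) * np.cos(l2)
        - 0.5 * vary**2 * np.sin(2.0 * l2)
        - 1.25 * ecc**2 * np.sin(2.0 * m)
    )
    return decl, eqtime_min, dist_au


def earth_sun_distance_au(t) -> float | np.ndarray:
    """Instantaneous Earth-Sun distance in AU at UTC time(s) ``t``."""
    _, _, d = _sun_ephemeris(_julian_day(t))
    return float(d[0]) if np.ndim(t) == 0 and not isinstance(t, (list, tuple)) else d


def solar_angles(loc: GeodeticLocation, t_utc) -> SolarAngles:
    """Solar zenith and azimuth for a site at UTC timestamp(s).

    ``t_utc`` may be a scalar timestamp or any datetime sequence; arrays in
    give arrays out.
    """
    scalar = np.ndim(t_utc) == 0 and not isinstance(t_utc, (list, tuple))
    jd = _julian_day(t_utc)
    decl, eqtime, _ = _sun_ephemeris(jd)

    frac_day = np.remainder(jd - 0.5, 1.0)  # fraction of UTC day
    minutes = frac_day * 1440.0
    tst = np.remainder(minutes + eqtime + 4.0 * loc.longitude_deg, 1440.0)
    ha_deg = tst / 4.0 - 180.0

    phi = np.radians(loc.latitude_deg)
    delta = np.radians(decl)
    ha = np.radians(ha_deg)
    cos_zen = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(ha)
    zen = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))

    sin_zen = np.sin(np.radians(zen))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = (np.sin(phi) * cos_zen - np.sin(delta)) / (np.cos(phi) * sin_zen)
    cos_az = np.clip(cos_az, -1.0, 1.0)
    az = np.where(
        ha_deg > 0.0,
        np.remainder(np.degrees(np.arccos(cos_az)) + 180.0, 360.0),
        np.remainder(540.0 - np.degrees(np.arccos(cos_az)), 360.0),
    )
    # at the pole or exactly overhead the azimuth is undefined; use 0
    az = np.where(np.isfinite(az), az, 0.0)

    if scalar:
        return SolarAngles(float(zen[0]), float(az[0]), pd.Timestamp(np.asarray(t_utc, dtype="datetime64[ns]").item()))
    return SolarAngles(zen, az, pd.DatetimeIndex(np.asarray(t_utc, dtype="datetime64[ns]")))


def solar_noon_utc(loc: GeodeticLocation, date) -> pd.Timestamp:
    """UTC time of minimum solar zenith angle on ``date`` (<= 1 min)."""
    day = pd.Timestamp(date).normalize()
    # evaluate the equation of time at the first-guess noon, then refine once
    noon_guess = day + pd.Timedelta(minutes=720.0 - 4.0 * loc.longitude_deg)
    for _ in range(2):
        _, eqtime, _ = _sun_ephemeris(_julian_day(noon_guess))
        noon_guess = day + pd.Timedelta(
            minutes=720.0 - 4.0 * loc.longitude_deg - float(eqtime[0])
        )
    return noon_guess.round("s")


def is_daytime(sza_deg, threshold_deg: float = DAYTIME_SZA_THRESHOLD_DEG):
    """True where the sun is high enough for daytime retrievals (SZA < cut)."""
    result = np.asarray(sza_deg) < threshold_deg
    return bool(result) if np.ndim(sza_deg) == 0 else result
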