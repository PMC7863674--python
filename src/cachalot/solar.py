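"""Solar position from time and place.

Implements the NOAA/Meeus low-precision solar ephemeris: apparent
declination and the equation of time from the Julian century, then the
local hour angle and elevation. Accuracy is a few hundredths of a degree
over 1900-2100, far below the half-degree scale that matters for
day/night classification of dive records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _julian_day(ts: pd.DatetimeIndex) -> np.ndarray:
    # days since the J2000.0 epoch (2000-01-01 12:00 UTC)
    epoch = pd.Timestamp("2000-01-01 12:00:00", tz="UTC")
    return (ts - epoch) / pd.Timedelta(days=1)


def solar_position(times, lons, lats):
    """Solar elevation and declination (degrees) at each (time, lon, lat).

    Parameters
    ----------
    times : datetime-like, scalar or sequence; naive values are taken as UTC.
    lons, lats : decimal degrees, broadcastable against ``times``.

    Returns
    -------
    elevation, declination : ndarray of degrees (elevation is geometric,
    no refraction correction).
    """
    ts = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(times)))
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)

    d = _julian_day(ts)
    t = d / 36525.0  # Julian centuries

    # geometric mean longitude and anomaly of the sun (deg)
    l0 = np.mod(280.46646 + 36000.76983 * t + 0.0003032 * t**2, 360.0)
    m = np.radians(357.52911 + 35999.05029 * t - 0.0001537 * t**2)
    ecc = 0.016708634 - 0.000042037 * t - 0.0000001267 * t**2

    eq_centre = (
        np.sin(m) * (1.914602 - 0.004817 * t - 0.000014 * t**2)
        + np.sin(2 * m) * (0.019993 - 0.000101 * t)
        + np.sin(3 * m) * 0.000289
    )
    true_long = l0 + eq_centre
    omega = np.radians(125.04 - 1934.136 * t)
    app_long = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = np.radians(mean_obliq + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))

    y = np.tan(obliq / 2.0) ** 2
    l0r = np.radians(l0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0r)
        - 0.5 * y**2 * np.sin(4 * l0r)
        - 1.25 * ecc**2 * np.sin(2 * m)
    )  # minutes

    minutes_utc = (
        ts.hour.to_numpy() * 60.0
        + ts.minute.to_numpy()
        + ts.second.to_numpy() / 60.0
        + ts.microsecond.to_numpy() / 6e7
    )
    true_solar_min = np.mod(minutes_utc + eqtime + 4.0 * lons, 1440.0)
    hour_angle = np.radians(true_solar_min / 4.0 - 180.0)

    phi = np.radians(lats)
    sin_elev = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(hour_angle)
    elev = np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    return elev, np.degrees(decl)


def solar_elevation(times, lons, lats):
    """Geometric solar elevation in degrees (vectorized)."""
    return solar_position(times, lons, lats)[0]
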