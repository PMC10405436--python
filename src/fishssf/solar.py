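"""Solar event calendar and dawn/day/dusk/night classification.

Times of nautical dawn (sun 12 deg below the horizon), sunrise, sunset and
nautical dusk are computed from standard solar-position geometry (NOAA
equations: equation of time and solar declination from the Julian century,
hour angle from the altitude threshold).  Sunrise/sunset use the conventional
-0.833 deg altitude (solar radius plus refraction).

Classification convention (all half-open):
  dawn  = [nautical dawn, sunrise)
  day   = [sunrise, sunset)
  dusk  = [sunset, nautical dusk)
  night = everything else
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from math import acos, asin, cos, degrees, radians, sin, tan

import pandas as pd

from .errors import UnsupportedLatitudeError

SUNRISE_ALTITUDE = -0.833  # deg
NAUTICAL_ALTITUDE = -12.0  # deg


def _solar_params(jc: float):
    """Equation of time (minutes) and solar declination (deg) at Julian century jc."""
    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        sin(radians(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + sin(radians(2 * gma)) * (0.019993 - 0.000101 * jc)
        + sin(radians(3 * gma)) * 0.000289
    )
    true_long = gml + ctr
    app_long = true_long - 0.00569 - 0.00478 * sin(radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * cos(radians(125.04 - 1934.136 * jc))
    decl = degrees(asin(sin(radians(obliq)) * sin(radians(app_long))))
    var_y = tan(radians(obliq / 2.0)) ** 2
    eqtime = 4.0 * degrees(
        var_y * sin(2 * radians(gml))
        - 2 * ecc * sin(radians(gma))
        + 4 * ecc * var_y * sin(radians(gma)) * cos(2 * radians(gml))
        - 0.5 * var_y * var_y * sin(4 * radians(gml))
        - 1.25 * ecc * ecc * sin(2 * radians(gma))
    )
    return eqtime, decl


def _julian_century(date: dt.date, minutes_utc: float) -> float:
    ts = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    jd = ts.timestamp() / 86400.0 + 2440587.5 + minutes_utc / 1440.0
    return (jd - 2451545.0) / 36525.0


def _event_minutes(date: dt.date, lat: float, lon: float, altitude: float, rising: bool):
    """UTC minutes-of-day when the sun crosses `altitude`, iterated once."""
    minutes = 720.0 - 4.0 * lon  # first guess: local solar noon
    for _ in range(3):
        eqtime, decl = _solar_params(_julian_century(date, minutes))
        cos_ha = (
            sin(radians(altitude)) - sin(radians(lat)) * sin(radians(decl))
        ) / (cos(radians(lat)) * cos(radians(decl)))
        if cos_ha < -1.0 or cos_ha > 1.0:
            raise UnsupportedLatitudeError(
                f"sun does not cross {altitude} deg at latitude {lat} on {date}"
            )
        ha = degrees(acos(cos_ha))
        noon = 720.0 - 4.0 * lon - eqtime
        minutes = noon - 4.0 * ha if rising else noon + 4.0 * ha
    return minutes


@dataclass(frozen=True)
class SolarDay:
    date: dt.date
    nautical_dawn: pd.Timestamp
    sunrise: pd.Timestamp
    sunset: pd.Timestamp
    nautical_dusk: pd.Timestamp


class SunCalendar:
    """Per-date solar events for one site; dates keyed in UTC."""

    def __init__(self, lat: float, lon: float):
        self.lat = float(lat)
        self.lon = float(lon)
        self._days: dict[dt.date, SolarDay] = {}

    def day(self, date: dt.date) -> SolarDay:
        if date not in self._days:
            def ev(alt, rising):
                m = _event_minutes(date, self.lat, self.lon, alt, rising)
                base = pd.Timestamp(date, tz="UTC")
                return base + pd.Timedelta(minutes=m)

            sd = SolarDay(
                date=date,
                nautical_dawn=ev(NAUTICAL_ALTITUDE, True),
                sunrise=ev(SUNRISE_ALTITUDE, True),
                sunset=ev(SUNRISE_ALTITUDE, False),
                nautical_dusk=ev(NAUTICAL_ALTITUDE, False),
            )
            if not (sd.nautical_dawn < sd.sunrise < sd.sunset < sd.nautical_dusk):
                raise UnsupportedLatitudeError(
                    f"solar events out of order at latitude {self.lat} on {date}"
                )
            self._days[date] = sd
        return self._days[date]


def classify_time_of_day(timestamp, calendar: SunCalendar) -> str:
    """Categorise one timestamp as dawn/day/dusk/night."""
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    d = calendar.day(ts.date())
    if d.nautical_dawn <= ts < d.sunrise:
        return "dawn"
    if d.sunrise <= ts < d.sunset:
        return "day"
    if d.sunset <= ts < d.nautical_dusk:
        return "dusk"
    return "night"


def classify_series(timestamps, calendar: SunCalendar) -> pd.Series:
    idx = pd.Series(pd.to_datetime(timestamps, utc=True))
    return idx.map(lambda t: classify_time_of_day(t, calendar))
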