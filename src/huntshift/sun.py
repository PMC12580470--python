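"""Solar geometry for day/night classification and solar-time transforms.

Camera-trap activity analyses need two pieces of solar geometry:

* a *nautical-twilight* day/night classification — "night" runs from the
  onset of evening nautical twilight (sun altitude crossing -12 degrees on
  the way down) to the end of morning nautical twilight (crossing -12 on
  the way up);
* a clock-to-solar-time transform that anchors sunrise at pi/2 and sunset
  at 3*pi/2 on the circle, so diel activity densities are comparable across
  seasons despite shifting day length.

Solar position uses the standard NOAA low-precision ephemeris (fractional
year, equation of time, declination), accurate to well under 0.5 degrees of
altitude, i.e. about a minute of event timing at mid-latitudes. Crossing
instants are refined by root finding on the altitude function.

All instants are timezone-aware; computation happens in UTC. Results for a
(date, lat, lon) triple are cached, so classifying large event tables costs
one ephemeris solve per study day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, timedelta, timezone
from functools import lru_cache

from scipy.optimize import brentq

TWO_PI = 2.0 * math.pi

#: geometric altitude of the sun centre at rise/set (refraction + solar radius)
RISE_SET_ALTITUDE_DEG = -0.833
#: nautical twilight depression
NAUTICAL_DEPRESSION_DEG = 12.0

# Bavarian Forest study-area centroid; individual cameras may override, but
# the park spans <0.5 degrees so twilight differs by under two minutes.
DEFAULT_LAT = 49.0
DEFAULT_LON = 13.4


class NoCrossingError(ValueError):
    """The sun never crosses the requested altitude on this date (polar edge case)."""


def _ensure_aware(instant: datetime) -> datetime:
    if instant.tzinfo is None:
        raise ValueError("instant must be timezone-aware")
    return instant.astimezone(timezone.utc)


def _frac_year(instant_utc: datetime) -> float:
    doy = instant_utc.timetuple().tm_yday
    hour = instant_utc.hour + instant_utc.minute / 60 + instant_utc.second / 3600
    return TWO_PI / 365.0 * (doy - 1 + (hour - 12) / 24)


def _eqtime_decl(instant_utc: datetime) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians), NOAA series."""
    g = _frac_year(instant_utc)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def sun_altitude(lat: float, lon: float, instant: datetime) -> float:
    """Geometric solar altitude in degrees above the horizon.

    No refraction correction is applied; rise/set uses the conventional
    -0.833 degree threshold instead.
    """
    t = _ensure_aware(instant)
    eqtime, decl = _eqtime_decl(t)
    utc_minutes = t.hour * 60 + t.minute + t.second / 60 + t.microsecond / 6e7
    true_solar_min = (utc_minutes + eqtime + 4 * lon) % 1440
    ha = math.radians(true_solar_min / 4 - 180)
    lat_r = math.radians(lat)
    cos_zenith = math.sin(lat_r) * math.sin(decl) + math.cos(lat_r) * math.cos(decl) * math.cos(ha)
    cos_zenith = max(-1.0, min(1.0, cos_zenith))
    return 90.0 - math.degrees(math.acos(cos_zenith))


@dataclass(frozen=True)
class SunTimes:
    """Rise/set and nautical twilight instants for one civil (UTC) date."""

    date: Date
    lat: float
    lon: float
    sunrise: datetime
    sunset: datetime
    nautical_dawn_end: datetime  # morning -12 degree crossing (upward)
    nautical_dusk_start: datetime  # evening -12 degree crossing (downward)


def _solar_noon_utc(lat: float, lon: float, date: Date) -> datetime:
    approx = datetime(date.year, date.month, date.day, 12, 0, tzinfo=timezone.utc)
    eqtime, _ = _eqtime_decl(approx)
    noon_minutes = 720 - 4 * lon - eqtime
    return datetime(date.year, date.month, date.day, tzinfo=timezone.utc) + timedelta(
        minutes=noon_minutes
    )


def _crossing(lat: float, lon: float, t_lo: datetime, t_hi: datetime, target_alt: float) -> datetime:
    """Instant in (t_lo, t_hi) where altitude crosses target, to < 1 s."""

    def f(seconds: float) -> float:
        return sun_altitude(lat, lon, t_lo + timedelta(seconds=seconds)) - target_alt

    span = (t_hi - t_lo).total_seconds()
    a, b = f(0.0), f(span)
    if a * b > 0:
        raise NoCrossingError(
            f"sun does not cross altitude {target_alt} deg between {t_lo} and {t_hi} "
            f"at lat={lat}, lon={lon}"
        )
    root = brentq(f, 0.0, span, xtol=0.5)
    return t_lo + timedelta(seconds=root)


@lru_cache(maxsize=4096)
def twilight_times(
    lat: float, lon: float, date: Date, depression: float = NAUTICAL_DEPRESSION_DEG
) -> SunTimes:
    """Sunrise/sunset and twilight crossings for the given UTC date.

    Raises :class:`NoCrossingError` at high latitudes where the sun does not
    cross the requested altitude; the study area (~49 N) always has crossings.
    """
    noon = _solar_noon_utc(lat, lon, date)
    midnight_before = noon - timedelta(hours=12)
    midnight_after = noon + timedelta(hours=12)
    sunrise = _crossing(lat, lon, midnight_before, noon, RISE_SET_ALTITUDE_DEG)
    sunset = _crossing(lat, lon, noon, midnight_after, RISE_SET_ALTITUDE_DEG)
    dawn_end = _crossing(lat, lon, midnight_before, noon, -abs(depression))
    dusk_start = _crossing(lat, lon, noon, midnight_after, -abs(depression))
    return SunTimes(
        date=date,
        lat=lat,
        lon=lon,
        sunrise=sunrise,
        sunset=sunset,
        nautical_dawn_end=dawn_end,
        nautical_dusk_start=dusk_start,
    )


def is_night(instant: datetime, lat: float = DEFAULT_LAT, lon: float = DEFAULT_LON) -> bool:
    """True iff the instant falls between evening nautical-dusk onset and the
    next morning nautical-dawn end.

    The day interval [dawn_end, dusk_start) is half-open: an event exactly at
    dawn end counts as day, one exactly at dusk start counts as night.
    """
    t = _ensure_aware(instant)
    d = t.date()
    for day in (d - timedelta(days=1), d, d + timedelta(days=1)):
        st = twilight_times(lat, lon, day)
        if st.nautical_dawn_end <= t < st.nautical_dusk_start:
            return False
    return True


def to_solar_radians(instant: datetime, lat: float = DEFAULT_LAT, lon: float = DEFAULT_LON) -> float:
    """Map clock time to solar radians with sunrise at pi/2 and sunset at 3*pi/2.

    The transform is the double-anchored ("equinoctial") map: the daylight
    interval [sunrise, sunset] is stretched linearly onto [pi/2, 3*pi/2] and
    each night interval [sunset, next sunrise] onto [3*pi/2, 2*pi + pi/2]
    (mod 2*pi), using date-specific sun times. Continuous and monotone within
    each 24 h window; returns a value in [0, 2*pi).
    """
    t = _ensure_aware(instant)
    d = t.date()
    days = (d - timedelta(days=1), d, d + timedelta(days=1))
    st = [twilight_times(lat, lon, day) for day in days]
    for i, s in enumerate(st):
        if s.sunrise <= t <= s.sunset:
            frac = (t - s.sunrise).total_seconds() / (s.sunset - s.sunrise).total_seconds()
            return (math.pi / 2 + math.pi * frac) % TWO_PI
        if i + 1 < len(st) and s.sunset < t < st[i + 1].sunrise:
            night_len = (st[i + 1].sunrise - s.sunset).total_seconds()
            frac = (t - s.sunset).total_seconds() / night_len
            return (3 * math.pi / 2 + math.pi * frac) % TWO_PI
    raise NoCrossingError(f"could not bracket {t} between sun events at lat={lat}, lon={lon}")
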