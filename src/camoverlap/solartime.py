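"""Conversion of clock times to solar-anchored times in radians.

Diel activity analyses compare times of day across a survey that spans
seasons, so the raw clock time is re-anchored to the sun: each day's sunrise
maps to pi/2 and sunset to 3*pi/2, with linear interpolation inside the day
and night segments.  This removes seasonal day-length variation — a detection
"one hour after sunrise" lands at the same angle in June and December.

Sunrise and sunset come from the standard NOAA solar-position equations
(fractional-year Fourier series for declination and the equation of time,
hour angle at the conventional -0.833 degree solar altitude).  Accuracy is a
couple of minutes, ample for activity-pattern work.

Three modes are exposed:

``anchored``
    the sunrise/sunset double-anchored transform above (default);
``equation_of_time``
    apparent solar time (clock corrected by the equation of time and the
    site's offset from its time-zone meridian) mapped linearly to radians —
    equalises solar noon but not day length;
``none``
    clock time mapped linearly to radians (2*pi = 24 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

TWO_PI = 2.0 * math.pi

#: Solar altitude defining sunrise/sunset (degrees): geometric horizon minus
#: standard refraction and solar semi-diameter.
SUNRISE_ALTITUDE_DEG = -0.833

#: Latitude band where the anchored transform is defined year-round.
MAX_ABS_LAT = 66.5

SOLAR_MODES = ("anchored", "equation_of_time", "none")


class PolarDayError(ValueError):
    """The sun does not rise or does not set on the given date."""


@dataclass(frozen=True)
class SolarContext:
    """Location, UTC offset and date for a solar-time conversion."""

    lon: float
    lat: float
    utc_offset: float
    date: date

    def __post_init__(self) -> None:
        if abs(self.lat) >= MAX_ABS_LAT:
            raise ValueError(
                f"latitude {self.lat} outside the +/-{MAX_ABS_LAT} deg band "
                "supported by the anchored transform"
            )


def _fractional_year(day: date, hour: float = 12.0) -> float:
    doy = day.timetuple().tm_yday
    year_len = 366 if day.year % 4 == 0 and (day.year % 100 != 0 or day.year % 400 == 0) else 365
    return TWO_PI / year_len * (doy - 1 + (hour - 12.0) / 24.0)


def equation_of_time_minutes(day: date) -> float:
    """NOAA equation of time (minutes; apparent minus mean solar time)."""
    g = _fractional_year(day)
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )


def solar_declination(day: date) -> float:
    """Solar declination (radians), NOAA Fourier series."""
    g = _fractional_year(day)
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def sun_events(ctx: SolarContext) -> tuple[datetime, datetime]:
    """Local-clock sunrise and sunset datetimes for the context's date."""
    lat = math.radians(ctx.lat)
    decl = solar_declination(ctx.date)
    cos_zenith = math.cos(math.radians(90.0 - SUNRISE_ALTITUDE_DEG))
    cos_ha = (cos_zenith - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise PolarDayError(
            f"no sunrise/sunset at lat {ctx.lat} on {ctx.date}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    eqtime = equation_of_time_minutes(ctx.date)
    noon_utc_min = 720.0 - 4.0 * ctx.lon - eqtime
    rise_min = noon_utc_min - 4.0 * ha_deg + ctx.utc_offset * 60.0
    set_min = noon_utc_min + 4.0 * ha_deg + ctx.utc_offset * 60.0
    midnight = datetime.combine(ctx.date, time(0, 0))
    return (
        midnight + timedelta(minutes=rise_min),
        midnight + timedelta(minutes=set_min),
    )


def _minutes_of_day(ts: datetime) -> float:
    return ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7


def clock_to_solar(
    timestamp: datetime,
    ctx: SolarContext | None = None,
    *,
    lon: float | None = None,
    lat: float | None = None,
    utc_offset: float | None = None,
    mode: str = "anchored",
) -> float:
    """Map a local clock time to a solar angle in [0, 2*pi).

    In ``anchored`` mode that day's sunrise maps to pi/2 and sunset to
    3*pi/2; times within daylight and within night are interpolated linearly,
    so the map is piecewise linear with exactly two pieces and strictly
    increasing through the day.
    """
    if mode not in SOLAR_MODES:
        raise ValueError(f"mode must be one of {SOLAR_MODES}")
    if mode == "none":
        return (_minutes_of_day(timestamp) / 1440.0 * TWO_PI) % TWO_PI
    if ctx is None:
        if lon is None or lat is None or utc_offset is None:
            raise ValueError("provide a SolarContext or lon/lat/utc_offset")
        ctx = SolarContext(lon=lon, lat=lat, utc_offset=utc_offset,
                           date=timestamp.date())
    elif ctx.date != timestamp.date():
        ctx = SolarContext(ctx.lon, ctx.lat, ctx.utc_offset, timestamp.date())

    if mode == "equation_of_time":
        # apparent solar minutes = clock + EoT + 4 min/deg offset from the
        # time-zone reference meridian
        meridian = ctx.utc_offset * 15.0
        solar_min = (
            _minutes_of_day(timestamp)
            + equation_of_time_minutes(ctx.date)
            + 4.0 * (ctx.lon - meridian)
        )
        return (solar_min / 1440.0 * TWO_PI) % TWO_PI

    sunrise, sunset = sun_events(ctx)
    t = _minutes_of_day(timestamp)
    rise = _minutes_of_day(sunrise)
    sset = _minutes_of_day(sunset)
    day_len = sset - rise
    night_len = 1440.0 - day_len
    if rise <= t <= sset:
        return (math.pi / 2 + math.pi * (t - rise) / day_len) % TWO_PI
    if t > sset:
        frac = (t - sset) / night_len
    else:  # pre-dawn: position within the night that ends at this sunrise
        frac = (t + 1440.0 - sset) / night_len
    return (3 * math.pi / 2 + math.pi * frac) % TWO_PI


def solar_to_clock(
    angle: float,
    ctx: SolarContext,
    mode: str = "anchored",
) -> float:
    """Inverse of :func:`clock_to_solar`: minutes of day for a solar angle.

    Used by the synthetic generator to turn activity-model angles into the
    clock times a camera would stamp.  For the night segment the angle is
    placed within the night that *starts* at this date's sunset, wrapping
    past midnight onto the same clock dial.
    """
    if mode not in SOLAR_MODES:
        raise ValueError(f"mode must be one of {SOLAR_MODES}")
    angle = angle % TWO_PI
    if mode == "none":
        return angle / TWO_PI * 1440.0
    if mode == "equation_of_time":
        meridian = ctx.utc_offset * 15.0
        solar_min = angle / TWO_PI * 1440.0
        return (
            solar_min - equation_of_time_minutes(ctx.date)
            - 4.0 * (ctx.lon - meridian)
        ) % 1440.0
    sunrise, sunset = sun_events(ctx)
    rise = _minutes_of_day(sunrise)
    sset = _minutes_of_day(sunset)
    day_len = sset - rise
    night_len = 1440.0 - day_len
    if math.pi / 2 <= angle <= 3 * math.pi / 2:
        return rise + (angle - math.pi / 2) / math.pi * day_len
    frac = ((angle - 3 * math.pi / 2) % TWO_PI) / math.pi
    return (sset + frac * night_len) % 1440.0
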