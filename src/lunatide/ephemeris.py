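"""Low-precision solar and lunar ephemeris.

Self-contained closed-form series (no ephemeris files, no network): solar
position after the truncated equation-of-center series, lunar position after
the standard low-precision polynomial series (the ones printed in the
Astronomical Almanac), both good to a few tenths of a degree — ample for
photoperiod and moonlight-availability work, where minutes matter but
arcseconds do not.

Accuracy contract (verified against frozen almanac values in the test
suite):

* sun altitude:  +/- 0.5 deg
* moon altitude: +/- 0.5 deg (geocentric; see note below)
* illuminated fraction: +/- 0.02
* full-moon instants: within 3 h of almanac values

Conventions: all timestamps UTC; moon "visibility" uses geometric
geocentric altitude > 0 (no refraction or topocentric parallax); sunrise
and sunset use the usual -0.83 deg disk-top-plus-refraction altitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GeoLocation",
    "MoonState",
    "RelativeMoonlightSeries",
    "SITES",
    "sun_altitude",
    "sunrise_sunset",
    "daylength",
    "moon_state",
    "full_moons",
    "relative_moonlight",
    "SYNODIC_MONTH_DAYS",
    "LUNAR_DAY_HOURS",
]

#: Mean synodic month (new moon to new moon), days.
SYNODIC_MONTH_DAYS = 29.530589

#: Mean lunar day (successive moon transits), hours; drives the ~48-min
#: daily shift of moonrise and of semidiurnal tides.
LUNAR_DAY_HOURS = 24.8

_J2000 = pd.Timestamp("2000-01-01 12:00:00")
_DEG = np.pi / 180.0


@dataclass(frozen=True)
class GeoLocation:
    """A site on Earth; latitude north, longitude east, degrees."""

    latitude: float
    longitude: float
    name: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


#: Field sites of the three Clunio marinus strains/populations studied.
SITES = {
    "dinard": GeoLocation(48.63, -2.06, "Dinard"),
    "vigo": GeoLocation(42.24, -8.72, "Vigo"),
    "port-en-bessin": GeoLocation(49.35, -0.75, "Port-en-Bessin"),
}


@dataclass(frozen=True)
class MoonState:
    """Geocentric moon altitude (deg) and illuminated fraction [0, 1]."""

    altitude: float | np.ndarray
    illuminated_fraction: float | np.ndarray


@dataclass
class RelativeMoonlightSeries:
    """Unitless in-land moonlight proxy, normalized to a maximum of 1.

    Value at each instant is ``illuminated_fraction * max(altitude, 0)``
    divided by the series maximum; zero whenever the moon is below the
    horizon.  The altitude factor is the clamped altitude angle itself
    (normalization absorbs the unit, so degrees vs radians is immaterial).
    """

    series: pd.Series
    location: GeoLocation
    normalization: float = field(default=1.0)

    @property
    def instants(self) -> pd.DatetimeIndex:
        return self.series.index

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()


# --------------------------------------------------------------------------
# time helpers


def _to_index(t) -> tuple[pd.DatetimeIndex, bool]:
    """Coerce scalar/sequence of instants to a DatetimeIndex (UTC, naive)."""
    scalar = np.isscalar(t) or isinstance(t, pd.Timestamp)
    idx = pd.DatetimeIndex([t]) if scalar else pd.DatetimeIndex(t)
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    return idx, scalar


def _days_j2000(idx: pd.DatetimeIndex) -> np.ndarray:
    """Days since J2000.0 (2000-01-01 12:00 UT), float."""
    return (idx - _J2000) / pd.Timedelta(days=1)


def _from_days(d: float) -> pd.Timestamp:
    return _J2000 + pd.Timedelta(days=float(d))


# --------------------------------------------------------------------------
# solar position (truncated equation-of-center series; ~0.01 deg)


def _sun_ecliptic(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geocentric ecliptic longitude (deg) and distance (AU) of the sun."""
    T = d / 36525.0
    L0 = 280.46646 + 36000.76983 * T
    M = 357.52911 + 35999.05029 * T
    Mr = M * _DEG
    C = (
        (1.914602 - 0.004817 * T) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    lon = (L0 + C) % 360.0
    e = 0.016708634 - 0.000042037 * T
    nu = (M + C) * _DEG
    R = 1.000001018 * (1 - e * e) / (1 + e * np.cos(nu))
    return lon, R


def _obliquity(d: np.ndarray) -> np.ndarray:
    return 23.4392911 - 0.0130042 * (d / 36525.0)


def _gmst_deg(d: np.ndarray) -> np.ndarray:
    T = d / 36525.0
    return (280.46061837 + 360.98564736629 * d + 0.000387933 * T * T) % 360.0


def _ecl_to_equatorial(
    lon: np.ndarray, lat: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ecliptic lon/lat (deg) -> right ascension, declination (deg)."""
    eps = _obliquity(d) * _DEG
    lo, la = lon * _DEG, lat * _DEG
    sin_dec = np.sin(la) * np.cos(eps) + np.cos(la) * np.sin(eps) * np.sin(lo)
    dec = np.arcsin(np.clip(sin_dec, -1.0, 1.0))
    ra = np.arctan2(
        np.sin(lo) * np.cos(eps) - np.tan(la) * np.sin(eps), np.cos(lo)
    )
    return np.degrees(ra) % 360.0, np.degrees(dec)


def _altitude(
    ra: np.ndarray, dec: np.ndarray, d: np.ndarray, loc: GeoLocation
) -> np.ndarray:
    """Geometric altitude (deg) of a body at RA/dec for a site."""
    H = (_gmst_deg(d) + loc.longitude - ra) * _DEG
    phi = loc.latitude * _DEG
    de = dec * _DEG
    sin_alt = np.sin(phi) * np.sin(de) + np.cos(phi) * np.cos(de) * np.cos(H)
    return np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))


def sun_altitude(t, loc: GeoLocation):
    """Geometric solar altitude in degrees at instant(s) ``t``.

    Total function: accepts a scalar timestamp or any sequence coercible to
    a DatetimeIndex; returns a float or ndarray accordingly.
    """
    idx, scalar = _to_index(t)
    d = _days_j2000(idx)
    lon, _ = _sun_ecliptic(d)
    ra, dec = _ecl_to_equatorial(lon, np.zeros_like(lon), d)
    alt = _altitude(ra, dec, d, loc)
    return float(alt[0]) if scalar else alt


# --------------------------------------------------------------------------
# lunar position (low-precision almanac series; ~0.3 deg)

# (coefficient deg, phase deg, rate deg/Julian-century) sine terms
_MOON_LON_TERMS = (
    (6.29, 134.9, 477198.85),
    (-1.27, 259.2, -413335.38),
    (0.66, 235.7, 890534.23),
    (0.21, 269.9, 954397.70),
    (-0.19, 357.5, 35999.05),
    (-0.11, 186.6, 966404.05),
)
_MOON_LAT_TERMS = (
    (5.13, 93.3, 483202.03),
    (0.28, 228.2, 960400.87),
    (-0.28, 318.3, 6003.18),
    (-0.17, 217.6, -407332.20),
)
_MOON_PAR_TERMS = (
    (0.0518, 134.9, 477198.85),
    (0.0095, 259.2, -413335.38),
    (0.0078, 235.7, 890534.23),
    (0.0028, 269.9, 954397.70),
)


def _moon_ecliptic(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moon ecliptic lon, lat (deg) and distance (AU)."""
    T = d / 36525.0
    lon = 218.32 + 481267.8813 * T
    for a, p, r in _MOON_LON_TERMS:
        lon = lon + a * np.sin((p + r * T) * _DEG)
    lat = np.zeros_like(T)
    for a, p, r in _MOON_LAT_TERMS:
        lat = lat + a * np.sin((p + r * T) * _DEG)
    par = np.full_like(T, 0.9508)
    for a, p, r in _MOON_PAR_TERMS:
        par = par + a * np.cos((p + r * T) * _DEG)
    dist_au = (6378.14 / np.sin(par * _DEG)) / 1.495978707e8
    return lon % 360.0, lat, dist_au


def _illuminated_fraction(d: np.ndarray) -> np.ndarray:
    """Fraction of the lunar disk illuminated, from the phase angle."""
    slon, R = _sun_ecliptic(d)
    mlon, mlat, delta = _moon_ecliptic(d)
    cos_psi = np.cos(mlat * _DEG) * np.cos((mlon - slon) * _DEG)
    psi = np.arccos(np.clip(cos_psi, -1.0, 1.0))
    # phase angle at the moon: sun much farther than the moon
    i = np.arctan2(R * np.sin(psi), delta - R * np.cos(psi))
    return (1.0 + np.cos(i)) / 2.0


def moon_state(t, loc: GeoLocation) -> MoonState:
    """Moon altitude (deg, geocentric geometric) and illuminated fraction."""
    idx, scalar = _to_index(t)
    d = _days_j2000(idx)
    mlon, mlat, _ = _moon_ecliptic(d)
    ra, dec = _ecl_to_equatorial(mlon, mlat, d)
    alt = _altitude(ra, dec, d, loc)
    frac = _illuminated_fraction(d)
    if scalar:
        return MoonState(float(alt[0]), float(frac[0]))
    return MoonState(alt, frac)


# --------------------------------------------------------------------------
# rise/set and full moons


def _sun_dec_eqtime(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solar declination (deg) and equation of time (hours)."""
    lon, _ = _sun_ecliptic(d)
    ra, dec = _ecl_to_equatorial(lon, np.zeros_like(lon), d)
    T = d / 36525.0
    L0 = (280.46646 + 36000.76983 * T) % 360.0
    eqt = (L0 - ra + 180.0) % 360.0 - 180.0  # deg; apparent - mean sun
    return dec, eqt / 15.0


def sunrise_sunset(
    date, loc: GeoLocation, altitude_deg: float = -0.83
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Sunrise and sunset (UTC) for the calendar date at a site.

    Crossing altitude defaults to -0.83 deg (solar disk top + mean
    refraction).  Returns ``None`` on polar day/night (no crossing).
    """
    day = pd.Timestamp(date).normalize()
    noon_guess = day + pd.Timedelta(hours=12 - loc.longitude / 15.0)
    d = np.atleast_1d(_days_j2000(pd.DatetimeIndex([noon_guess])))
    dec, eqt = _sun_dec_eqtime(d)
    solar_noon = day + pd.Timedelta(
        hours=12.0 - loc.longitude / 15.0 - float(eqt[0])
    )
    phi = loc.latitude * _DEG

    def _half_arc_hours(dec_deg: float) -> float | None:
        de = dec_deg * _DEG
        cos_h = (np.sin(altitude_deg * _DEG) - np.sin(phi) * np.sin(de)) / (
            np.cos(phi) * np.cos(de)
        )
        if not -1.0 <= cos_h <= 1.0:
            return None
        return float(np.degrees(np.arccos(cos_h))) / 15.0

    h = _half_arc_hours(float(dec[0]))
    if h is None:
        return None
    rise = solar_noon - pd.Timedelta(hours=h)
    sett = solar_noon + pd.Timedelta(hours=h)
    # one refinement pass with declination at the event times
    for _ in range(2):
        dr = np.atleast_1d(_days_j2000(pd.DatetimeIndex([rise, sett])))
        decs, _eq = _sun_dec_eqtime(dr)
        h1 = _half_arc_hours(float(decs[0]))
        h2 = _half_arc_hours(float(decs[1]))
        if h1 is None or h2 is None:
            return None
        rise = solar_noon - pd.Timedelta(hours=h1)
        sett = solar_noon + pd.Timedelta(hours=h2)
    return rise.round("s"), sett.round("s")


def daylength(date, loc: GeoLocation) -> float | None:
    """Light-phase duration in hours for a date, or None on polar days."""
    rs = sunrise_sunset(date, loc)
    if rs is None:
        return None
    rise, sett = rs
    return (sett - rise) / pd.Timedelta(hours=1)


def _elongation_deg(d: np.ndarray) -> np.ndarray:
    """Sun->moon ecliptic longitude difference in [0, 360)."""
    slon, _ = _sun_ecliptic(d)
    mlon, _, _ = _moon_ecliptic(d)
    return (mlon - slon) % 360.0


def full_moons(start, end) -> pd.DatetimeIndex:
    """Instants of full moon (maximum illuminated fraction) in [start, end].

    The illuminated fraction peaks where the sun-moon elongation passes
    180 deg; each upward crossing is bracketed on a coarse grid and refined
    by root finding, well within the 3-h accuracy contract.
    """
    t0, t1 = pd.Timestamp(start), pd.Timestamp(end)
    if t1 <= t0:
        return pd.DatetimeIndex([])
    # pad so events at the range edges are bracketed
    grid = pd.date_range(
        t0 - pd.Timedelta(days=1), t1 + pd.Timedelta(days=1), freq="3h"
    )
    d = _days_j2000(grid)
    g = (_elongation_deg(d) - 180.0 + 180.0) % 360.0 - 180.0  # in [-180,180)

    def _g(day: float) -> float:
        e = _elongation_deg(np.atleast_1d(np.asarray(day, dtype=float)))
        return float((e[0] - 180.0 + 180.0) % 360.0 - 180.0)

    events = []
    for i in np.nonzero((g[:-1] < 0) & (g[1:] >= 0))[0]:
        root = brentq(_g, d[i], d[i + 1], xtol=1e-5)
        ts = _from_days(root).round("min")
        if t0 <= ts <= t1:
            events.append(ts)
    return pd.DatetimeIndex(events)


def relative_moonlight(
    instants, loc: GeoLocation, altitude_unit: str = "deg"
) -> RelativeMoonlightSeries:
    """In-land relative moonlight: illuminated fraction x clamped altitude.

    The product is normalized so the series maximum is 1.  ``altitude_unit``
    ("deg" or "rad") only rescales the altitude factor; the normalization
    absorbs it, which the test suite asserts.

    Raises ``ValueError`` if the moon never rises in the series (the
    normalization would be degenerate).
    """
    idx, _ = _to_index(instants)
    st = moon_state(idx, loc)
    alt = np.asarray(st.altitude, dtype=float)
    if altitude_unit == "rad":
        alt = alt * _DEG
    elif altitude_unit != "deg":
        raise ValueError(f"unknown altitude unit: {altitude_unit!r}")
    raw = np.asarray(st.illuminated_fraction) * np.clip(alt, 0.0, None)
    peak = float(raw.max()) if len(raw) else 0.0
    if peak <= 0.0:
        raise ValueError(
            "moon never above the horizon in the series; "
            "relative moonlight normalization is degenerate"
        )
    return RelativeMoonlightSeries(
        pd.Series(raw / peak, index=idx, name="rel_moonlight"), loc, peak
    )
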