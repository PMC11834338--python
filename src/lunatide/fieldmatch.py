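"""Matching laboratory moonlight windows to field moonlight availability.

The laboratory experiments present moonlight in fixed zeitgeber-time (ZT)
windows under a 16:8 LD cycle with ZT0 at mid-dark.  To ask where those
windows would fall in nature, the field photoperiod is embedded in the
same 16:8 frame (longest-day light phase rounded to whole hours, mid-dark
anchored at ZT0), each experimental window is placed on the four
consecutive lunar days where it overlaps tidally-gated moonlight best,
laboratory emergence histograms are projected onto field days through that
placement, and the result is compared against the spring-tide days (lowest
averaged low tide +/- 2 days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ephemeris import GeoLocation, sunrise_sunset
from .underwater import AveragedLunarCycle

__all__ = [
    "LDFit",
    "WindowPlacement",
    "SpringTideSet",
    "fit_field_ld",
    "place_window",
    "project_emergence",
    "spring_tide_days",
]


@dataclass(frozen=True)
class LDFit:
    """Field photoperiod embedded in the laboratory light-dark frame.

    ``field_light_h``: longest-day light phase rounded to whole hours.
    ``lab_light_h``/``lab_dark_h``: the laboratory frame (16:8).
    ``zt0_utc_h``: UTC clock time (hours) of ZT0 = middle of the fitted
    dark phase.  The fitted light phase runs from ``light_start_utc_h``
    to ``light_end_utc_h`` (the 16-h lab photophase centered opposite
    ZT0).
    """

    field_light_h: int
    lab_light_h: float
    lab_dark_h: float
    zt0_utc_h: float
    longest_day: pd.Timestamp

    @property
    def light_start_utc_h(self) -> float:
        return (self.zt0_utc_h + self.lab_dark_h / 2.0) % 24.0

    @property
    def light_end_utc_h(self) -> float:
        return (self.zt0_utc_h - self.lab_dark_h / 2.0) % 24.0

    def zt_to_utc_h(self, zt: float) -> float:
        """ZT clock value -> UTC clock hours (ZT0 anchored)."""
        offset = ((zt + 12.0) % 24.0) - 12.0  # ZT20 -> -4 h, ZT2 -> +2 h
        return (self.zt0_utc_h + offset) % 24.0


@dataclass(frozen=True)
class WindowPlacement:
    """A ZT window placed on four consecutive lunar days."""

    window_start_zt: float
    window_hours: float
    start_day: int
    end_day: int
    overlap_hours: float
    period_days: int = 30

    @property
    def days(self) -> tuple[int, ...]:
        p = self.period_days
        return tuple(
            (self.start_day - 1 + k) % p + 1 for k in range(4)
        )


@dataclass(frozen=True)
class SpringTideSet:
    """Spring-tide block: anchor day (lowest low tide) +/- 2 days."""

    anchor_day: int
    days: tuple[int, ...]
    period_days: int = 30


def fit_field_ld(
    loc: GeoLocation,
    start,
    end,
    lab_light_h: float = 16.0,
) -> LDFit:
    """Embed a site's photoperiod into the laboratory LD frame.

    Finds the longest day in [start, end], rounds its light phase to whole
    hours (the field LD), and anchors ZT0 at the middle of that day's dark
    phase, rounded to the nearest half hour — the laboratory 16:8 frame is
    then laid around that anchor.  Raises for polar locations where some
    day in the range has no sunrise/sunset.
    """
    dates = pd.date_range(
        pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize(), freq="D"
    )
    best: tuple[float, pd.Timestamp, pd.Timestamp, pd.Timestamp] | None = None
    for date in dates:
        rs = sunrise_sunset(date, loc)
        if rs is None:
            raise ValueError(
                f"no sunrise/sunset at {loc.name or loc} on {date.date()}"
            )
        rise, sett = rs
        dl = (sett - rise) / pd.Timedelta(hours=1)
        if best is None or dl > best[0]:
            best = (dl, date, rise, sett)
    assert best is not None
    dl, date, rise, sett = best
    field_light = int(round(dl))
    mid_dark = sett + pd.Timedelta(hours=(24.0 - dl) / 2.0)
    zt0 = (mid_dark.hour + mid_dark.minute / 60.0 + mid_dark.second / 3600.0)
    zt0 = (round(zt0 * 2.0) / 2.0) % 24.0  # nearest half hour
    return LDFit(field_light, lab_light_h, 24.0 - lab_light_h, zt0, date)


def _availability_minutes(
    availability: AveragedLunarCycle | pd.DataFrame, threshold: float
) -> tuple[np.ndarray, int, int]:
    """Grid -> (visible boolean per minute-of-cycle, period, bin minutes)."""
    grid = (
        availability.grid.values
        if isinstance(availability, AveragedLunarCycle)
        else availability
    )
    period = grid.shape[1]
    clock = grid.index.to_numpy()
    bin_min = int(clock[1] - clock[0]) if len(clock) > 1 else 1440
    vals = grid.to_numpy()  # clock x day
    vis = np.zeros(period * 1440, dtype=bool)
    for j, day in enumerate(grid.columns):
        for i, c in enumerate(clock):
            v = vals[i, j]
            if np.isfinite(v) and v > threshold:
                s = (int(day) - 1) * 1440 + int(c)
                vis[s : s + bin_min] = True
    return vis, period, bin_min


def place_window(
    window_start_zt: float,
    window_hours: float,
    availability: AveragedLunarCycle | pd.DataFrame,
    ld: LDFit,
    min_visible_h: float = 2.0,
    threshold: float = 0.0,
) -> WindowPlacement:
    """Place a ZT window on the field days where it best meets moonlight.

    Scans every run of four consecutive lunar days on which at least
    ``min_visible_h`` of moonlight is visible per night (availability
    above ``threshold`` on the tidally filtered grid), and returns the
    placement maximizing the summed overlap between the window (converted
    to field UTC clock through ``ld``) and the visible minutes.  Ties go
    to the earliest day range in cycle order.  Raises if no run of four
    days satisfies the visibility requirement or the window never overlaps
    visible moonlight.
    """
    vis, period, _ = _availability_minutes(availability, threshold)
    total = period * 1440

    # night n is centered on ZT0 of day n (clock zt0_utc_h, near midnight)
    zt0_min = int(round(ld.zt0_utc_h * 60.0))
    dark_half = int(round(ld.lab_dark_h * 30.0))  # dark_h/2 in minutes
    u0 = ld.zt_to_utc_h(window_start_zt)
    woff = int(round((((u0 - ld.zt0_utc_h + 12.0) % 24.0) - 12.0) * 60.0))
    wlen = int(round(window_hours * 60.0))

    def night_slice(n: int) -> np.ndarray:
        c = (n - 1) * 1440 + zt0_min
        return vis.take(
            np.arange(c - dark_half, c + dark_half), mode="wrap"
        )

    def window_overlap(n: int) -> int:
        c = (n - 1) * 1440 + zt0_min
        return int(
            vis.take(np.arange(c + woff, c + woff + wlen), mode="wrap").sum()
        )

    night_vis_min = np.array([night_slice(n).sum() for n in range(1, period + 1)])
    need = min_visible_h * 60.0

    best: tuple[int, int] | None = None  # (overlap, start_day)
    for s in range(1, period + 1):
        nights = [(s - 1 + k) % period + 1 for k in range(4)]
        if any(night_vis_min[n - 1] < need for n in nights):
            continue
        score = sum(window_overlap(n) for n in nights)
        if best is None or score > best[0]:
            best = (score, s)
    if best is None:
        raise ValueError(
            "no four consecutive days with enough visible moonlight"
        )
    if best[0] == 0:
        raise ValueError("window never overlaps visible moonlight")
    score, s = best
    return WindowPlacement(
        window_start_zt,
        window_hours,
        s,
        (s + 2) % period + 1,
        score / 60.0,
        period,
    )


def project_emergence(
    lab_hist: pd.Series,
    placement: WindowPlacement,
    lab_day1: int = 1,
) -> pd.Series:
    """Shift a laboratory emergence histogram onto field days.

    ``lab_hist`` is indexed by day-in-cycle (1..P).  Laboratory Day
    ``lab_day1`` (the treatment's Day-1 anchor) maps to the placement's
    start day; all other days follow circularly.
    """
    p = placement.period_days
    offset = placement.start_day - lab_day1
    days = lab_hist.index.to_numpy(dtype=int)
    new_days = (days - 1 + offset) % p + 1
    out = pd.Series(
        lab_hist.to_numpy(), index=new_days, name=lab_hist.name
    ).sort_index()
    out.index.name = "field_day"
    return out


def spring_tide_days(
    low_tide_levels: pd.Series, halfwidth_days: int = 2
) -> SpringTideSet:
    """Spring-tide block from per-lunar-day averaged low-tide levels.

    The anchor is the day with the minimum averaged low-tide level; the
    flagged block is anchor +/- ``halfwidth_days`` (5 days by default),
    wrapping around the cycle.
    """
    levels = low_tide_levels.dropna()
    if levels.empty:
        raise ValueError("no low-tide levels supplied")
    period = int(low_tide_levels.index.max())
    anchor = int(levels.idxmin())
    days = tuple(
        sorted(
            (anchor - 1 + k) % period + 1
            for k in range(-halfwidth_days, halfwidth_days + 1)
        )
    )
    return SpringTideSet(anchor, days, period)
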