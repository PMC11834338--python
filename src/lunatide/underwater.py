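"""Simulated underwater moonlight: tidal gating of in-land moonlight.

The in-land relative moonlight proxy is multiplied by a tidal attenuation
factor derived from water levels scaled to [-1, 1].  Under the default
"inverted-clamped" convention the factor is ``max(-scaled_level, 0)``:
full transmission at the lowest low tide, darkness whenever the water is
above its midrange — which reproduces the field observation that light
intensities peak at low tide.  The literal product (moonlight x scaled
level, sign and all) is retained behind a flag for comparison.

The gated series is folded into one representative 30-day lunar cycle
(Day 1 = full moon), alongside circularly averaged low-tide and
moon-zenith clock times per lunar day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .radiometry import DielGrid, fold_grid
from .tides import scale_levels

__all__ = [
    "AveragedLunarCycle",
    "modulate",
    "fold_lunar",
    "moontides_filter",
    "circular_mean_hours",
]


@dataclass
class AveragedLunarCycle:
    """One averaged 30-day lunar cycle of underwater moonlight.

    ``grid``: averaged intensity heatmap (clock x day, Day 1 = full moon).
    ``low_tides``: one row per averaged low-tide event — columns ``day``,
    ``rank`` (order within the lunar day; semidiurnal tides have two),
    ``clock_h`` (circular mean over cycles) and ``level_m`` (mean level).
    ``low_tide_level_m``: mean low-tide level per lunar day (all lows of
    the day pooled) — the quantity whose minimum anchors the spring tides.
    ``zenith_clock_h``: circular-mean clock time of the nightly moonlight
    maximum per lunar day (NaN on days without visible moonlight).
    """

    grid: DielGrid
    low_tides: pd.DataFrame
    low_tide_level_m: pd.Series
    zenith_clock_h: pd.Series

    @property
    def period_days(self) -> int:
        return self.grid.period_days


def circular_mean_hours(hours: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of clock times on a ``period``-hour dial."""
    h = np.asarray(hours, dtype=float)
    if len(h) == 0:
        return float("nan")
    ang = 2 * np.pi * h / period
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * period / (2 * np.pi)) % period)


def modulate(
    moon: pd.Series,
    tide: pd.Series,
    convention: str = "inverted",
    step: str = "10min",
) -> pd.Series:
    """Underwater moonlight = in-land moonlight x tidal attenuation.

    Both series are resampled onto a common regular grid over their
    overlap.  ``convention``: "inverted" (default) uses
    ``max(-scaled_level, 0)``; "literal" multiplies by the scaled level
    itself (in [-1, 1], so the product can be negative at high tide).
    """
    t0 = max(moon.index[0], tide.index[0])
    t1 = min(moon.index[-1], tide.index[-1])
    if t1 <= t0:
        raise ValueError("moon and tide series do not overlap in time")
    grid = pd.date_range(t0.ceil(step), t1.floor(step), freq=step)

    def _on_grid(s: pd.Series) -> np.ndarray:
        x = (s.index - s.index[0]) / pd.Timedelta(hours=1)
        xg = (grid - s.index[0]) / pd.Timedelta(hours=1)
        return np.interp(xg, x, s.to_numpy(dtype=float))

    m = _on_grid(moon)
    scaled = _on_grid(scale_levels(tide))
    if convention == "inverted":
        att = np.clip(-scaled, 0.0, None)
    elif convention == "literal":
        att = scaled
    else:
        raise ValueError(f"unknown attenuation convention: {convention!r}")
    return pd.Series(m * att, index=grid, name="underwater_moonlight")


def _assign_lunar_day(
    times: pd.DatetimeIndex, anchors: pd.DatetimeIndex, period_days: int
) -> np.ndarray:
    """Day-in-cycle (1..P) for each instant, or 0 outside all cycles."""
    pos = np.searchsorted(anchors.values, times.values, side="right") - 1
    day = np.zeros(len(times), dtype=int)
    ok = pos >= 0
    offs = (times.values[ok] - anchors.values[pos[ok]]) / np.timedelta64(1, "D")
    d = np.floor(offs).astype(int) + 1
    d[(d < 1) | (d > period_days)] = 0
    day[ok] = d
    return day


def fold_lunar(
    series: pd.Series,
    full_moon_instants,
    period_days: int = 30,
    tide_events: pd.DataFrame | None = None,
    bin_minutes: int | None = None,
) -> AveragedLunarCycle:
    """Average lunar cycles into one representative cycle.

    Cycle anchors are *midnight (UTC) of each full-moon day* — the
    calendar-date midnight containing the full-moon instant.  The grid
    averages the series position-wise; low-tide events (if given) yield
    per-lunar-day circular-mean clock times and mean levels; the nightly
    moonlight maximum yields the per-day zenith clock time.
    """
    fm = pd.DatetimeIndex(full_moon_instants)
    if len(fm) == 0:
        raise ValueError("no full moons in range")
    anchors = fm.normalize().unique().sort_values()
    grid = fold_grid(series, anchors, period_days, bin_minutes)

    if tide_events is not None and len(tide_events):
        lows = tide_events[tide_events["kind"] == "low"]
        lt = pd.DatetimeIndex(lows["time"])
        day = _assign_lunar_day(lt, anchors, period_days)
        cyc = np.searchsorted(anchors.values, lt.values, side="right") - 1
        df = pd.DataFrame(
            {
                "cyc": cyc,
                "day": day,
                "clock": lt.hour + lt.minute / 60.0 + lt.second / 3600.0,
                "level": lows["level_m"].to_numpy(),
            }
        )
        df = df[df["day"] > 0]
        # corresponding lows are matched across cycles by their order
        # within the lunar day (semidiurnal tides: two per day)
        df["rank"] = df.sort_values("clock").groupby(["cyc", "day"]).cumcount()
        by = df.groupby(["day", "rank"])
        low_tides = pd.DataFrame(
            {
                "clock_h": by["clock"].apply(
                    lambda h: circular_mean_hours(h.to_numpy())
                ),
                "level_m": by["level"].mean(),
            }
        ).reset_index()
        low_level = df.groupby("day")["level"].mean()
    else:
        low_tides = pd.DataFrame(columns=["day", "rank", "clock_h", "level_m"])
        low_level = pd.Series(dtype=float)

    # nightly zenith: per (cycle, day) argmax of the series, then circular
    # mean of the clock times across cycles
    idx = series.index
    day = _assign_lunar_day(idx, anchors, period_days)
    cyc = np.searchsorted(anchors.values, idx.values, side="right") - 1
    vals = series.to_numpy(dtype=float)
    zen: dict[int, list[float]] = {}
    df = pd.DataFrame({"cyc": cyc, "day": day, "v": vals}, index=idx)
    df = df[df["day"] > 0]
    for (_, d), sub in df.groupby(["cyc", "day"]):
        if sub["v"].max() > 0:
            t = sub["v"].idxmax()
            zen.setdefault(int(d), []).append(
                t.hour + t.minute / 60.0 + t.second / 3600.0
            )
    zenith = pd.Series(
        {
            d: circular_mean_hours(np.array(h))
            for d, h in sorted(zen.items())
        },
        dtype=float,
    )
    full = pd.RangeIndex(1, period_days + 1, name="day")
    return AveragedLunarCycle(
        grid,
        low_tides,
        low_level.reindex(full),
        zenith.reindex(full),
    )


def moontides_filter(
    series: pd.Series,
    tide_events: pd.DataFrame,
    halfwidth: pd.Timedelta | str = "2h",
) -> pd.Series:
    """Restrict light visibility to windows around low tide.

    Values outside ``[low - halfwidth, low + halfwidth]`` of every low-tide
    instant are set to zero (the "moon x tides 4-h" construction for the
    default 2-h halfwidth).
    """
    hw = pd.Timedelta(halfwidth)
    if hw <= pd.Timedelta(0):
        raise ValueError("halfwidth must be positive")
    lows = pd.DatetimeIndex(
        tide_events.loc[tide_events["kind"] == "low", "time"]
    ).sort_values()
    if len(lows) == 0:
        raise ValueError("no low-tide events supplied")
    t = series.index.values
    pos = np.searchsorted(lows.values, t)
    dist = np.full(len(t), np.inf)
    left = pos > 0
    dist[left] = np.minimum(
        dist[left],
        np.abs(t[left] - lows.values[pos[left] - 1]) / np.timedelta64(1, "s"),
    )
    right = pos < len(lows)
    dist[right] = np.minimum(
        dist[right],
        np.abs(lows.values[pos[right]] - t[right]) / np.timedelta64(1, "s"),
    )
    out = series.copy()
    out[dist > hw.total_seconds()] = 0.0
    return out
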