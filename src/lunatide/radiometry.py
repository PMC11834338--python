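"""Preprocessing of hyperspectral irradiance time series.

Mirrors the treatment of submerged-radiometer recordings from the
intertidal: 5-min spectra (mW m^-2 nm^-1, 317-953 nm) are averaged into
30-min intervals, summed into 100-nm wavelength bands, split empirically
into day and night by an intensity threshold, and folded into lunar-cycle
(day-in-cycle x clock-time) grids for actogram-style heatmaps.

In-memory conventions: a spectral series is a DataFrame with a
DatetimeIndex and float wavelength columns (nm); a band series is a
DataFrame with interval-labelled columns ("300-399", "400-499", ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "DielGrid",
    "preprocess",
    "day_night_split",
    "night_window",
    "fold_grid",
    "normalize_bands",
    "DEFAULT_NIGHT_THRESHOLD",
]

#: Highest band intensity observed in the middle of the night of the field
#: recordings (mW m^-2 nm^-1, on a full-moon night); values above it are
#: daylight.  Exposed as a default, not hard-coded into the split.
DEFAULT_NIGHT_THRESHOLD = 0.06


@dataclass
class DielGrid:
    """Day-in-cycle x clock-time grid of averaged values.

    ``values``: DataFrame indexed by clock time (minutes since midnight,
    bin start) with columns day-in-cycle 1..P; mean per cell over all
    contributing cycles.  ``counts`` holds the per-cell sample count
    (0 where no cycle contributed; the value there is NaN).
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    period_days: int

    @property
    def day_axis(self) -> np.ndarray:
        return self.values.columns.to_numpy()

    @property
    def clock_minutes(self) -> np.ndarray:
        return self.values.index.to_numpy()


def preprocess(
    spectral: pd.DataFrame,
    average: str = "30min",
    band_nm: int = 100,
) -> pd.DataFrame:
    """Average spectra in time and sum them into wavelength bands.

    Raw values are averaged over ``average`` windows, then summed within
    each ``band_nm``-wide wavelength band aligned to multiples of
    ``band_nm`` (300-399, 400-499, ...).
    """
    if spectral.empty:
        raise ValueError("empty spectral series")
    wl = np.asarray([float(c) for c in spectral.columns])
    averaged = spectral.resample(average).mean()
    edges = (wl // band_nm).astype(int) * band_nm
    out = {}
    for e in np.unique(edges):
        cols = spectral.columns[edges == e]
        out[f"{e}-{e + band_nm - 1}"] = averaged[cols].sum(axis=1)
    return pd.DataFrame(out, index=averaged.index)


def day_night_split(
    band: pd.DataFrame,
    threshold: float = DEFAULT_NIGHT_THRESHOLD,
    per_band: bool = True,
) -> pd.Series:
    """Boolean night mask per time bin: True where intensity is nocturnal.

    With ``per_band`` (default) a bin is night only if *every* band stays
    below the threshold; otherwise the total across bands is compared.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if per_band:
        return (band < threshold).all(axis=1).rename("night")
    return (band.sum(axis=1) < threshold).rename("night")


def night_window(mask: pd.Series) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Typical (dusk, dawn) clock times of the night blocks in a mask.

    Dusk is the modal clock time at which night begins (day->night
    transition), dawn the modal night->day transition; returned as
    timedelta-like clock offsets within the day via Timestamps on an
    arbitrary reference date.
    """
    m = mask.to_numpy(dtype=bool)
    idx = mask.index
    starts = idx[1:][(~m[:-1]) & m[1:]]
    ends = idx[1:][m[:-1] & (~m[1:])]
    if len(starts) == 0 or len(ends) == 0:
        raise ValueError("mask has no day/night transitions")
    ref = pd.Timestamp("2000-01-01")

    def _mode_clock(ts: pd.DatetimeIndex) -> pd.Timestamp:
        mins = ts.hour * 60 + ts.minute
        vals, cnts = np.unique(mins, return_counts=True)
        return ref + pd.Timedelta(minutes=int(vals[np.argmax(cnts)]))

    return _mode_clock(starts), _mode_clock(ends)


def fold_grid(
    series: pd.Series,
    cycle_starts,
    period_days: int = 30,
    bin_minutes: int | None = None,
) -> DielGrid:
    """Fold a time series into an averaged (day-in-cycle x clock) grid.

    ``cycle_starts`` are the Day-1 anchors (e.g. midnights of full-moon
    days).  Each sample is assigned a cycle, a day-in-cycle (1-based) and a
    clock-time bin; cells average all samples sharing (day, clock) across
    cycles.  Days beyond ``period_days`` within a cycle are truncated
    (cycles of 29-30 calendar days fold to a fixed-length grid with
    missing-cell bookkeeping in ``counts``).
    """
    anchors = pd.DatetimeIndex(cycle_starts).sort_values()
    if len(anchors) == 0:
        raise ValueError("no cycle starts given")
    idx = series.index
    if bin_minutes is None:
        bin_minutes = int((idx[1] - idx[0]) / pd.Timedelta(minutes=1))
    pos = np.searchsorted(anchors.values, idx.values, side="right") - 1
    ok = pos >= 0
    day = np.full(len(idx), -1)
    offs = (idx.values[ok] - anchors.values[pos[ok]]) / np.timedelta64(1, "D")
    day[ok] = np.floor(offs).astype(int) + 1
    ok &= (day >= 1) & (day <= period_days)
    if not ok.any():
        raise ValueError("no samples fall inside the given cycles")
    if (day[pos >= 0] > period_days).any():
        warnings.warn(
            f"cycle spacing exceeds {period_days} days; extra days truncated"
        )
    clock = (idx.hour * 60 + idx.minute).to_numpy()
    clock = (clock // bin_minutes) * bin_minutes
    df = pd.DataFrame(
        {
            "day": day[ok],
            "clock": clock[ok],
            "value": series.to_numpy()[ok],
        }
    )
    g = df.groupby(["clock", "day"])["value"]
    values = g.mean().unstack("day")
    counts = g.size().unstack("day")
    full_days = pd.RangeIndex(1, period_days + 1, name="day")
    full_clock = pd.RangeIndex(0, 24 * 60, bin_minutes, name="clock")
    values = values.reindex(index=full_clock, columns=full_days)
    counts = counts.reindex(index=full_clock, columns=full_days).fillna(0)
    return DielGrid(values, counts.astype(int), period_days)


def normalize_bands(
    grids: Mapping[str, DielGrid]
) -> dict[str, DielGrid]:
    """Normalize each band's grid independently by its own maximum.

    Makes faint bands (moonlight) comparable to bright ones across the
    cycle without letting any band dominate the display scale.
    """
    out = {}
    for name, grid in grids.items():
        peak = np.nanmax(grid.values.to_numpy())
        if not np.isfinite(peak) or peak <= 0:
            raise ValueError(f"band {name!r} has no positive values")
        out[name] = DielGrid(
            grid.values / peak, grid.counts.copy(), grid.period_days
        )
    return out
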