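"""Synthetic harmonic tides and tide-event extraction.

Water levels are synthesized as a sum of harmonic constituents
``level(t) = sum_i A_i cos(2 pi t / T_i + phi_i)`` with ``t`` in hours since
J2000 (so constituent phases are anchored in absolute time and presets can
pin a low tide to a calendar instant).  This stands in for observed/reanalysis
water levels; it is deliberately not a full tidal prediction.

Event extraction finds the per-cycle minimum (low tide) and maximum (high
tide) with a sliding-extremum window sized from the dominant period, then
refines each instant by a local parabolic fit — exact for a sampled cosine
and robust to modest noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TideConstituent",
    "CONSTITUENT_PERIODS_H",
    "synth_tide",
    "extract_tide_events",
    "scale_levels",
    "beat_period_days",
    "trough_aligned_constituents",
    "dinard_like",
    "vigo_like",
    "por_like",
    "low_tide_daily_advance_min",
]

_EPOCH = pd.Timestamp("2000-01-01 12:00:00")

#: Periods (hours) of the constituents used here: principal lunar (M2) and
#: solar (S2) semidiurnal, lunisolar (K1) and lunar (O1) diurnal, and the
#: M4 shallow-water overtide responsible for tidal asymmetry.
CONSTITUENT_PERIODS_H = {
    "M2": 12.4206012,
    "S2": 12.0000000,
    "K1": 23.9344697,
    "O1": 25.8193417,
    "M4": 6.2103006,
}


@dataclass(frozen=True)
class TideConstituent:
    """One harmonic constituent: amplitude (m), period (h), phase (rad)."""

    name: str
    period_h: float
    amplitude_m: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("constituent period must be positive")
        if self.amplitude_m < 0:
            raise ValueError("constituent amplitude must be non-negative")


def _hours_since_epoch(idx: pd.DatetimeIndex) -> np.ndarray:
    return (idx - _EPOCH) / pd.Timedelta(hours=1)


def synth_tide(
    constituents: Sequence[TideConstituent],
    start,
    end,
    step: str = "10min",
    noise_sd_m: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Harmonic water-level series on a regular grid (meters)."""
    if not constituents:
        raise ValueError("need at least one tidal constituent")
    if pd.Timedelta(step) <= pd.Timedelta(0):
        raise ValueError("step must be positive")
    idx = pd.date_range(start, end, freq=step)
    t = _hours_since_epoch(idx)
    level = np.zeros(len(idx))
    for c in constituents:
        level += c.amplitude_m * np.cos(
            2 * np.pi * t / c.period_h + c.phase_rad
        )
    if noise_sd_m > 0:
        if rng is None:
            raise ValueError("noise requested but no rng supplied")
        level = level + rng.normal(0.0, noise_sd_m, len(level))
    return pd.Series(level, index=idx, name="level_m")


def beat_period_days(period1_h: float, period2_h: float) -> float:
    """Spring-neap (envelope) period of two constituents, in days.

    For M2 + S2 this is the semilunar ~14.77 days.
    """
    f1, f2 = 1.0 / period1_h, 1.0 / period2_h
    return 1.0 / abs(f1 - f2) / 24.0


# --------------------------------------------------------------------------
# presets


def trough_aligned_constituents(
    spec: Iterable[tuple[str, float]], low_at
) -> list[TideConstituent]:
    """Constituents phased so every constituent has a trough at ``low_at``.

    Aligning all troughs puts a spring low tide exactly at the reference
    instant; with an M4 overtide included, in-phase alignment also deepens
    and sharpens the lows relative to the highs, the asymmetry typical of
    shallow coastal seas.
    """
    t0 = float(_hours_since_epoch(pd.DatetimeIndex([pd.Timestamp(low_at)]))[0])
    out = []
    for name, amp in spec:
        T = CONSTITUENT_PERIODS_H[name]
        phase = (np.pi - 2 * np.pi * t0 / T) % (2 * np.pi)
        out.append(TideConstituent(name, T, amp, phase))
    return out


#: Default full-moon anchor for the presets: midnight (UTC) of the November
#: 2013 full-moon date, the configuration of the Dinard field recordings.
DEFAULT_FULL_MOON_MIDNIGHT = pd.Timestamp("2013-11-17 00:00:00")

#: Macrotidal Channel-like amplitudes: M2 + S2 with an M4 overtide.
_PRESET_AMPLITUDES = (("M2", 3.5), ("S2", 1.2), ("M4", 0.45))


def _preset(low_at, offset_days: float) -> list[TideConstituent]:
    t = pd.Timestamp(low_at) + pd.Timedelta(days=offset_days)
    return trough_aligned_constituents(_PRESET_AMPLITUDES, t)


def dinard_like(low_at=DEFAULT_FULL_MOON_MIDNIGHT) -> list[TideConstituent]:
    """Spring low tide at midnight of a full-moon date (Dinard's situation)."""
    return _preset(low_at, 0.0)


def vigo_like(low_at=DEFAULT_FULL_MOON_MIDNIGHT) -> list[TideConstituent]:
    """Midnight low tide a few days after full moon (Vigo's situation)."""
    return _preset(low_at, 4.0)


def por_like(low_at=DEFAULT_FULL_MOON_MIDNIGHT) -> list[TideConstituent]:
    """Midnight low tide a few days before full moon (Port-en-Bessin)."""
    return _preset(low_at, -4.0)


# --------------------------------------------------------------------------
# event extraction


def _dominant_period_h(series: pd.Series) -> float:
    """Dominant tidal period from the series autocorrelation."""
    x = series.to_numpy(dtype=float)
    x = x - x.mean()
    n = len(x)
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    acf = acf / acf[0]
    step_h = (series.index[1] - series.index[0]) / pd.Timedelta(hours=1)
    # first zero crossing, then the acf peak within the next period
    below = np.nonzero(acf < 0)[0]
    if len(below) == 0:
        raise ValueError("series too short to estimate a tidal period")
    z = below[0]
    hi = min(len(acf), 4 * z)
    lag = z + int(np.argmax(acf[z:hi]))
    return lag * step_h


def extract_tide_events(
    series: pd.Series, period_h: float | None = None, smooth: bool = True
) -> pd.DataFrame:
    """Low/high tide events from a water-level series.

    Low tide is the minimum, high tide the maximum water level within each
    tidal cycle.  Returns a DataFrame with columns ``time`` (refined
    instant), ``kind`` ("low"/"high") and ``level_m``, in time order with
    lows and highs alternating.  A series shorter than one tidal cycle
    yields an empty frame with a warning.

    ``smooth`` applies a centered rolling mean of ~1/6 of the tidal
    period before locating extrema, which keeps measurement noise from
    displacing the flat cosine extrema; a centered window leaves the
    extremum times of a symmetric harmonic unchanged.  On by default.
    """
    idx = series.index
    step = idx[1] - idx[0]
    step_h = step / pd.Timedelta(hours=1)
    if period_h is None:
        try:
            period_h = _dominant_period_h(series)
        except ValueError:
            warnings.warn("series shorter than one tidal cycle; no events")
            return pd.DataFrame(columns=["time", "kind", "level_m"])
    if len(series) * step_h < period_h:
        warnings.warn("series shorter than one tidal cycle; no events")
        return pd.DataFrame(columns=["time", "kind", "level_m"])
    if smooth:
        win = max(3, int(round(period_h / 6.0 / step_h)) | 1)
        series = series.rolling(win, center=True, min_periods=1).mean()
    x = series.to_numpy(dtype=float)

    half = max(int(round(period_h / 2.0 / step_h)) - 1, 1)
    events: list[tuple[int, str]] = []
    for kind, sgn in (("low", 1.0), ("high", -1.0)):
        y = sgn * x
        cand = []
        i = half
        while i < len(y) - half:
            lo = y[i - half : i + half + 1].min()
            if y[i] <= lo + 1e-12:
                # plateau-safe: take the window argmin once per window
                j = i - half + int(np.argmin(y[i - half : i + half + 1]))
                if not cand or j - cand[-1] > half:
                    cand.append(j)
                i = j + half
            else:
                i += 1
        events.extend((j, kind) for j in cand)
    events.sort()

    # enforce alternation: within a same-kind run keep the most extreme
    kept: list[tuple[int, str]] = []
    for j, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (
                x[j] < x[prev] if kind == "low" else x[j] > x[prev]
            )
            if better:
                kept[-1] = (j, kind)
        else:
            kept.append((j, kind))

    rows = []
    for j, kind in kept:
        t, lvl = _refine_extremum(idx, x, j)
        rows.append({"time": t, "kind": kind, "level_m": lvl})
    return pd.DataFrame(rows, columns=["time", "kind", "level_m"])


def _refine_extremum(
    idx: pd.DatetimeIndex, x: np.ndarray, j: int
) -> tuple[pd.Timestamp, float]:
    """Parabolic sub-sample refinement of an extremum at index ``j``."""
    if j == 0 or j == len(x) - 1:
        return idx[j], float(x[j])
    y0, y1, y2 = x[j - 1], x[j], x[j + 2 - 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-15:
        return idx[j], float(x[j])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = idx[1] - idx[0]
    t = idx[j] + delta * step
    lvl = y1 - 0.25 * (y0 - y2) * delta
    return t.round("s"), float(lvl)


def scale_levels(series: pd.Series) -> pd.Series:
    """Affine rescale of water levels to [-1, 1] (min -> -1, max -> +1)."""
    x = series.to_numpy(dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise ValueError("cannot scale a constant water-level series")
    return pd.Series(
        2.0 * (x - lo) / (hi - lo) - 1.0, index=series.index, name="scaled"
    )


def low_tide_daily_advance_min(events: pd.DataFrame) -> float:
    """Mean day-to-day clock-time advance of low tides, in minutes.

    For a semidiurnal tide, pairs each low with the low one lunar day
    (~two tidal cycles) later; the mean excess over 24 h is the daily
    advance (~48 min for a 12.4-h tide).
    """
    lows = events.loc[events["kind"] == "low", "time"].reset_index(drop=True)
    if len(lows) < 3:
        raise ValueError("need at least three low tides")
    gaps = (lows[2:].to_numpy() - lows[:-2].to_numpy()) / np.timedelta64(1, "m")
    return float(np.mean(gaps) - 24 * 60)
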