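"""Parametric artificial-moonlight schedules for entrainment experiments.

All programs live on a zeitgeber-time (ZT) clock under a 16:8 light-dark
cycle with ZT0 defined as the *middle of the dark phase* (the convention of
the experiments; note this differs from the common ZT0 = lights-on).  The
dark phase therefore spans ZT20-ZT4.

Internally a program is a list of moonlight pulses on an absolute hour
axis, with hour 0 = dawn (ZT4) of Day 1; day ``d`` covers absolute hours
``[24(d-1), 24d)``.  This keeps pulses that cross midnight or drift across
the photophase well-defined; rendering to a minute-resolution schedule
restores the conventional ZT clock and flags the night-visible part.

The four experimental regimes:

* ``standard_program`` — full 8-h nights of moonlight on nights 1-4 of a
  30-day cycle.
* ``window_program`` — the same scaffold restricted to a 2-h or 4-h ZT
  window within the dark phase.
* ``shifting_block_program`` — a 2/4/6-h block advancing 48 min per day
  (the 24.8-h lunar day): 30 moonlit nights in a 31-day cycle.
* ``natural_moon_program`` — nightly half-sine pulses whose peak advances
  48 min per day, scaled by a raised-cosine 30-day lunar envelope with
  full moon on Day 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZTConvention",
    "LightPulse",
    "LightProgram",
    "standard_program",
    "window_program",
    "shifting_block_program",
    "natural_moon_program",
    "DAILY_SHIFT_MIN",
]

#: Daily advance of moonrise/moonset and of the tides (minutes), from the
#: 24.8-h lunar day.
DAILY_SHIFT_MIN = (24.8 - 24.0) * 60.0


@dataclass(frozen=True)
class ZTConvention:
    """Light-dark frame: ZT0 = middle of the dark phase."""

    light_hours: float = 16.0

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours

    @property
    def dark_start_zt(self) -> float:
        """Dark onset on the ZT clock (ZT20 for 16:8)."""
        return 24.0 - self.dark_hours / 2.0

    @property
    def dark_end_zt(self) -> float:
        """Dark offset, unwrapped past 24 (ZT28 == ZT4 for 16:8)."""
        return 24.0 + self.dark_hours / 2.0


@dataclass(frozen=True)
class LightPulse:
    """One moonlight pulse on the absolute hour axis (0 = Day-1 dawn)."""

    start_h: float
    end_h: float
    peak: float
    profile: str = "constant"  # or "half-sine"

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("pulse must have positive duration")
        if self.peak < 0:
            raise ValueError("pulse intensity must be non-negative")
        if self.profile not in ("constant", "half-sine"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def midpoint_h(self) -> float:
        return 0.5 * (self.start_h + self.end_h)


@dataclass
class LightProgram:
    """A periodic moonlight schedule over a 30- or 31-day cycle."""

    cycle_days: int
    pulses: list[LightPulse]
    zt: ZTConvention = field(default_factory=ZTConvention)
    name: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def cycle_hours(self) -> float:
        return 24.0 * self.cycle_days

    def moonlit_nights(self) -> int:
        """Number of moonlight presentations per cycle."""
        return sum(1 for p in self.pulses if p.peak > 0)

    def onsets_h(self) -> np.ndarray:
        """Pulse onset times on the absolute hour axis, sorted."""
        return np.sort([p.start_h for p in self.pulses if p.peak > 0])

    def lit_hours(self) -> float:
        """Total pulse duration per cycle (hours)."""
        return float(sum(p.end_h - p.start_h for p in self.pulses))

    def intensity_at(self, abs_hours: np.ndarray) -> np.ndarray:
        """Intensity at absolute hours (wrapped into the cycle)."""
        h = np.asarray(abs_hours, dtype=float) % self.cycle_hours
        out = np.zeros_like(h)
        for p in self.pulses:
            for shift in (-self.cycle_hours, 0.0, self.cycle_hours):
                s, e = p.start_h + shift, p.end_h + shift
                m = (h >= s) & (h < e)
                if not m.any():
                    continue
                if p.profile == "constant":
                    out[m] = np.maximum(out[m], p.peak)
                else:
                    out[m] = np.maximum(
                        out[m],
                        p.peak * np.sin(np.pi * (h[m] - s) / (e - s)),
                    )
        return out

    def schedule(self, step_min: int = 1) -> pd.DataFrame:
        """Minute-resolution table: day, zt hours, intensity, night_visible.

        ``zt`` is the conventional clock in [0, 24); ``night_visible``
        flags bins inside the dark phase (moonlight during the photophase
        is emitted but masked by daylight).
        """
        n = int(self.cycle_hours * 60 / step_min)
        abs_h = np.arange(n) * step_min / 60.0
        day = (abs_h // 24).astype(int) + 1
        zt = (abs_h % 24.0 + 4.0) % 24.0  # hour 0 == ZT4 (dawn)
        dark = ((abs_h % 24.0) >= self.zt.dark_start_zt - 4.0) & (
            (abs_h % 24.0) < self.zt.dark_end_zt - 4.0
        )
        return pd.DataFrame(
            {
                "day": day,
                "zt": zt,
                "intensity": self.intensity_at(abs_h),
                "night_visible": dark,
            }
        )


def _zt_to_abs(day: int, zt_unwrapped: float) -> float:
    """(day, unwrapped ZT in [4, 28)) -> absolute hour (0 = Day-1 dawn)."""
    return 24.0 * (day - 1) + (zt_unwrapped - 4.0)


def _unwrap_zt(zt: float) -> float:
    """ZT clock value -> unwrapped [4, 28) frame (ZT0-ZT4 map past 24)."""
    z = zt % 24.0
    return z + 24.0 if z < 4.0 else z


def standard_program(
    intensity: float = 1.0, cycle_days: int = 30, zt: ZTConvention | None = None
) -> LightProgram:
    """Historical standard: whole-night (8-h) moonlight on nights 1-4.

    Day 1 is the first day moonlight is provided; nights 5-30 are dark.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    zt = zt or ZTConvention()
    pulses = [
        LightPulse(
            _zt_to_abs(d, zt.dark_start_zt),
            _zt_to_abs(d, zt.dark_end_zt),
            intensity,
        )
        for d in range(1, 5)
    ]
    return LightProgram(cycle_days, pulses, zt, name="standard")


def window_program(
    start_zt: float,
    duration_h: float,
    intensity: float = 1.0,
    cycle_days: int = 30,
    zt: ZTConvention | None = None,
) -> LightProgram:
    """Moonlight restricted to a ZT window on nights 1-4.

    The window must lie entirely within the dark phase (ZT20-ZT4);
    ``start_zt`` accepts 20-24 or 0-4 (24 == 0).  Raises ``ValueError``
    for windows reaching into the photophase.
    """
    zt = zt or ZTConvention()
    s = _unwrap_zt(start_zt)
    e = s + duration_h
    if s < zt.dark_start_zt or e > zt.dark_end_zt:
        raise ValueError(
            f"window ZT{start_zt}+{duration_h}h exceeds the dark phase "
            f"(ZT{zt.dark_start_zt}-ZT{zt.dark_end_zt - 24.0})"
        )
    pulses = [
        LightPulse(_zt_to_abs(d, s), _zt_to_abs(d, e), intensity)
        for d in range(1, 5)
    ]
    return LightProgram(
        cycle_days, pulses, zt, name=f"window_ZT{start_zt}_{duration_h}h"
    )


def shifting_block_program(
    duration_h: float,
    intensity: float = 1.0,
    shift_min: float = DAILY_SHIFT_MIN,
    zt: ZTConvention | None = None,
) -> LightProgram:
    """A block of light advancing ``shift_min`` per day (lunar-day cycle).

    With the 48-min daily shift, 30 shifts add up to a full 24 h, so the
    onset clock time first recurs after 31 days: one cycle holds 30
    moonlit nights.  Day 1 is the day the block's midpoint falls at ZT0.
    """
    if not 0 < duration_h < 24:
        raise ValueError("duration must be in (0, 24) hours")
    zt = zt or ZTConvention()
    spacing = 24.0 + shift_min / 60.0
    n_lights = int(round(24.0 * 60.0 / shift_min))  # 30 for 48 min
    cycle_days = int(round(n_lights * spacing / 24.0))  # 31 for 48 min
    mid0 = _zt_to_abs(1, 24.0)  # Day-1 ZT0
    pulses = [
        LightPulse(
            mid0 + k * spacing - duration_h / 2.0,
            mid0 + k * spacing + duration_h / 2.0,
            intensity,
        )
        for k in range(n_lights)
    ]
    return LightProgram(
        cycle_days, pulses, zt, name=f"shifting_{duration_h}h",
        meta={"shift_min": shift_min},
    )


def natural_moon_program(
    width_h: float,
    peak_intensity: float,
    cycle_days: int = 30,
    zt: ZTConvention | None = None,
) -> LightProgram:
    """Simulated natural moonlight: nightly half-sine under a lunar envelope.

    Each day carries one half-sine pulse of ``width_h`` whose peak clock
    time advances 48 min per day; the nightly peak intensity follows a
    raised-cosine envelope over the 30-day cycle with its maximum (full
    moon) on Day 1 and zero near Day 16 (new moon).  Day 1 is anchored
    with the peak at ZT0.

    The 48-min shift is fitted to the 30-day frame by computing each day's
    peak clock time modulo 24 h within that day (30 shifts of 48 min close
    a full day, so the program is exactly 30-day periodic); around new
    moon the drifting peak crosses the photophase, where the envelope is
    near zero and daylight masks it anyway.
    """
    if peak_intensity <= 0:
        raise ValueError("peak intensity must be positive")
    zt = zt or ZTConvention()
    pulses = []
    for d in range(1, cycle_days + 1):
        env = 0.5 * (1.0 + np.cos(2 * np.pi * (d - 1) / cycle_days))
        clock = (20.0 + (d - 1) * 0.8) % 24.0  # Day-1 midpoint at ZT0
        mid = 24.0 * (d - 1) + clock
        pulses.append(
            LightPulse(
                mid - width_h / 2.0,
                mid + width_h / 2.0,
                peak_intensity * float(env),
                profile="half-sine",
            )
        )
    return LightProgram(
        cycle_days, pulses, zt, name=f"natural_{width_h}h",
        meta={"peak_intensity": peak_intensity},
    )
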