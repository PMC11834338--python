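"""Tidal gating of moonlight and lunar-cycle averaging."""

import numpy as np
import pandas as pd
import pytest

from lunatide import ephemeris as eph
from lunatide import tides
from lunatide import underwater as uw


class TestModulate:
    def test_constant_midrange_water_gives_zero(self, dinard_moon):
        idx = dinard_moon.instants
        # water oscillating symmetrically: scaled midrange = 0 at mean level
        tide = pd.Series(
            np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0), index=idx
        )
        out = uw.modulate(dinard_moon.series, tide)
        # at every instant where scaled level is 0 or positive: no light
        scaled = tides.scale_levels(tide)
        assert (out[scaled >= 0] == 0).all()

    def test_spring_low_at_zenith_transmits_fully(self, dinard_moon, dinard_tide):
        out = uw.modulate(dinard_moon.series, dinard_tide)
        # at the anchored spring low (scaled = -1) the moon value passes
        t = dinard_tide.idxmin()
        assert out[t] == pytest.approx(
            float(dinard_moon.series[t]), abs=1e-9
        )

    def test_dinard_preset_shortens_nightly_moonlight(
        self, dinard_moon, dinard_underwater, run_hours
    ):
        # in-land moonlight > 12 h on the full-moon night; tidally gated
        # underwater moonlight only 4-6 h
        inland = dinard_moon.series["2013-11-16 12:00":"2013-11-17 12:00"]
        assert run_hours(inland.to_numpy() > 0, 10) > 12.0
        night = dinard_underwater["2013-11-16 12:00":"2013-11-17 12:00"]
        stretch = run_hours(night.to_numpy() > 0, 10)
        assert 4.0 <= stretch <= 6.0

    def test_monotone_attenuation(self, dinard_moon, dinard_tide):
        # raising the water level never increases underwater intensity
        out = uw.modulate(dinard_moon.series, dinard_tide)
        raised = dinard_tide + 0.5 * (dinard_tide.max() - dinard_tide)
        out_hi = uw.modulate(dinard_moon.series, raised)
        # same scaling range endpoints: compare on common support
        assert (out_hi <= out + 1e-9).all()

    def test_literal_convention_signs(self, dinard_moon, dinard_tide):
        lit = uw.modulate(dinard_moon.series, dinard_tide, convention="literal")
        assert (lit < 0).any()  # bright moon at high tide goes negative
        with pytest.raises(ValueError):
            uw.modulate(dinard_moon.series, dinard_tide, convention="bogus")

    def test_disjoint_ranges_rejected(self, dinard_moon):
        idx = pd.date_range("2020-01-01", periods=10, freq="10min")
        tide = pd.Series(np.sin(np.arange(10.0)), index=idx)
        with pytest.raises(ValueError, match="overlap"):
            uw.modulate(dinard_moon.series, tide)


class TestFoldLunar:
    def test_single_cycle_fold_is_identity_on_grid(
        self, dinard_underwater, november_full_moons, dinard_tide_events
    ):
        cyc = uw.fold_lunar(
            dinard_underwater,
            november_full_moons,
            tide_events=dinard_tide_events,
        )
        anchor = november_full_moons[0].normalize()
        sub = dinard_underwater[anchor : anchor + pd.Timedelta(days=1)]
        # day-1 column equals the raw day-1 values (one contributing cycle)
        col = cyc.grid.values[1].dropna()
        np.testing.assert_allclose(
            col.to_numpy()[: len(sub)], sub.to_numpy()[: len(col)], atol=1e-9
        )

    def test_grid_peak_near_full_moon_midnight(
        self, dinard_underwater, november_full_moons, dinard_tide_events
    ):
        cyc = uw.fold_lunar(
            dinard_underwater,
            november_full_moons,
            tide_events=dinard_tide_events,
        )
        per_day = cyc.grid.values.max(axis=0)
        assert int(per_day.idxmax()) <= 2  # within a day of full moon

    def test_low_tide_drift_matches_lunar_day(
        self, dinard_underwater, november_full_moons, dinard_tide_events
    ):
        cyc = uw.fold_lunar(
            dinard_underwater,
            november_full_moons,
            tide_events=dinard_tide_events,
        )
        r0 = (
            cyc.low_tides[cyc.low_tides["rank"] == 0]
            .sort_values("day")["clock_h"]
            .to_numpy()
        )
        # advance on the semidiurnal (12.42-h) dial: the rank-0 label hops
        # to the companion low when one crosses midnight, so day-to-day
        # differences are meaningful modulo half a lunar day
        drift = np.diff(r0) % (tides.CONSTITUENT_PERIODS_H["M2"])
        assert (drift > 0.2).all() and (drift < 1.6).all()
        assert np.mean(drift) * 60 == pytest.approx(50.0, abs=10.0)

    def test_no_full_moons_rejected(self, dinard_underwater):
        with pytest.raises(ValueError, match="full moon"):
            uw.fold_lunar(dinard_underwater, [])


class TestMoontidesFilter:
    def test_blocks_limited_to_4h(
        self, dinard_underwater, dinard_tide_events, run_hours
    ):
        filt = uw.moontides_filter(
            dinard_underwater, dinard_tide_events, "2h"
        )
        # no contiguous positive stretch can exceed the 4-h gate (the
        # window endpoints are sample-inclusive: allow one 10-min bin)
        assert run_hours(filt.to_numpy() > 0, 10) <= 4.0 + 10.0 / 60.0

    def test_infinite_halfwidth_is_identity(
        self, dinard_underwater, dinard_tide_events
    ):
        filt = uw.moontides_filter(
            dinard_underwater, dinard_tide_events, pd.Timedelta(days=400)
        )
        np.testing.assert_allclose(
            filt.to_numpy(), dinard_underwater.to_numpy()
        )

    def test_zero_outside_windows(
        self, dinard_underwater, dinard_tide_events
    ):
        filt = uw.moontides_filter(dinard_underwater, dinard_tide_events, "2h")
        lows = pd.DatetimeIndex(
            dinard_tide_events.loc[
                dinard_tide_events["kind"] == "low", "time"
            ]
        )
        t = filt.index.values
        dist = np.min(
            np.abs(t[:, None] - lows.values[None, :]), axis=1
        ) / np.timedelta64(1, "h")
        assert (filt.to_numpy()[dist > 2.001] == 0).all()

    def test_requires_low_events(self, dinard_underwater):
        empty = pd.DataFrame(columns=["time", "kind", "level_m"])
        with pytest.raises(ValueError, match="low-tide"):
            uw.moontides_filter(dinard_underwater, empty)


class TestGeographicPhase:
    def test_tide_phase_shift_moves_availability_day(self, dinard_moon):
        # shifting the tide preset by +4 days moves the lunar-cycle day of
        # mid-night moonlight availability accordingly (the three-site
        # contrast reproduced qualitatively)
        span = ("2013-11-03", "2013-12-05")
        fm = eph.full_moons(*span)
        days = {}
        for name, preset in (("dinard", tides.dinard_like), ("vigo", tides.vigo_like)):
            tide = tides.synth_tide(preset(), *span, "10min")
            u = uw.modulate(dinard_moon.series, tide)
            cyc = uw.fold_lunar(u, fm)
            # day whose midnight-window (23:00-01:00) intensity is largest
            g = cyc.grid.values
            mid = g.loc[[0, 10, 20, 30, 40, 50, 1380, 1390, 1400, 1410, 1420, 1430]]
            days[name] = int(mid.mean(axis=0).idxmax())
        shift = (days["vigo"] - days["dinard"]) % 30
        assert 2 <= shift <= 6  # ~4-day phase offset propagates
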