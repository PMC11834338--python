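"""Shared fixtures: the Dinard-like autumn-2013 configuration.

Everything is generated at run time from the package's own ephemeris,
tide presets and synthetic generators; session scope keeps the ephemeris
evaluations from being repeated across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from lunatide import ephemeris as eph
from lunatide import tides
from lunatide import underwater as uw

SPAN = ("2013-11-03", "2013-12-05")  # one lunar month around the Nov full moon


@pytest.fixture(scope="session")
def dinard():
    return eph.SITES["dinard"]


@pytest.fixture(scope="session")
def dinard_moon(dinard):
    idx = pd.date_range(*SPAN, freq="10min")
    return eph.relative_moonlight(idx, dinard)


@pytest.fixture(scope="session")
def dinard_tide():
    return tides.synth_tide(tides.dinard_like(), *SPAN, "10min")


@pytest.fixture(scope="session")
def dinard_tide_events(dinard_tide):
    return tides.extract_tide_events(dinard_tide)


@pytest.fixture(scope="session")
def dinard_underwater(dinard_moon, dinard_tide):
    return uw.modulate(dinard_moon.series, dinard_tide)


@pytest.fixture(scope="session")
def november_full_moons():
    return eph.full_moons(*SPAN)


def longest_true_run_hours(flags: np.ndarray, step_minutes: float) -> float:
    """Length in hours of the longest contiguous run of True."""
    best = run = 0
    for f in np.asarray(flags, dtype=bool):
        run = run + 1 if f else 0
        best = max(best, run)
    return best * step_minutes / 60.0


@pytest.fixture(scope="session")
def run_hours():
    return longest_true_run_hours
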