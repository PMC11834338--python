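"""Synthetic data generators for every pipeline stage.

Two generators provide test inputs with the statistical structure the
analysis assumes, without any external data:

* ``gen_emergence`` draws individual emergence days from a von Mises
  mixture on the P-day circle (any member of the ten-model family) and
  tabulates daily counts per strain/replicate/cycle — the synthetic
  counterpart of a laboratory emergence table.
* ``gen_radiometer`` builds a 5-min hyperspectral irradiance matrix
  (317-953 nm) with a broad daylight term following the sun, a faint
  moonlight term confined to 400-700 nm and gated by the tidal water
  column, and a noise floor — the synthetic counterpart of a submerged
  radiometer recording.

All randomness flows through one explicit ``numpy.random.Generator``; the
same seed reproduces the same tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephemeris import GeoLocation, sun_altitude
from .rhythm import MODELS, _TWO_PI
from .tides import scale_levels

__all__ = [
    "EmergenceGenSpec",
    "RadiometerGenSpec",
    "gen_emergence",
    "gen_radiometer",
]


@dataclass(frozen=True)
class EmergenceGenSpec:
    """Generating mixture for synthetic emergence counts.

    Phases are given in day-in-cycle (1..P, matching the reporting
    convention); ``lam`` is the weight of the first mode.  The generating
    ``model`` must be one of the ten family ids; parameters that the model
    fixes (e.g. the antipodal phi2 of M3A) are derived, not read.
    """

    model: str = "M2A"
    phi1_day: float = 1.0
    kappa1: float = 3.0
    phi2_day: float | None = None
    kappa2: float | None = None
    lam: float = 1.0
    period_days: int = 30
    individuals_per_cycle: int = 500
    replicates: int = 3
    cycles: int = 2
    strain: str = "SYN"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.individuals_per_cycle <= 0:
            raise ValueError("need a positive number of individuals")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")

    def full_params(self) -> dict:
        """Resolve to (mu1, kappa1, mu2, kappa2, lam) in radians."""
        spec = MODELS[self.model]
        p = self.period_days
        mu1 = _TWO_PI * (self.phi1_day - 1) / p
        if spec.axial:
            mu2 = mu1 + np.pi
        elif spec.shared_mu or self.phi2_day is None:
            mu2 = mu1
        else:
            mu2 = _TWO_PI * (self.phi2_day - 1) / p
        k2 = (
            self.kappa1
            if spec.shared_kappa
            else (self.kappa2 if self.kappa2 is not None else 0.0)
        )
        lam = spec.fixed_lam if spec.fixed_lam is not None else self.lam
        if spec.second == "none":
            lam = 1.0
        return {
            "mu1": mu1 % _TWO_PI,
            "kappa1": self.kappa1,
            "mu2": mu2 % _TWO_PI,
            "kappa2": k2,
            "lam": lam,
        }


def _draw_vonmises(
    rng: np.random.Generator, mu: float, kappa: float, n: int
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if kappa < 1e-9:
        return rng.uniform(0.0, _TWO_PI, n)
    return rng.vonmises(mu, kappa, n) % _TWO_PI


def gen_emergence(
    spec: EmergenceGenSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Synthetic emergence table: strain, replicate, cycle, day, count.

    For each cycle, ``individuals_per_cycle`` emergence angles are drawn
    from the mixture (component per individual, then von Mises or uniform
    within the component), binned to days at the bin centers
    (day = round(theta / (2 pi / P)) + 1), and allocated uniformly at
    random over replicates.  The table is dense: every
    (replicate, cycle, day) combination appears, zeros included.
    """
    p = spec.full_params()
    model = MODELS[spec.model]
    P = spec.period_days
    frames = []
    for cyc in range(1, spec.cycles + 1):
        n = spec.individuals_per_cycle
        n1 = rng.binomial(n, p["lam"]) if model.second != "none" else n
        first = _draw_vonmises(rng, p["mu1"], p["kappa1"], n1)
        if model.second == "uniform":
            second = rng.uniform(0.0, _TWO_PI, n - n1)
        elif model.second == "vm":
            second = _draw_vonmises(rng, p["mu2"], p["kappa2"], n - n1)
        else:
            second = np.empty(0)
        theta = np.concatenate([first, second])
        day = (np.round(theta / (_TWO_PI / P)).astype(int) % P) + 1
        rep = rng.integers(1, spec.replicates + 1, len(day))
        df = pd.DataFrame({"replicate": rep, "cycle": cyc, "day": day})
        counts = (
            df.groupby(["replicate", "cycle", "day"]).size().rename("count")
        )
        full = pd.MultiIndex.from_product(
            [range(1, spec.replicates + 1), [cyc], range(1, P + 1)],
            names=["replicate", "cycle", "day"],
        )
        frames.append(counts.reindex(full, fill_value=0).reset_index())
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "strain", spec.strain)
    return out


@dataclass(frozen=True)
class RadiometerGenSpec:
    """Shape of the synthetic hyperspectral recording.

    Intensities are in the radiometer's units (mW m^-2 nm^-1 per
    wavelength sample).  Daylight is broad-band and follows the solar
    elevation; moonlight is confined to ``moon_band_nm`` and is a factor
    ~10^-3 of daylight, gated by the tidal water column (inverted-clamped
    scaled level); the noise floor sits well below moonlight at full moon
    low tide.
    """

    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(317.0, 953.0, 192)
    )
    day_amplitude: float = 2.0
    moon_amplitude: float = 2e-3
    moon_band_nm: tuple[float, float] = (400.0, 700.0)
    noise_floor: float = 1e-5
    step: str = "5min"
    attenuate_daylight: bool = False

    def __post_init__(self) -> None:
        if self.day_amplitude <= 0 or self.moon_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.noise_floor >= self.moon_amplitude:
            raise ValueError("noise floor must sit below the moonlight")


def gen_radiometer(
    spec: RadiometerGenSpec,
    tide: pd.Series,
    moon: pd.Series,
    loc: GeoLocation,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic spectral series over the overlap of tide and moon inputs.

    intensity(t, wl) = daylight(t) * shape(wl)
                     + moon_amplitude * moon(t) * att(t) * band(wl)
                     + noise,
    with att(t) = max(-scaled_level(t), 0), daylight following the clamped
    sine of solar altitude with a broad spectral shape peaking near 550 nm,
    and the moon term confined to the 400-700 nm band.  ``rng=None``
    disables the noise term entirely.
    """
    t0 = max(moon.index[0], tide.index[0])
    t1 = min(moon.index[-1], tide.index[-1])
    if t1 <= t0:
        raise ValueError("tide and moon series do not overlap")
    idx = pd.date_range(t0.ceil(spec.step), t1.floor(spec.step), freq=spec.step)

    def _on_grid(s: pd.Series) -> np.ndarray:
        x = (s.index - s.index[0]) / pd.Timedelta(hours=1)
        xg = (idx - s.index[0]) / pd.Timedelta(hours=1)
        return np.interp(xg, x, s.to_numpy(dtype=float))

    wl = np.asarray(spec.wavelengths_nm, dtype=float)
    day_shape = np.exp(-0.5 * ((wl - 550.0) / 150.0) ** 2)
    lo, hi = spec.moon_band_nm
    moon_band = ((wl >= lo) & (wl <= hi)).astype(float)

    sun = np.clip(
        np.sin(np.radians(sun_altitude(idx, loc))), 0.0, None
    )
    att = np.clip(-_on_grid(scale_levels(tide)), 0.0, None)
    moonv = np.clip(_on_grid(moon), 0.0, None)

    day_t = spec.day_amplitude * sun * (att if spec.attenuate_daylight else 1.0)
    moon_t = spec.moon_amplitude * moonv * att
    mat = np.outer(day_t, day_shape) + np.outer(moon_t, moon_band)
    if rng is not None and spec.noise_floor > 0:
        mat = mat + rng.exponential(spec.noise_floor, mat.shape)
    return pd.DataFrame(mat, index=idx, columns=wl)
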