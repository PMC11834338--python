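# Methods

This note documents the models, conventions, parameter choices and known
limitations of `lunatide`.

## Astronomical model

The ephemeris is a closed-form, low-precision one: solar ecliptic
longitude from the truncated equation-of-center series, lunar ecliptic
longitude/latitude/parallax from the standard low-precision polynomial
series (the Astronomical Almanac's "low accuracy" formulae), sidereal
time from the usual GMST polynomial. Accuracy, verified in the test
suite against frozen almanac anchors: sun altitude to ~0.01°, moon
altitude to a few tenths of a degree, illuminated fraction to ±0.02,
full-moon instants to well under 3 h. This is ample for photoperiod and
moonlight-availability questions, where the quantities of interest are
durations and clock times at 10-min resolution.

Deliberate simplifications:

* Moon altitude is **geocentric and geometric** — no topocentric
  parallax (up to ~1° at the horizon) and no refraction. "Moon up" means
  geometric altitude > 0. This shifts moonrise/moonset by minutes,
  which is below the resolution of the analyses built on it.
* Sunrise/sunset use the conventional −0.83° crossing (solar disk top
  plus mean refraction).
* Full moons are located as the upward crossing of 180° sun–moon
  elongation (equivalently, the maximum of the illuminated fraction),
  bracketed on a 3-h grid and refined by root finding.

Relative in-land moonlight is `illuminated_fraction × max(altitude, 0)`,
normalized to a series maximum of 1. The altitude factor is the clamped
altitude *angle* (the source convention); since the normalization
absorbs any linear rescaling, degrees vs radians is immaterial — a
property the tests assert. What the proxy ignores: atmospheric
extinction at low altitude, the moon's distance variation (±10% in
apparent brightness), and weather.

## Tides

Water levels are synthesized as sums of harmonic constituents with
absolute-time phase anchoring (hours since J2000), so a preset can pin a
spring low tide to a calendar instant. The site-like presets use
M2 = 3.5 m and S2 = 1.2 m — a macrotidal, Channel-like regime with the
semilunar 14.77-day spring–neap beat — plus an **M4 overtide of 0.45 m**
phase-locked to M2 (all troughs aligned at the reference low). The M4
term encodes the tidal asymmetry of shallow coastal seas: it deepens and
sharpens the lows and flattens the highs. This matters for the
underwater light model: a purely symmetric tide sits below its midrange
exactly half of each 12.42-h cycle, which would make moonlight "visible"
for ~6.2 h per night; the observed restriction in macrotidal intertidal
habitats is 4–6 h, and the asymmetric preset reproduces it (~5.5 h).

The three geographic presets differ only in which calendar day carries
the midnight low tide: at the Dinard-like site the spring low falls at
midnight of the full-moon date; the Vigo-like and Port-en-Bessin-like
presets shift that anchor by +4 and −4 days respectively, reproducing
the qualitative three-site contrast (moonlight in the middle of the
night after vs before full moon).

Tide events are per-cycle extrema found by a sliding-extremum window
sized from the dominant period (estimated from the autocorrelation when
not given), after a centered rolling-mean smoothing of ~1/6 period that
suppresses measurement noise without biasing symmetric extrema, followed
by parabolic sub-sample refinement (exact for a sampled cosine). Lows
and highs are forced to alternate; within a same-kind run the more
extreme event wins. Scaling to [−1, 1] is min–max over the whole input
series; a constant series is an error, not a silent zero.

## Underwater moonlight

The simulated underwater series is
`moonlight(t) × max(−scaled_level(t), 0)`. Taken literally, a product
of moonlight with the scaled level itself would *brighten* at high
tide, contradicting the field observation that intensities peak at low
tide, so the inverted-and-clamped factor is the default; the literal
product is retained behind `convention="literal"` for comparison. The
attenuation is an availability weight, not radiative transfer — no
Beer–Lambert water column, turbidity or surface effects.

Lunar cycles are anchored at **midnight (UTC) of the calendar date
containing each full-moon instant**, folded position-wise into a
30-day × clock grid (days beyond 30 are truncated with per-cell count
bookkeeping). Low-tide clock times are averaged across cycles per lunar
day with circular means on the 24-h dial, matching corresponding lows
across cycles by their within-day order (semidiurnal tides have two);
the per-day mean low-tide *level* anchors the spring-tide block. The
moon-zenith time is the circular mean of each day's intensity argmax,
missing on days with no visible moonlight.

The moon × tides filter zeroes the series outside ±2 h (configurable)
around each low tide — the "4-h" data sets used for window matching.

## Light programs

All programs live on a zeitgeber clock with **ZT0 = middle of the dark
phase** of a 16:8 LD cycle (dark ZT20–ZT4). Internally a program is a
pulse list on an absolute hour axis (0 = dawn of Day 1), which keeps
midnight-crossing and drifting pulses exact; schedules render at 1-min
resolution with a `night_visible` flag marking the dark phase (drifting
pulses are emitted even when they cross into the photophase, where
daylight masks them — both the hardware-faithful and the
perception-relevant view are preserved).

* **standard**: nights 1–4 fully lit (8 h), 30-day cycle, Day 1 = first
  lit night.
* **windows**: the same scaffold restricted to a 2-h or 4-h window that
  must lie inside the dark phase.
* **shifting block**: onsets advance 48 min/day (the 24.8-h lunar day);
  30 shifts close a full 24 h, so a cycle is 31 days with 30 moonlit
  nights; Day 1 has the block midpoint at ZT0.
* **natural moonlight**: one half-sine pulse of 4 or 6 h per night whose
  peak clock time advances 48 min/day *computed within each day modulo
  24 h* (30 shifts close the day, making the program exactly 30-day
  periodic), under a raised-cosine lunar envelope with maximum on Day 1
  and zero on Day 16; around new moon the drifting peak crosses the
  photophase where the envelope is near zero, so the wrap is invisible
  in the emitted light. The half-sine integral is (2/π)·width·peak.

The known firmware artifact of the original 6-h high-intensity hardware
(an intensity jump at midnight from per-day recalculation) is *not*
reproduced; the corrected continuous behavior is the default.

## Circular statistics

Daily counts on a P-day cycle map to bin-center angles
θ = 2π(day−1)/P, pooled over replicates and cycles (weights =
counts). The model family is the ten-member von Mises mixture hierarchy
used in animal-orientation statistics (uniform; one mode; axial and
free two-mode combinations with shared or free concentrations and
weights — see the table in `lunatide.rhythm`). Densities use the
exponentially-scaled Bessel function for numerical stability.

Fitting is bounded L-BFGS-B from a deterministic multi-start grid seeded
by the sample's circular moments, plus **warm starts from the embedded
optima of nested submodels** — every model starts (among others) from
the best fit of each model it contains, which guarantees the nesting
inequality (the saturated M5B log-likelihood dominates all others) by
construction and, in practice, finds the same optima as much larger
grids at a fraction of the cost.

Numerical choices:

* κ is bounded at **50**. Unbounded (or very loosely bounded)
  concentrations admit degenerate near-point-mass components — a
  κ-at-the-cap spike with a few percent of the mass can capture a single
  day bin and win the likelihood, the classic unboundedness of mixture
  ML. At P = 30, κ = 50 still describes a peak far sharper than one day
  bin, an order of magnitude above biologically observed emergence
  concentrations.
* Model selection is by AIC = −2 logL + 2k. Models within **2 AIC
  units** of the minimum are treated as equivalent (the conventional
  ΔAIC < 2 band) and the most parsimonious of them is selected; exact
  AIC ties have probability zero, so a parsimony tie-break is only
  meaningful with such a band. Strict lowest-AIC selection is available
  via `tie_tolerance=0`.
* Reported phases follow the convention that φ1 is the fitted peak
  closer to Day 1, rounded to 0.1 day; κs and λ are matched to that
  ordering.

Measured on synthetic generators (n = 500/cycle, κ = 3, 100 seeds per
generator, computed by the test suite): family-level selection accuracy
is 83% for uniform, 86% for unimodal and 100% for antipodal bimodal
generators; M2A phase recovery is within ±0.3 day and concentration
within ±14% in the worst seed. Without the ΔAIC band, flexible
two-mode models whose density is effectively unimodal win by <2 AIC on
roughly a third of unimodal draws — an intrinsic property of AIC, not
of the optimizer.

The **rhythmicity index** normalizes counts within each 30-day cycle to
fractions, concatenates cycles, and evaluates the sample autocorrelation
at a lag equal to the rhythm period — 15 days for semilunar, 30 for
lunar rhythms. (Descriptions of this statistic that quote "lag 16" and
"lag 31" count 1-based positions in an ACF vector whose first element is
lag 0.) Categories: RI > 0.3 highly significant, 0.1–0.3 significant,
otherwise not significant. Cycles with zero total count contribute
zeros rather than NaNs.

## Laboratory-to-field matching

The field photoperiod is summarized by the longest day in the assessment
window (March–October): its light phase rounded to whole hours is the
field LD, and ZT0 is anchored at the middle of that day's dark phase
rounded to the nearest half hour; the laboratory 16:8 frame is laid
around that anchor. For 2017 this yields LD 15:9 at Vigo (ZT0 = 0030
UTC, fitted light phase 0430–2030) and LD 16:8 at Port-en-Bessin
(ZT0 = 0000 UTC, 0400–2000) — computed, not hard-coded.

A ZT window is placed on the run of four consecutive lunar days that
maximizes its summed overlap with tidally-gated moonlight, subject to at
least 2 h of visible moonlight on each of the four nights ("visible" =
above a configurable threshold, default anything positive on the
filtered grid). Night *n* is the dark phase centered on ZT0 of day *n*;
windows and nights wrap around the 30-day cycle. Ties — which the
synthetic presets do not produce — go to the earliest day range in cycle
order. Laboratory emergence histograms are projected onto field days by
the circular shift that maps the treatment's Day 1 to the placement's
first day.

Spring tides are the lunar day with the minimum averaged low-tide level
±2 days (a 5-day block, wrapping). Where descriptions of the procedure
disagree between a 4-day and a 5-day block, the 5-day (±2) definition is
used.

## Synthetic data

The emergence generator draws individual emergence angles from any
member of the mixture family (component choice, then von Mises or
uniform within the component; κ = 0 degenerates exactly to uniform),
bins them to days at the bin centers, and scatters individuals uniformly
over replicate boxes. Counts are exact per cycle (default 500
individuals/cycle, 3 replicates — the scale of a few laboratory boxes of
~250 eggs each). One explicit `numpy.random.Generator` is threaded
through all draws; a seed fixes the output tables bit for bit.

The radiometer generator emits 5-min spectra on the instrument's grid
(192 wavelengths, 317–953 nm): a broad daylight term (Gaussian spectral
shape centered at 550 nm) following the clamped sine of solar altitude,
a moonlight term confined to 400–700 nm at ~10⁻³ of daylight and gated
by the tidal attenuation, and an exponential noise floor of 10⁻⁵ (all in
mW m⁻² nm⁻¹ per wavelength sample). Daylight is *not* tidally
attenuated by default: the clamped attenuation is exactly zero whenever
water is above midrange, and zeroing daylight for half of each day would
destroy the photoperiod that the day/night split is meant to recover;
the flag `attenuate_daylight=True` restores the fully gated variant.

What the generators do not emulate: weather and cloud cover, spectral
attenuation of the water column, moonlight's dependence on lunar
distance, larval development and mortality, and between-replicate
heterogeneity. Passing tests therefore demonstrate the correctness of
the computational chain under the stated statistical structure, not
robustness to every feature of field recordings.

## Problem sizes

The test suite and the acceptance script run everything at the sizes the
analyses were designed for: one lunar month of 10-min series for the
underwater model, eight lunar cycles (March–October 2017) for the
matching procedure, five years of full moons for the synodic-spacing
check, and 100-seed batteries at 500 individuals/cycle for the
statistical properties. The full suite completes in a few minutes on one
CPU.
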