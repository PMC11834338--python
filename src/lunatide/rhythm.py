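"""Circular maximum-likelihood analysis of emergence rhythms.

Daily emergence counts on a P-day cycle are mapped to angles on the circle
(bin centers, theta = 2*pi*(day-1)/P) and fitted by maximum likelihood to
the ten-model family of unimodal/bimodal von Mises mixtures used in animal
orientation statistics (Schnute-Groot hierarchy):

====  =========================================================  ====
id    density                                                    free
====  =========================================================  ====
M1    uniform                                                    0
M2A   VM(phi1, k1)                                               2
M2B   lam VM(phi1, k1) + (1-lam)/2pi                             3
M2C   lam VM(phi1, k1) + (1-lam) VM(phi1, k2)                    4
M3A   axial: phi2 = phi1 + pi, k2 = k1, lam = 1/2                2
M3B   axial with free lam                                        3
M4A   free phi2, k2 = k1, lam = 1/2                              3
M4B   free phi2, k2 = k1, free lam                               4
M5A   free phi2, k2, lam = 1/2                                   4
M5B   all free                                                   5
====  =========================================================  ====

where VM(theta; mu, kappa) = exp(kappa cos(theta - mu)) / (2 pi I0(kappa)).
Models are ranked by AIC = -2 logL + 2 (free parameters); the reported
phi1 is the fitted peak closer to Day 1.

The rhythmicity index (RI) is the sample autocorrelation of cycle-
normalized daily counts at a lag equal to the rhythm period (15 days for
semilunar, 30 for lunar rhythms), categorized at 0.1 / 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import i0e
from statsmodels.tsa.stattools import acf as _acf

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "MODELS",
    "CircularSample",
    "CircFit",
    "RIResult",
    "mixture_loglik",
    "mixture_pdf",
    "fit_model",
    "fit_all",
    "select_model",
    "rhythmicity_index",
    "fits_table",
]

_TWO_PI = 2.0 * np.pi
_KAPPA_MAX = 50.0


@dataclass(frozen=True)
class ModelSpec:
    """One member of the mixture family.

    ``free``: names of the free parameters, a subset of
    (mu1, kappa1, mu2, kappa2, lam).  ``second``: the second component —
    "none" (pure unimodal), "uniform", or "vm".  ``axial`` forces
    mu2 = mu1 + pi; ``shared_kappa`` forces kappa2 = kappa1;
    ``shared_mu`` forces mu2 = mu1 (the M2C two-concentration case);
    ``fixed_lam`` pins the mixing weight.
    """

    id: str
    free: tuple[str, ...]
    second: str = "none"
    axial: bool = False
    shared_kappa: bool = False
    shared_mu: bool = False
    fixed_lam: float | None = None

    @property
    def n_free(self) -> int:
        return len(self.free)

    def expand(self, theta: Sequence[float]) -> dict[str, float]:
        """Free-parameter vector -> full (mu1, kappa1, mu2, kappa2, lam)."""
        p = dict(zip(self.free, theta))
        mu1 = p.get("mu1", 0.0) % _TWO_PI
        k1 = p.get("kappa1", 0.0)
        lam = self.fixed_lam if self.fixed_lam is not None else p.get("lam", 1.0)
        if self.second == "none":
            lam = 1.0
        if self.axial:
            mu2 = (mu1 + np.pi) % _TWO_PI
        elif self.shared_mu:
            mu2 = mu1
        else:
            mu2 = p.get("mu2", (mu1 + np.pi)) % _TWO_PI
        k2 = k1 if self.shared_kappa else p.get("kappa2", 0.0)
        return {"mu1": mu1, "kappa1": k1, "mu2": mu2, "kappa2": k2, "lam": lam}


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", ()),
    "M2A": ModelSpec("M2A", ("mu1", "kappa1")),
    "M2B": ModelSpec("M2B", ("mu1", "kappa1", "lam"), second="uniform"),
    "M2C": ModelSpec(
        "M2C", ("mu1", "kappa1", "kappa2", "lam"), second="vm", shared_mu=True
    ),
    "M3A": ModelSpec(
        "M3A", ("mu1", "kappa1"), second="vm", axial=True,
        shared_kappa=True, fixed_lam=0.5,
    ),
    "M3B": ModelSpec(
        "M3B", ("mu1", "kappa1", "lam"), second="vm", axial=True,
        shared_kappa=True,
    ),
    "M4A": ModelSpec(
        "M4A", ("mu1", "kappa1", "mu2"), second="vm",
        shared_kappa=True, fixed_lam=0.5,
    ),
    "M4B": ModelSpec(
        "M4B", ("mu1", "kappa1", "mu2", "lam"), second="vm", shared_kappa=True
    ),
    "M5A": ModelSpec(
        "M5A", ("mu1", "kappa1", "mu2", "kappa2"), second="vm", fixed_lam=0.5
    ),
    "M5B": ModelSpec(
        "M5B", ("mu1", "kappa1", "mu2", "kappa2", "lam"), second="vm"
    ),
}

MODEL_IDS = tuple(MODELS)


@dataclass
class CircularSample:
    """Angles (radians, [0, 2pi)) with non-negative multiplicities."""

    angles: np.ndarray
    weights: np.ndarray
    period_days: int = 30

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float) % _TWO_PI
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.angles) != len(self.weights):
            raise ValueError("angles and weights differ in length")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if self.n == 0:
            raise ValueError("empty circular sample")

    @property
    def n(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def from_emergence(
        cls, emergence: pd.DataFrame, period_days: int = 30
    ) -> "CircularSample":
        """Pool daily counts over replicates and cycles onto bin centers.

        ``emergence`` columns: strain, replicate, cycle, day, count (extra
        columns ignored).  theta = 2 pi (day - 1) / P.
        """
        counts = emergence.groupby("day")["count"].sum()
        days = counts.index.to_numpy(dtype=float)
        if (days < 1).any() or (days > period_days).any():
            raise ValueError("day outside [1, period_days]")
        return cls(
            _TWO_PI * (days - 1) / period_days,
            counts.to_numpy(dtype=float),
            period_days,
        )

    @classmethod
    def from_angles(
        cls, angles: np.ndarray, period_days: int = 30
    ) -> "CircularSample":
        return cls(np.asarray(angles), np.ones(len(angles)), period_days)


@dataclass
class CircFit:
    """A fitted model: parameters, log-likelihood and AIC.

    ``phi1``/``phi2`` follow the reporting convention that phi1 is the
    mode closer to Day 1 (angle 0); for unimodal models phi2 is None.
    """

    model: str
    params: dict
    loglik: float
    aic: float
    n_free: int
    converged: bool = True

    def _ordered_modes(self) -> tuple[tuple, tuple | None]:
        spec = MODELS[self.model]
        p = self.params
        m1 = (p["mu1"], p["kappa1"], p["lam"])
        if spec.second in ("none", "uniform") or spec.shared_mu:
            return m1, None
        m2 = (p["mu2"], p["kappa2"], 1.0 - p["lam"])
        d1 = min(p["mu1"] % _TWO_PI, _TWO_PI - p["mu1"] % _TWO_PI)
        d2 = min(p["mu2"] % _TWO_PI, _TWO_PI - p["mu2"] % _TWO_PI)
        return (m1, m2) if d1 <= d2 else (m2, m1)

    def _angle_to_day(self, ang: float, period: int) -> float:
        return round((ang % _TWO_PI) / _TWO_PI * period, 1) + 1.0

    def phases_days(self, period_days: int = 30) -> tuple[float, float | None]:
        """(phi1, phi2) as day-in-cycle, phi1 nearest Day 1, 0.1-day grid."""
        m1, m2 = self._ordered_modes()
        p1 = self._angle_to_day(m1[0], period_days)
        p2 = None if m2 is None else self._angle_to_day(m2[0], period_days)
        return p1, p2

    def concentrations(self) -> tuple[float, float | None]:
        """(k1, k2) matched to the phi1/phi2 ordering."""
        m1, m2 = self._ordered_modes()
        return m1[1], None if m2 is None else m2[1]


def _vm_pdf(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # exponentially scaled Bessel keeps kappa up to the 500 cap finite
    return np.exp(kappa * (np.cos(theta - mu) - 1.0)) / (_TWO_PI * i0e(kappa))


def mixture_pdf(theta: np.ndarray, model: str, params: dict) -> np.ndarray:
    """Density of a family member at angles ``theta``."""
    spec = MODELS[model]
    th = np.asarray(theta, dtype=float)
    if model == "M1":
        return np.full_like(th, 1.0 / _TWO_PI)
    lam = params["lam"]
    f = lam * _vm_pdf(th, params["mu1"], params["kappa1"])
    if spec.second == "uniform":
        f = f + (1.0 - lam) / _TWO_PI
    elif spec.second == "vm":
        f = f + (1.0 - lam) * _vm_pdf(th, params["mu2"], params["kappa2"])
    return f


def mixture_loglik(
    sample: CircularSample, model: str, params: dict
) -> float:
    """Weighted log-likelihood of the sample under a family member."""
    if params.get("kappa1", 0.0) < 0 or params.get("kappa2", 0.0) < 0:
        raise ValueError("concentration parameters must be non-negative")
    lam = params.get("lam", 1.0)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("mixing weight must be in [0, 1]")
    f = mixture_pdf(sample.angles, model, params)
    return float(np.sum(sample.weights * np.log(np.maximum(f, 1e-300))))


def _circular_moments(sample: CircularSample) -> tuple[float, float]:
    """Weighted circular mean direction and resultant length."""
    w = sample.weights
    C = float(np.sum(w * np.cos(sample.angles))) / sample.n
    S = float(np.sum(w * np.sin(sample.angles))) / sample.n
    return float(np.arctan2(S, C)) % _TWO_PI, float(np.hypot(C, S))


def _kappa_from_r(r: float) -> float:
    """Banerjee et al. approximation of the ML concentration from R-bar."""
    r = min(max(r, 1e-6), 1 - 1e-9)
    k = r * (2.0 - r * r) / (1.0 - r * r)
    return float(min(k, _KAPPA_MAX))


_BOUNDS = {
    "mu1": (-_TWO_PI, 2 * _TWO_PI),
    "mu2": (-_TWO_PI, 2 * _TWO_PI),
    "kappa1": (0.0, _KAPPA_MAX),
    "kappa2": (0.0, _KAPPA_MAX),
    "lam": (0.0, 1.0),
}


def _default_starts(sample: CircularSample, spec: ModelSpec) -> list[dict]:
    """Deterministic start grid, seeded by the sample's circular moments."""
    mu_hat, r = _circular_moments(sample)
    k_hat = _kappa_from_r(r)
    mus = [mu_hat, (mu_hat + np.pi) % _TWO_PI,
           (mu_hat + np.pi / 2) % _TWO_PI, (mu_hat - np.pi / 2) % _TWO_PI]
    kappas = [max(k_hat, 0.5), 2.0]
    lams = [0.5, 0.75]
    starts = []
    for mu in mus[: 4 if "mu1" in spec.free else 1]:
        for k in kappas:
            base = {"mu1": mu, "kappa1": k, "kappa2": k,
                    "mu2": (mu + np.pi) % _TWO_PI, "lam": 0.5}
            if "lam" in spec.free:
                for lam in lams:
                    starts.append({**base, "lam": lam})
            else:
                starts.append(base)
    return starts


def fit_model(
    sample: CircularSample,
    model: str,
    extra_starts: Sequence[dict] = (),
) -> CircFit:
    """Constrained ML fit of one model by deterministic multi-start.

    Local optimization (L-BFGS-B on the free parameters) from a moment-
    seeded grid plus any ``extra_starts`` (full parameter dicts, e.g. the
    optima of nested submodels).  Non-convergence of every start raises;
    partial convergence is reported on the returned fit.
    """
    spec = MODELS[model]
    if spec.n_free == 0:
        ll = mixture_loglik(sample, "M1", {})
        return CircFit("M1", MODELS["M1"].expand(()), ll, -2 * ll, 0)

    bounds = [_BOUNDS[name] for name in spec.free]

    def negll(theta: np.ndarray) -> float:
        return -mixture_loglik(sample, model, spec.expand(theta))

    best = None
    any_converged = False
    for start in list(_default_starts(sample, spec)) + list(extra_starts):
        x0 = np.array([start.get(name, 0.5) for name in spec.free])
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"optimizer failed to fit {model}")
    if not any_converged:
        raise RuntimeError(f"no start converged for {model}")
    ll = -float(best.fun)
    return CircFit(
        model, spec.expand(best.x), ll, -2 * ll + 2 * spec.n_free,
        spec.n_free, True,
    )


# warm-start chains: each model also starts from the embedded optimum of
# these already-fitted submodels (guarantees nested log-likelihood order)
_NESTED: dict[str, tuple[str, ...]] = {
    "M2A": ("M1",),
    "M2B": ("M2A",),
    "M2C": ("M2B", "M2A"),
    "M3A": ("M2A",),
    "M3B": ("M3A", "M2A"),
    "M4A": ("M3A",),
    "M4B": ("M4A", "M3B", "M2A"),
    "M5A": ("M4A", "M3A"),
    "M5B": ("M5A", "M4B", "M2C", "M2B", "M2A", "M3B"),
}


def _embed(parent_fit: CircFit, child: ModelSpec) -> dict:
    """Express a fitted submodel as a start point for a larger model."""
    p = dict(parent_fit.params)
    parent = MODELS[parent_fit.model]
    if parent.second == "none":
        # unimodal optimum enters a mixture as a dominant first mode
        p["lam"] = 0.999 if "lam" in child.free else 0.5
    if parent.second == "uniform" and child.second == "vm":
        p["kappa2"] = 0.0  # a kappa=0 von Mises is the uniform component
    return p


def fit_all(sample: CircularSample) -> dict[str, CircFit]:
    """Fit all ten models, warm-starting along the nesting partial order."""
    fits: dict[str, CircFit] = {}
    for mid in MODEL_IDS:
        extra = [
            _embed(fits[parent], MODELS[mid])
            for parent in _NESTED.get(mid, ())
            if parent in fits
        ]
        fits[mid] = fit_model(sample, mid, extra)
    return fits


def select_model(
    sample: CircularSample, tie_tolerance: float = 2.0
) -> list[CircFit]:
    """All ten fits ranked by AIC; the head of the list is the selection.

    Models whose AIC lies within ``tie_tolerance`` of the minimum are
    treated as tied (the conventional "delta-AIC < 2" equivalence band)
    and the tie is broken toward fewer free parameters — exact AIC ties
    have probability zero, so parsimony tie-breaking is only meaningful
    with an equivalence band.  Set ``tie_tolerance=0`` for strict
    lowest-AIC selection.
    """
    fits = fit_all(sample)
    ranked = sorted(fits.values(), key=lambda f: (f.aic, f.n_free))
    if tie_tolerance > 0:
        limit = ranked[0].aic + tie_tolerance
        winner = sorted(
            (f for f in ranked if f.aic <= limit),
            key=lambda f: (f.n_free, f.aic),
        )[0]
        ranked.remove(winner)
        ranked.insert(0, winner)
    return ranked


def fits_table(fits: Sequence[CircFit], period_days: int = 30) -> pd.DataFrame:
    """Summary table (model, phi1, phi2, k1, k2, lam, logL, AIC)."""
    rows = []
    for f in fits:
        p1, p2 = f.phases_days(period_days)
        k1, k2 = f.concentrations()
        rows.append(
            {
                "model": f.model,
                "phi1_day": p1 if f.model != "M1" else np.nan,
                "phi2_day": p2,
                "k1": k1,
                "k2": k2,
                "lambda": f.params["lam"],
                "logL": f.loglik,
                "AIC": f.aic,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# rhythmicity index


@dataclass
class RIResult:
    """Autocorrelation rhythmicity index and its significance category."""

    ri: float
    lag: int
    category: str

    THRESHOLDS = (0.1, 0.3)


def _categorize(ri: float) -> str:
    if ri > 0.3:
        return "highly significant"
    if ri > 0.1:
        return "significant"
    return "not significant"


def rhythmicity_index(
    emergence: pd.DataFrame,
    period_days: int = 30,
    cycle_days: int = 30,
) -> RIResult:
    """Strength of entrainment from the autocorrelation of daily counts.

    Counts are pooled over replicates, normalized within each cycle
    (fractions summing to 1 per ``cycle_days``-day cycle), concatenated in
    time order, and the sample autocorrelation is evaluated at a lag equal
    to the rhythm period (15 days for semilunar, 30 for lunar rhythms).
    Categories: RI > 0.3 highly significant; 0.1 < RI <= 0.3 significant;
    otherwise not significant.
    """
    lag = int(period_days)
    pooled = (
        emergence.groupby(["cycle", "day"])["count"].sum().reset_index()
    )
    chunks = []
    for _, sub in pooled.groupby("cycle"):
        counts = (
            sub.set_index("day")["count"]
            .reindex(pd.RangeIndex(1, cycle_days + 1), fill_value=0)
            .to_numpy(dtype=float)
        )
        total = counts.sum()
        chunks.append(counts / total if total > 0 else counts)
    x = np.concatenate(chunks)
    if len(x) < lag + 2:
        raise ValueError(
            f"series of {len(x)} days too short for lag {lag}"
        )
    ri = float(_acf(x, nlags=lag, fft=True)[lag])
    return RIResult(ri, lag, _categorize(ri))
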