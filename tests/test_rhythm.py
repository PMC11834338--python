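"""Circular mixture fitting, model selection, rhythmicity index."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from lunatide import rhythm as rh
from lunatide import synth

P = 30


def binned_sample(angles, period=P):
    days = (np.round(angles / (2 * np.pi / period)).astype(int) % period) + 1
    counts = np.bincount(days, minlength=period + 1)[1:]
    keep = counts > 0
    return rh.CircularSample(
        2 * np.pi * (np.arange(1, period + 1)[keep] - 1) / period,
        counts[keep].astype(float),
        period,
    )


def emergence_frame(rows):
    return pd.DataFrame(
        rows, columns=["strain", "replicate", "cycle", "day", "count"]
    )


class TestLoglik:
    def test_uniform_closed_form(self):
        s = rh.CircularSample.from_angles(np.linspace(0, 6, 50), P)
        ll = rh.mixture_loglik(s, "M1", {})
        assert ll == pytest.approx(50 * np.log(1 / (2 * np.pi)))

    def test_vm_kappa_zero_is_uniform(self):
        s = rh.CircularSample.from_angles(np.linspace(0, 6, 50), P)
        ll = rh.mixture_loglik(
            s, "M2A", {"mu1": 1.23, "kappa1": 0.0, "lam": 1.0}
        )
        assert ll == pytest.approx(50 * np.log(1 / (2 * np.pi)))

    def test_invalid_parameters_rejected(self):
        s = rh.CircularSample.from_angles(np.array([0.1, 0.2]), P)
        with pytest.raises(ValueError):
            rh.mixture_loglik(s, "M2A", {"mu1": 0, "kappa1": -1, "lam": 1})
        with pytest.raises(ValueError):
            rh.mixture_loglik(
                s, "M2B", {"mu1": 0, "kappa1": 1, "lam": 1.5}
            )

    @pytest.mark.parametrize("model", list(rh.MODEL_IDS))
    def test_every_fitted_density_integrates_to_one(self, model):
        rng = np.random.default_rng(5)
        s = binned_sample(rng.vonmises(1.0, 2.0, 300))
        fit = rh.fit_model(s, model)
        total, _ = quad(
            lambda th: rh.mixture_pdf(np.array([th]), model, fit.params)[0],
            0.0, 2 * np.pi, limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestFitModel:
    def test_m2a_parameter_recovery(self):
        rng = np.random.default_rng(0)
        mu = 2 * np.pi * 9 / P  # day 10
        fit = rh.fit_model(binned_sample(rng.vonmises(mu, 3.0, 500)), "M2A")
        phi1, _ = fit.phases_days(P)
        assert abs(phi1 - 10.0) <= 1.0
        k1, _ = fit.concentrations()
        assert abs(k1 - 3.0) / 3.0 <= 0.2

    def test_m3a_antipodal_constraint(self):
        rng = np.random.default_rng(1)
        a = np.concatenate(
            [rng.vonmises(0.7, 3.0, 200), rng.vonmises(0.7 + np.pi, 3.0, 200)]
        )
        fit = rh.fit_model(binned_sample(a), "M3A")
        diff = (fit.params["mu2"] - fit.params["mu1"]) % (2 * np.pi)
        assert diff == pytest.approx(np.pi)
        assert fit.params["kappa2"] == fit.params["kappa1"]
        assert fit.params["lam"] == 0.5

    def test_lambda_small_on_uniform_data_under_m2b(self):
        rng = np.random.default_rng(2)
        s = binned_sample(rng.uniform(0, 2 * np.pi, 500))
        fit = rh.fit_model(s, "M2B")
        # concentrated-mode weight stays small on structureless data
        if fit.params["kappa1"] > 0.5:
            assert fit.params["lam"] <= 0.2

    def test_aic_formula(self):
        rng = np.random.default_rng(3)
        s = binned_sample(rng.vonmises(1.0, 3.0, 200))
        for model in ("M1", "M2A", "M5B"):
            fit = rh.fit_model(s, model)
            assert fit.aic == pytest.approx(
                -2 * fit.loglik + 2 * rh.MODELS[model].n_free
            )


class TestNestingAndEquivariance:
    def test_m5b_dominates_all_models(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.vonmises(rng.uniform(0, 6), 2.0, 300)
            fits = rh.fit_all(binned_sample(a))
            top = fits["M5B"].loglik
            for mid, fit in fits.items():
                assert top >= fit.loglik - 1e-6, mid

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(4)
        base = rng.vonmises(1.0, 3.0, 400)
        delta = 2 * np.pi * 6 / P  # whole-day rotation keeps binning exact
        f0 = rh.fit_model(binned_sample(base), "M2A")
        f1 = rh.fit_model(binned_sample(base + delta), "M2A")
        rotated = (f0.params["mu1"] + delta) % (2 * np.pi)
        assert f1.params["mu1"] == pytest.approx(rotated, abs=1e-3)
        assert f1.params["kappa1"] == pytest.approx(
            f0.params["kappa1"], rel=1e-3
        )
        assert f1.aic == pytest.approx(f0.aic, abs=1e-6)


class TestSelectModel:
    def test_uniform_data_selects_m1(self):
        # plurality over seeds; individual draws can favor richer models
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = binned_sample(rng.uniform(0, 2 * np.pi, 300))
            wins += rh.select_model(s)[0].model == "M1"
        assert wins >= 6

    def test_unimodal_data_selects_unimodal_family(self):
        rng = np.random.default_rng(0)
        s = binned_sample(rng.vonmises(1.0, 3.0, 500))
        best = rh.select_model(s)[0]
        assert best.model in {"M2A", "M2B", "M2C"}
        assert abs(best.phases_days(P)[0] - (1 + 1.0 / (2 * np.pi) * P)) <= 1.0

    def test_antipodal_data_selects_bimodal_family(self):
        rng = np.random.default_rng(0)
        a = np.concatenate(
            [rng.vonmises(1.0, 3.0, 250), rng.vonmises(1.0 + np.pi, 3.0, 250)]
        )
        best = rh.select_model(binned_sample(a))[0]
        assert best.model in {"M3A", "M3B", "M4A", "M4B", "M5A", "M5B"}

    def test_phi1_is_peak_closer_to_day_one(self):
        rng = np.random.default_rng(6)
        near = 2 * np.pi * 2 / P     # day 3
        far = 2 * np.pi * 15 / P     # day 16
        a = np.concatenate(
            [rng.vonmises(near, 4.0, 200), rng.vonmises(far, 4.0, 300)]
        )
        fit = rh.fit_model(binned_sample(a), "M5B")
        phi1, phi2 = fit.phases_days(P)
        assert abs(phi1 - 3.0) <= 1.5
        assert abs(phi2 - 16.0) <= 1.5


class TestRhythmicityIndex:
    def test_periodic_15day_pattern_highly_significant(self):
        rows = [
            ("S", 1, c, d, 100 if d % 15 == 1 else 0)
            for c in range(1, 5)
            for d in range(1, 31)
        ]
        res = rh.rhythmicity_index(emergence_frame(rows), period_days=15)
        assert res.lag == 15
        assert res.ri > 0.3
        assert res.category == "highly significant"

    def test_uniform_counts_not_significant(self):
        rng = np.random.default_rng(8)
        rows = [
            ("S", 1, c, d, int(rng.integers(0, 10)))
            for c in range(1, 5)
            for d in range(1, 31)
        ]
        res = rh.rhythmicity_index(emergence_frame(rows), period_days=30)
        assert abs(res.ri) < 0.1
        assert res.category == "not significant"

    def test_single_spike_per_cycle_lag30(self):
        rows = [
            ("S", 1, c, d, 50 if d == 7 else 0)
            for c in range(1, 4)
            for d in range(1, 31)
        ]
        res = rh.rhythmicity_index(emergence_frame(rows), period_days=30)
        assert res.ri > 0.3

    def test_too_short_series_rejected(self):
        rows = [("S", 1, 1, d, 1) for d in range(1, 31)]
        with pytest.raises(ValueError, match="too short"):
            rh.rhythmicity_index(emergence_frame(rows), period_days=30)


class TestEndToEnd:
    def test_generated_emergence_recovers_generator(self):
        spec = synth.EmergenceGenSpec(
            model="M2A", phi1_day=10, kappa1=3.0, individuals_per_cycle=500,
            cycles=2,
        )
        df = synth.gen_emergence(spec, np.random.default_rng(12))
        sample = rh.CircularSample.from_emergence(df, P)
        best = rh.select_model(sample)[0]
        assert best.model in {"M2A", "M2B", "M2C"}
        assert abs(best.phases_days(P)[0] - 10.0) <= 1.0
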