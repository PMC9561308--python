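"""Survival laws, Kaplan-Meier estimation, MLE fitting and selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from psmcea import (
    FAMILIES,
    FitResult,
    ParametricSurvival,
    PseudoIPD,
    SimSpec,
    fit_all,
    fit_parametric,
    generate_pseudo_ipd,
    km_estimate,
    median_time,
    select_model,
    survival_prob,
)

GENERIC = {
    "log-logistic": (1.5, 0.02),
    "weibull": (1.3, 0.05),
    "log-normal": (0.9, 16.0),
    "gompertz": (0.08, 0.03),
    "exponential": (1.0, 0.06),
    "gamma": (1.8, 0.11),
}


class TestParametricSurvival:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_boundary_behaviour(self, family):
        """S(0)=1 and S decays towards 0 at large times, every family."""
        m = ParametricSurvival(family, *GENERIC[family])
        assert survival_prob(m, 0.0) == 1.0
        assert survival_prob(m, 1e6) < 1e-6

    def test_tail_limit_loglogistic(self):
        m = ParametricSurvival("log-logistic", 1.941, 0.06522)
        assert survival_prob(m, 1e6) < 1e-9

    def test_negative_time_rejected(self):
        m = ParametricSurvival("exponential", 1.0, 0.1)
        with pytest.raises(ValueError):
            survival_prob(m, -0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParametricSurvival("log-logistic", -1.0, 0.1)
        with pytest.raises(ValueError):
            ParametricSurvival("loglogistic", 1.0, 0.1)  # misspelled family

    def test_median_at_halfway_root(self):
        """Closed-form median equals the root of 1 + lam*t**gam = 2."""
        lam, gam = 0.01375, 1.5396
        m = ParametricSurvival("log-logistic", gam, lam)
        root = brentq(lambda t: 1.0 + lam * t**gam - 2.0, 1.0, 100.0)
        assert median_time(m) == pytest.approx(root, rel=1e-10)
        assert median_time(m) == pytest.approx(16.1886, abs=1e-3)
        assert survival_prob(m, median_time(m)) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "shape,scale,expected",
        [
            (1.0, 1.0, 1.0),
            (1.6294, 0.04528, 6.6819),  # LP PFS
            (1.8582, 0.01024, 11.7698),  # chemo OS
        ],
    )
    def test_loglogistic_median_closed_form(self, shape, scale, expected):
        m = ParametricSurvival("log-logistic", shape, scale)
        assert median_time(m) == pytest.approx(expected, abs=5e-4)
        assert median_time(m) == pytest.approx((1 / scale) ** (1 / shape), rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_median_consistency(self, family):
        m = ParametricSurvival(family, *GENERIC[family])
        assert survival_prob(m, median_time(m)) == pytest.approx(0.5, abs=1e-8)

    @settings(deadline=None, max_examples=60)
    @given(
        family=st.sampled_from(FAMILIES),
        log_shape=st.floats(-1.5, 1.5),
        log_scale=st.floats(-4.0, 0.0),
    )
    def test_sf_non_increasing(self, family, log_shape, log_scale):
        """S is non-increasing on a dense grid for any admissible parameters."""
        m = ParametricSurvival(family, np.exp(log_shape), np.exp(log_scale))
        s = m.sf(np.linspace(0.0, 200.0, 400))
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        ipd = PseudoIPD(np.array([1.0, 2.0, 3.0]), np.array([True, True, True]))
        km = km_estimate(ipd)
        assert np.allclose(km.time, [0, 1, 2, 3])
        assert np.allclose(km.survival, [1, 2 / 3, 1 / 3, 0])

    def test_all_censored_flat_curve(self):
        ipd = PseudoIPD(np.array([1.0, 2.0, 5.0]), np.zeros(3, bool))
        km = km_estimate(ipd)
        assert np.all(km.survival == 1.0)

    def test_censoring_shrinks_risk_set_without_step(self):
        # events at 1 and 3, censor at 2: S = 2/3 then 2/3 * (1 - 1/1) = 0
        ipd = PseudoIPD(np.array([1.0, 2.0, 3.0]), np.array([True, False, True]))
        km = km_estimate(ipd)
        assert np.allclose(km.time, [0, 1, 3])
        assert np.allclose(km.survival, [1, 2 / 3, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            PseudoIPD(np.array([]), np.array([]))

    def test_km_tracks_truth_within_confidence_band(self, lp_os):
        """n=1000 simulated cohort: the pointwise 95% band covers true S."""
        from lifelines import KaplanMeierFitter

        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=1000, admin_censor_time=80.0, seed=42))
        km = km_estimate(ipd)
        kmf = KaplanMeierFitter().fit(ipd.time, ipd.event.astype(int))
        ci = kmf.confidence_interval_survival_function_
        for t_check in (5.0, 10.0, 20.0, 40.0):
            truth = lp_os.sf(t_check)
            idx = ci.index[ci.index <= t_check][-1]
            lo, hi = ci.loc[idx].to_numpy()
            assert lo - 1e-9 <= truth <= hi + 1e-9
            # and our curve matches the fitter's point estimate
            assert km.evaluate(t_check) == pytest.approx(
                kmf.predict(t_check), abs=1e-12
            )


class TestFitting:
    def test_exponential_closed_form_mle(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1 / 0.08, size=300)
        ipd = PseudoIPD(t, np.ones_like(t, bool))
        fit = fit_parametric(ipd, "exponential")
        assert fit.model.scale == pytest.approx(ipd.n_events / t.sum(), rel=1e-8)
        assert fit.k == 1

    def test_aic_bic_identities(self, lp_os):
        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=200, admin_censor_time=60.0, seed=5))
        for fit in fit_all(ipd):
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood, abs=1e-12)
            assert fit.bic == pytest.approx(
                fit.k * np.log(fit.n) - 2 * fit.log_likelihood, abs=1e-12
            )

    def test_loglogistic_recovery_uncensored(self, lp_os):
        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=5000, admin_censor_time=1e9, seed=1))
        fit = fit_parametric(ipd, "log-logistic")
        assert fit.model.shape == pytest.approx(1.5396, rel=0.05)
        assert fit.model.scale == pytest.approx(0.01375, rel=0.05)

    def test_matches_lifelines_loglogistic(self, lp_os):
        """Our MLE agrees with lifelines' independent fitter."""
        from lifelines import LogLogisticFitter

        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=800, admin_censor_time=50.0, seed=9))
        ours = fit_parametric(ipd, "log-logistic").model
        llf = LogLogisticFitter().fit(ipd.time, ipd.event.astype(int))
        assert ours.shape == pytest.approx(llf.beta_, rel=1e-4)
        assert ours.scale == pytest.approx(llf.alpha_**-llf.beta_, rel=1e-3)

    def test_too_few_events_rejected(self):
        ipd = PseudoIPD(np.array([1.0, 2.0, 3.0]), np.array([True, False, False]))
        with pytest.raises(ValueError):
            fit_parametric(ipd, "weibull")

    def test_unknown_family_rejected(self, lp_os):
        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=50, seed=0))
        with pytest.raises(ValueError):
            fit_parametric(ipd, "spline")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_with_censoring(self, family):
        """n=5000, ~20% random censoring: parameters within 10% in >=90% of 50 reps."""
        sh, sc = GENERIC[family]
        truth = ParametricSurvival(family, sh, sc)
        ok = 0
        for rep in range(50):
            ipd = generate_pseudo_ipd(
                SimSpec(truth, n=5000, admin_censor_time=120.0,
                        random_censor_rate=0.2, seed=1000 + rep)
            )
            f = fit_parametric(ipd, family).model
            ok += abs(f.shape / sh - 1) < 0.1 and abs(f.scale / sc - 1) < 0.1
        assert ok >= 45, f"{family}: only {ok}/50 replicates recovered parameters"


class TestSelection:
    def test_single_candidate(self, lp_os):
        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=100, seed=2))
        fit = fit_parametric(ipd, "weibull")
        assert select_model([fit]) is fit

    def test_tie_broken_by_bic(self, lp_os):
        a = FitResult(ParametricSurvival("weibull", 1, 1), -100.0, 204.0, 210.0, 50, 2)
        b = FitResult(ParametricSurvival("gamma", 1, 1), -100.0, 204.0, 205.0, 50, 2)
        assert select_model([a, b]) is b

    def test_mixed_datasets_rejected(self, lp_os):
        i1 = generate_pseudo_ipd(SimSpec(lp_os, n=100, seed=3))
        i2 = generate_pseudo_ipd(SimSpec(lp_os, n=120, seed=4))
        with pytest.raises(ValueError):
            select_model([fit_parametric(i1, "weibull"), fit_parametric(i2, "gamma")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_large_sample_recovers_generating_family(self, lp_os):
        ipd = generate_pseudo_ipd(SimSpec(lp_os, n=5000, admin_censor_time=1e9, seed=11))
        assert select_model(fit_all(ipd)).model.family == "log-logistic"
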