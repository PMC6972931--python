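"""Global fit recovery, model selection, uncertainty, and reporting."""

import warnings

import numpy as np
import pytest
from sklearn.base import clone

from enzkin import (
    FitError,
    KineticParameters,
    OpticalConstants,
    ProgressCurve,
    ProgressCurveFitter,
    PseudoFirstOrderRateFitter,
    TraceSetSpec,
    bootstrap_uncertainty,
    estimate_specificity,
    fit_global,
    generate_trace_set,
    initial_guess,
    report_table,
    select_model,
    substrate_timecourse,
)
from enzkin.fitting import format_sig


def make_noiseless(params, n_points=150, **kw):
    spec = TraceSetSpec(params=params, seed=0, noise_sd_au=0.0, n_points=n_points, **kw)
    return list(generate_trace_set(spec))


def exponential_curve(k_obs, s0=1e-5, e0=1e-6, n=200):
    times = np.linspace(0.0, 3.0 / k_obs if k_obs > 0 else 100.0, n)
    return ProgressCurve(
        curve_id="pfo__c", times=times, signal=s0 * np.exp(-k_obs * times),
        s0=s0, e0=e0, signal_units="M",
    )


class TestGlobalFitRecovery:
    @pytest.mark.parametrize(
        "params",
        [
            KineticParameters(km=6.2e-5, kcat=157.0, ki=1.3e-4),  # fast, inhibited
            KineticParameters(km=2.0e-6, kcat=7.0e-2, ki=3.0e-7),  # slow, Ki < Km
        ],
        ids=["wild-type-regime", "slow-mutant-regime"],
    )
    def test_noiseless_recovery_with_inhibition(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_global(make_noiseless(params), model="mm+pi")
        assert res.km == pytest.approx(params.km, rel=1e-3)
        assert res.kcat == pytest.approx(params.kcat, rel=1e-3)
        assert res.ki == pytest.approx(params.ki, rel=1e-3)
        assert res.specificity_hat == pytest.approx(params.specificity, rel=1e-3)

    def test_noiseless_recovery_without_inhibition(self, slow_params):
        res = fit_global(make_noiseless(slow_params, e0=1e-6), model="mm")
        assert res.km == pytest.approx(slow_params.km, rel=1e-3)
        assert res.kcat == pytest.approx(slow_params.kcat, rel=1e-3)
        assert res.ki is None

    def test_absorbance_and_concentration_fits_agree(self, wt_params):
        curves_au = make_noiseless(wt_params)
        curves_m = []
        for c in curves_au:
            s = substrate_timecourse(wt_params, c.s0, c.e0, c.times)
            curves_m.append(ProgressCurve(
                curve_id=c.curve_id, times=c.times, signal=s,
                s0=c.s0, e0=c.e0, signal_units="M",
            ))
        res_au = fit_global(curves_au, model="mm+pi")
        res_m = fit_global(curves_m, model="mm+pi")
        assert res_au.km == pytest.approx(res_m.km, rel=1e-6)
        assert res_au.kcat == pytest.approx(res_m.kcat, rel=1e-6)
        assert res_au.ki == pytest.approx(res_m.ki, rel=1e-6)

    def test_scale_equivariance(self, wt_params):
        # multiplying all concentrations (S0, E0 fixed) and Km, Ki by c
        # leaves kcat invariant and scales Km, Ki by c
        c = 10.0
        base = make_noiseless(wt_params, n_points=80)
        scaled_params = KineticParameters(
            km=c * wt_params.km, kcat=wt_params.kcat, ki=c * wt_params.ki
        )
        scaled = []
        for curve in base:
            s = substrate_timecourse(scaled_params, c * curve.s0, curve.e0, curve.times)
            scaled.append(ProgressCurve(
                curve_id=curve.curve_id, times=curve.times, signal=s,
                s0=c * curve.s0, e0=curve.e0, signal_units="M",
            ))
        res_base = fit_global(
            [ProgressCurve(curve_id=b.curve_id, times=b.times,
                           signal=substrate_timecourse(wt_params, b.s0, b.e0, b.times),
                           s0=b.s0, e0=b.e0, signal_units="M") for b in base],
            model="mm+pi",
        )
        res_scaled = fit_global(scaled, model="mm+pi")
        assert res_scaled.kcat == pytest.approx(res_base.kcat, rel=1e-6)
        assert res_scaled.km == pytest.approx(c * res_base.km, rel=1e-6)
        assert res_scaled.ki == pytest.approx(c * res_base.ki, rel=1e-6)

    def test_rss_not_worse_than_initial_guess(self, wt_params):
        spec = TraceSetSpec(params=wt_params, seed=8, noise_sd_au=0.002, n_points=60)
        curves = list(generate_trace_set(spec))
        from enzkin.fitting import _residuals

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            guess = initial_guess(curves)
            res = fit_global(curves, model="mm+pi", n_restarts=2)
        rss_guess = float(np.sum(_residuals(guess, curves) ** 2))
        assert res.rss <= rss_guess

    def test_few_s0_values_warn(self, wt_params):
        curves = make_noiseless(wt_params)[:2]
        with pytest.warns(UserWarning, match="distinct initial substrate"):
            fit_global(curves, model="mm")

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            fit_global([], model="mm")


class TestModelSelection:
    def test_zero_noise_inhibited_data_always_selects_inhibition(self, wt_params):
        res = select_model(make_noiseless(wt_params))
        assert res.model == "with_inhibition"
        assert res.p_value < 1e-10

    def test_zero_noise_uninhibited_data_selects_plain_model(self):
        params = KineticParameters(km=6.2e-5, kcat=157.0)
        res = select_model(make_noiseless(params))
        assert res.model == "without_inhibition"
        assert res.ki is None

    def test_strong_inhibition_detected_under_noise(self):
        params = KineticParameters(km=6.2e-5, kcat=157.0, ki=6.2e-5 / 2)
        detected = 0
        for seed in range(10):
            spec = TraceSetSpec(params=params, seed=seed, noise_sd_au=0.002, n_points=60)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = select_model(list(generate_trace_set(spec)), n_restarts=1)
            detected += res.model == "with_inhibition"
        assert detected >= 9

    def test_discarded_model_rss_recorded(self, wt_params):
        res = select_model(make_noiseless(wt_params))
        assert res.rss_alternative is not None
        assert res.rss_alternative >= res.rss


class TestPseudoFirstOrder:
    def test_planted_k_obs_recovery(self):
        e0 = 1e-6
        curve = exponential_curve(k_obs=15.0 * e0, e0=e0)
        assert estimate_specificity(curve) == pytest.approx(15.0, rel=1e-6)

    def test_flat_trace_returns_zero_with_warning(self):
        curve = exponential_curve(k_obs=0.0)
        with pytest.warns(UserWarning, match="flat"):
            assert estimate_specificity(curve) == 0.0

    def test_halving_e0_doubles_the_estimate(self):
        k = 1.5e-5
        full = estimate_specificity(exponential_curve(k, e0=1e-6))
        half = estimate_specificity(exponential_curve(k, e0=5e-7))
        assert half == pytest.approx(2 * full, rel=1e-9)

    def test_saturation_curvature_warns(self, wt_params):
        # S0 comparable to Km: the trace is not pseudo-first-order
        s0, e0 = 5e-4, 1e-8
        times = np.linspace(0.0, 1500.0, 150)
        s = substrate_timecourse(
            KineticParameters(km=wt_params.km, kcat=wt_params.kcat), s0, e0, times
        )
        curve = ProgressCurve(curve_id="sat__c", times=times, signal=s,
                              s0=s0, e0=e0, signal_units="M")
        with pytest.warns(UserWarning, match="S0"):
            PseudoFirstOrderRateFitter().fit(curve)


class TestInitialGuess:
    def test_within_decade_of_truth_across_regimes(self):
        regimes = [
            KineticParameters(km=7.0e-5, kcat=196.0, ki=7.7e-5),
            KineticParameters(km=4.0e-4, kcat=101.0),
            KineticParameters(km=7.0e-4, kcat=0.016),
        ]
        for params in regimes:
            curves = make_noiseless(params, n_points=80, e0=1e-7)
            guess = initial_guess(curves)
            assert params.km / 10 <= guess.km <= params.km * 10
            assert params.kcat / 10 <= guess.kcat <= params.kcat * 10

    def test_two_point_curves_rejected(self):
        curve = ProgressCurve(curve_id="tiny", times=np.array([0.0, 1.0]),
                              signal=np.array([1e-4, 9e-5]), s0=1e-4, e0=1e-8,
                              signal_units="M")
        with pytest.raises(FitError):
            initial_guess([curve])

    def test_constant_signal_falls_back_with_warning(self):
        curve = ProgressCurve(curve_id="flat", times=np.linspace(0, 10, 30),
                              signal=np.full(30, 1e-4), s0=1e-4, e0=1e-8,
                              signal_units="M")
        with pytest.warns(UserWarning, match="initial guess"):
            guess = initial_guess([curve])
        assert guess.km > 0 and guess.kcat > 0


class TestBootstrap:
    def _noisy_curves(self, params, seed=13):
        spec = TraceSetSpec(params=params, seed=seed, noise_sd_au=0.002, n_points=60)
        return list(generate_trace_set(spec))

    def test_seeded_determinism(self, wt_params):
        curves = self._noisy_curves(wt_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_global(curves, model="mm+pi", n_restarts=1)
            a = bootstrap_uncertainty(curves, fit, n_boot=50, seed=5)
            b = bootstrap_uncertainty(curves, fit, n_boot=50, seed=5)
        assert a.ci95 == b.ci95

    def test_zero_noise_gives_vanishing_interval(self, wt_params):
        curves = make_noiseless(wt_params, n_points=80)
        fit = fit_global(curves, model="mm+pi", n_restarts=1)
        boot = bootstrap_uncertainty(curves, fit, n_boot=50, seed=0)
        lo, hi = boot.ci95["km"]
        assert (hi - lo) < 1e-6 * wt_params.km

    def test_small_n_boot_rejected(self, wt_params):
        curves = self._noisy_curves(wt_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_global(curves, model="mm+pi", n_restarts=1)
        with pytest.raises(FitError):
            bootstrap_uncertainty(curves, fit, n_boot=10)

    def test_km_coverage_near_nominal(self, wt_params):
        # scaled-down coverage check: 25 datasets x 60 replicates
        covered = 0
        n_sets = 25
        for seed in range(n_sets):
            curves = self._noisy_curves(wt_params, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_global(curves, model="mm+pi", n_restarts=1)
                boot = bootstrap_uncertainty(curves, fit, n_boot=60, seed=seed)
            lo, hi = boot.ci95["km"]
            covered += lo <= wt_params.km <= hi
        # binomial(25, 0.95): P(X >= 20) > 0.999
        assert covered >= 20


class TestEstimatorProtocol:
    def test_get_set_params_and_clone(self):
        fitter = ProgressCurveFitter(model="mm", alpha=0.01, n_restarts=2)
        params = fitter.get_params()
        assert params["model"] == "mm" and params["alpha"] == 0.01
        cloned = clone(fitter)
        assert cloned.get_params() == params

    def test_fitted_attributes_and_predict(self, wt_params):
        curves = make_noiseless(wt_params, n_points=60)
        fitter = ProgressCurveFitter(model="mm+pi").fit(curves)
        assert fitter.km_ == pytest.approx(wt_params.km, rel=1e-6)
        preds = fitter.predict(curves)
        for pred, curve in zip(preds, curves):
            assert np.allclose(pred, curve.signal, atol=1e-9)

    def test_predict_before_fit_rejected(self, noiseless_wt_traces):
        with pytest.raises(FitError):
            ProgressCurveFitter().predict(noiseless_wt_traces)


class TestReportTable:
    def test_specificity_cells_match_printed_ratio_convention(self):
        # ratio of 2-significant-figure table entries, e.g. 196/7.0e-5 = 2.8e6
        assert format_sig(196.0 / 7.0e-5) == "2.8e+06"
        assert float(format_sig(0.07 / 3.0e-4).replace("e", "E")) == pytest.approx(230.0)

    def test_table_rows_and_nd_rendering(self, wt_params, slow_params):
        results = {
            "fast": fit_global(make_noiseless(wt_params, n_points=60), model="mm+pi"),
            "slow": fit_global(make_noiseless(slow_params, e0=1e-6, n_points=60), model="mm"),
        }
        df, text = report_table(results)
        assert list(df["substrate"]) == ["fast", "slow"]
        assert df.loc[df.substrate == "slow", "Ki_M"].isna().all()
        slow_line = next(l for l in text.splitlines() if l.startswith("slow"))
        assert "N.D." in slow_line
        fast_line = next(l for l in text.splitlines() if l.startswith("fast"))
        assert "2.5e+06" in fast_line  # 157/6.2e-5 = 2.5e6 at 2 sig figs

    def test_empty_input_gives_header_only(self):
        df, text = report_table({})
        assert df.empty
        assert len(text.splitlines()) == 2
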