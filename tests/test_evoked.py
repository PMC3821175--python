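"""Evoked-EPSC analysis: integration, kinetic decomposition, decay times,
windowed and sucrose charges, checked against closed forms and independent
numerical oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from synaptiq.data import SweepTrace
from synaptiq.synthgen import (
    EvokedParams, gen_evoked_trace, evoked_amplitudes, evoked_charge_curve,
)
from synaptiq.evoked import (
    baseline_subtract, peak_amplitude, cumulative_charge,
    fit_double_exponential, DoubleExponentialChargeFit, decay_time_90_10,
    windowed_charge, sucrose_charges, release_ratio, analyze_sweep,
)


def flat_trace(value_pA=0.0, duration_ms=400.0, fs=10.0, markers=None):
    n = int(duration_ms * fs) + 1
    t = np.arange(n) / fs
    return SweepTrace(t, np.full(n, value_pA), fs, markers or {"t0_ms": 100.0})


class TestBaselineSubtract:
    def test_constant_trace_becomes_zero(self):
        out = baseline_subtract(flat_trace(-10.0), 50.0)
        assert np.allclose(out.current_pA, 0.0)

    def test_step_preserved(self):
        tr = flat_trace(-5.0)
        tr.current_pA[tr.time_ms >= 100.0] = -105.0
        out = baseline_subtract(tr, 50.0)
        assert out.current_pA[-1] == pytest.approx(-100.0)
        assert out.current_pA[0] == pytest.approx(0.0)

    def test_noisy_baseline_mean_near_zero(self, rng):
        tr = flat_trace(0.0, duration_ms=700.0)
        tr.current_pA += rng.normal(0, 10.0, tr.n_samples)
        out = baseline_subtract(tr, 100.0)
        pre = out.current_pA[(out.time_ms >= 0) & (out.time_ms < 100.0)]
        assert abs(pre.mean()) < 10.0 / np.sqrt(1000)

    def test_empty_window_errors(self):
        tr = flat_trace()
        tr.markers["t0_ms"] = 0.0
        with pytest.raises(ValueError):
            baseline_subtract(tr, 50.0)


class TestPeakAmplitude:
    def test_flat_trace_zero(self):
        amp, lat = peak_amplitude(flat_trace(), 100.0)
        assert amp == 0.0 and lat == 0.0

    def test_generated_peak_matches_analytic(self):
        p = EvokedParams(noise_sd=0.0)
        trace, _ = gen_evoked_trace(p, 0)
        a_f, b_s = evoked_amplitudes(p)
        expected = 1000.0 * (a_f / p.tau_fast + b_s / p.tau_slow)
        amp, lat = peak_amplitude(trace, p.t0)
        assert amp == pytest.approx(expected, rel=1e-6)
        assert lat < 2.0  # fast-dominated response peaks promptly


class TestCumulativeCharge:
    def test_constant_current_closed_form(self):
        tr = flat_trace(-100.0)
        curve = cumulative_charge(tr, 100.0, 50.0)
        assert curve.q50 == pytest.approx(5.0, rel=1e-9)

    def test_zero_trace(self):
        curve = cumulative_charge(flat_trace(0.0), 100.0)
        assert np.allclose(curve.charge_pc, 0.0)

    def test_generated_biexponential(self):
        p = EvokedParams(q_total=1.5, noise_sd=0.0)
        trace, _ = gen_evoked_trace(p, 0)
        curve = cumulative_charge(trace, p.t0)
        assert abs(curve.q50 - 1.5) < 0.002

    def test_out_of_record_errors(self):
        with pytest.raises(ValueError):
            cumulative_charge(flat_trace(duration_ms=120.0), 100.0, 50.0)


class TestDoubleExponentialFit:
    def test_pure_fast_component(self):
        t = np.arange(0, 50.01, 0.1)
        q = 1.0 - np.exp(-t / 5.0)
        d = fit_double_exponential(t, q)
        assert d.tau_fast == pytest.approx(5.0, rel=1e-3)
        assert d.f_fast == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("tau_fast", [2.0, 5.0, 10.0])
    @pytest.mark.parametrize("tau_slow", [30.0, 40.0, 80.0])
    @pytest.mark.parametrize("f_fast", [0.3, 0.5, 0.77, 0.9])
    def test_noiseless_roundtrip_grid(self, tau_fast, tau_slow, f_fast):
        p = EvokedParams(q_total=1.0, f_fast=f_fast, tau_fast=tau_fast,
                         tau_slow=tau_slow, noise_sd=0.0)
        t = np.arange(0, 50.0001, 0.05)
        q = evoked_charge_curve(p, t)
        d = fit_double_exponential(t, q)
        assert d.converged
        assert d.tau_fast == pytest.approx(tau_fast, rel=0.01)
        assert d.tau_slow == pytest.approx(tau_slow, rel=0.01)
        assert d.f_fast == pytest.approx(f_fast, rel=0.01)

    def test_conservation_exact(self):
        # a_fast + a_slow_eff equals q50 exactly, including on noisy fits
        p = EvokedParams(noise_sd=50.0)
        for seed in range(3):
            trace, _ = gen_evoked_trace(p, seed)
            curve = cumulative_charge(trace, p.t0)
            d = fit_double_exponential(curve.time_ms, curve.charge_pc)
            assert d.a_fast + d.a_slow_eff == d.q50

    def test_noisy_replicates_median_recovery(self):
        # simulation oracle: generator truth tau 5/40 ms, f 0.75, SNR 20.
        # tau_fast and f_fast recover tightly; tau_slow is weakly identified
        # from a 50 ms window (1.25 time constants) and spreads widely.
        p = EvokedParams(q_total=15.0, f_fast=0.75, tau_fast=5.0,
                         tau_slow=40.0, noise_sd=0.0)
        a_f, b_s = evoked_amplitudes(p)
        p.noise_sd = 1000.0 * (a_f / p.tau_fast + b_s / p.tau_slow) / 20.0
        tf, ts, ff = [], [], []
        for seed in range(100):
            trace, _ = gen_evoked_trace(p, seed)
            curve = cumulative_charge(trace, p.t0)
            d = fit_double_exponential(curve.time_ms, curve.charge_pc)
            tf.append(d.tau_fast)
            ts.append(d.tau_slow)
            ff.append(d.f_fast)
        assert np.median(tf) == pytest.approx(5.0, rel=0.10)
        assert np.median(ff) == pytest.approx(0.75, rel=0.10)
        assert np.median(ts) == pytest.approx(40.0, rel=0.30)

    def test_estimator_interface(self):
        t = np.arange(0, 50.01, 0.1)
        q = 0.8 * (1 - np.exp(-t / 5.0)) + 0.25 * (1 - np.exp(-t / 40.0))
        est = DoubleExponentialChargeFit().fit(t, q)
        assert est.converged_
        assert est.tau_fast_ < est.tau_slow_
        assert est.get_params()["window_ms"] == 50.0
        assert est.a_fast_ + est.a_slow_eff_ == est.q50_

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            fit_double_exponential(np.arange(5.0), np.arange(5.0))


class TestDecayTime:
    @pytest.mark.parametrize("tau", [2.0, 5.0, 10.0, 40.0])
    def test_pure_exponential_tau_ln9(self, tau):
        tr = flat_trace(0.0, duration_ms=600.0)
        m = tr.time_ms >= 100.0
        tr.current_pA[m] = -np.exp(-(tr.time_ms[m] - 100.0) / tau)
        dt = decay_time_90_10(tr, 100.0)
        assert not dt.censored
        assert abs(dt.ms - tau * np.log(9.0)) < 0.1  # one sample interval

    def test_biexponential_vs_rootfinding_oracle(self):
        p = EvokedParams(q_total=1.0, f_fast=0.7721, tau_fast=5.29,
                         tau_slow=40.30, noise_sd=0.0, duration_ms=500.0)
        a_f, b_s = evoked_amplitudes(p)

        def current(t):  # analytic inward current magnitude after t0
            return a_f / p.tau_fast * np.exp(-t / p.tau_fast) + \
                b_s / p.tau_slow * np.exp(-t / p.tau_slow)

        peak = current(0.0)
        t90 = brentq(lambda t: current(t) - 0.9 * peak, 0, 500)
        t10 = brentq(lambda t: current(t) - 0.1 * peak, 0, 500)
        trace, _ = gen_evoked_trace(p, 0)
        dt = decay_time_90_10(trace, p.t0)
        assert dt.ms == pytest.approx(t10 - t90, abs=0.15)

    def test_censored_when_no_10_percent_crossing(self):
        p = EvokedParams(tau_slow=400.0, tau_fast=5.0, f_fast=0.2,
                         noise_sd=0.0, duration_ms=300.0, window_ms=50.0)
        trace, _ = gen_evoked_trace(p, 0)
        dt = decay_time_90_10(trace, p.t0)
        assert dt.censored


class TestWindowedCharge:
    def test_constant_current_windows(self):
        tr = flat_trace(-100.0)
        q = windowed_charge(tr, 100.0, [(0.0, 20.0), (25.0, 50.0)])
        assert q[0] == pytest.approx(2.0, rel=1e-9)
        assert q[1] == pytest.approx(2.5, rel=1e-9)

    def test_contiguous_windows_sum_to_q50(self):
        p = EvokedParams(noise_sd=20.0)
        trace, _ = gen_evoked_trace(p, 4)
        trace = baseline_subtract(trace, 50.0)
        parts = windowed_charge(trace, p.t0, [(0, 20), (20, 35), (35, 50)])
        q50 = cumulative_charge(trace, p.t0).q50
        assert sum(parts) == pytest.approx(q50, rel=1e-9)

    def test_biexponential_window_split_analytic(self):
        p = EvokedParams(q_total=1.0, noise_sd=0.0)
        trace, _ = gen_evoked_trace(p, 0)
        q = windowed_charge(trace, p.t0, [(0.0, 20.0), (25.0, 50.0)])
        q20 = evoked_charge_curve(p, np.array([20.0]))[0]
        q25 = evoked_charge_curve(p, np.array([25.0]))[0]
        q50 = evoked_charge_curve(p, np.array([50.0]))[0]
        assert q[0] == pytest.approx(q20, abs=2e-4)
        assert q[1] == pytest.approx(q50 - q25, abs=2e-4)

    def test_overlapping_windows_error(self):
        with pytest.raises(ValueError):
            windowed_charge(flat_trace(), 100.0, [(0, 30), (20, 50)])


class TestSucrose:
    def _sucrose_trace(self, duration_ms=8000.0, fs=2.0):
        n = int(duration_ms * fs) + 1
        t = np.arange(n) / fs
        i = np.zeros(n)
        return t, i, fs

    def test_constant_response(self):
        t, i, fs = self._sucrose_trace()
        i[t >= 1000.0] = -20.0
        tr = SweepTrace(t, i, fs, {"app_start_ms": 1000.0})
        res = sucrose_charges(tr)
        assert res.q_1s == pytest.approx(20.0, rel=1e-6)
        assert res.q_5s == pytest.approx(100.0, rel=1e-6)
        assert not res.censored

    def test_zero_response(self):
        t, i, fs = self._sucrose_trace()
        tr = SweepTrace(t, i, fs, {"app_start_ms": 1000.0})
        res = sucrose_charges(tr)
        assert res.q_1s == pytest.approx(0.0, abs=1e-12)
        assert res.q_5s == pytest.approx(0.0, abs=1e-12)

    def test_exponential_response_closed_form(self):
        t, i, fs = self._sucrose_trace()
        tau = 1500.0  # ms
        m = t >= 1000.0
        i[m] = -50.0 * np.exp(-(t[m] - 1000.0) / tau)
        tr = SweepTrace(t, i, fs, {"app_start_ms": 1000.0})
        res = sucrose_charges(tr)
        q = lambda w: 50.0 * tau * (1 - np.exp(-w / tau)) / 1000.0
        assert res.q_1s == pytest.approx(q(1000.0), rel=1e-3)
        assert res.q_5s == pytest.approx(q(5000.0), rel=1e-3)

    def test_baseline_compensation(self):
        t, i, fs = self._sucrose_trace()
        i[:] = -7.0  # standing inward current
        i[t >= 1000.0] += -20.0
        tr = SweepTrace(t, i, fs, {"app_start_ms": 1000.0})
        res = sucrose_charges(tr)
        assert res.q_1s == pytest.approx(20.0, rel=1e-6)

    def test_truncated_window_censored(self):
        t, i, fs = self._sucrose_trace(duration_ms=4000.0)
        i[t >= 1000.0] = -20.0
        tr = SweepTrace(t, i, fs, {"app_start_ms": 1000.0})
        res = sucrose_charges(tr)
        assert res.censored
        assert res.q_5s == pytest.approx(60.0, rel=1e-6)  # 3 s available

    def test_application_beyond_record_errors(self):
        t, i, fs = self._sucrose_trace(duration_ms=2000.0)
        tr = SweepTrace(t, i, fs, {})
        with pytest.raises(ValueError):
            sucrose_charges(tr, app_start_ms=3000.0)


class TestReleaseRatio:
    def test_basic_and_homogeneity(self):
        assert release_ratio(100.0, 100.0) == 1.0
        assert release_ratio(25.0, 100.0) == 0.25
        assert release_ratio(12.5, 100.0) == 0.5 * release_ratio(25.0, 100.0)

    def test_zero_sucrose_errors(self):
        with pytest.raises(ValueError):
            release_ratio(25.0, 0.0)


class TestAnalyzeSweep:
    def test_full_sweep_summary(self):
        p = EvokedParams(noise_sd=5.0)
        trace, _ = gen_evoked_trace(p, 2)
        res = analyze_sweep(trace, windows=[(0, 20), (25, 50)])
        assert res["fit_converged"]
        assert res["q50_pC"] == pytest.approx(p.q_total, rel=0.02)
        assert res["tau_fast_ms"] == pytest.approx(p.tau_fast, rel=0.05)
        assert res["f_fast"] == pytest.approx(p.f_fast, rel=0.05)
        assert len(res["windowed_charge_pC"]) == 2
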