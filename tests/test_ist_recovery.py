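"""Tests of sinusoid fitting and the single-compartment IST inversion."""

import math

import numpy as np
import pytest

from istct.ist import (
    SineFit,
    fit_sinusoid,
    heterogeneity_ratios,
    invert_dc,
    invert_single_compartment,
    recover_ist,
)
from istct.lung import BreathTrace, SineForcing, build_lung, simulate
from istct.settings import SimSettings


def _trace_from_samples(t, y, period_T, RR=25.0, VT=300.0, V_D=150.0):
    tau = 60.0 / RR
    return BreathTrace(
        t_insp=t - tau, t_end=t, F_I=y, F_ET=y, period_T=period_T, VT=VT, RR=RR, V_D=V_D
    )


class TestFitSinusoid:
    def test_exact_sine_recovered_to_machine_precision(self):
        T = 60.0
        t = 2.4 * np.arange(200)
        y = 0.05 + 0.013 * np.sin(2 * np.pi * t / T + 0.7)
        fit = fit_sinusoid(_trace_from_samples(t, y, T), "F_ET")
        assert fit.mean == pytest.approx(0.05, abs=1e-12)
        assert fit.amplitude == pytest.approx(0.013, abs=1e-12)
        assert fit.phase == pytest.approx(0.7, abs=1e-9)
        assert fit.residual_rms < 1e-12

    def test_constant_signal_has_zero_amplitude(self):
        t = 2.4 * np.arange(200)
        fit = fit_sinusoid(_trace_from_samples(t, np.full_like(t, 0.04), 60.0), "F_ET")
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_error_within_least_squares_bound(self):
        # white noise of sd sigma over N samples: amplitude error sd is
        # sigma * sqrt(2/N); check a batch stays within 3 sigma
        T, sigma = 60.0, 0.002
        t = 2.4 * np.arange(150)  # 6 periods
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(20):
            y = 0.05 + 0.013 * np.sin(2 * np.pi * t / T) + rng.normal(0, sigma, len(t))
            fit = fit_sinusoid(
                _trace_from_samples(t, y, T), "F_ET", warmup_periods=0.0
            )
            errs.append(fit.amplitude - 0.013)
        n_used = len(t)
        assert np.std(errs) < 3 * sigma * math.sqrt(2 / n_used)

    def test_short_trace_rejected(self):
        t = 2.4 * np.arange(30)  # barely over one period at T=60
        with pytest.raises(ValueError, match="too short"):
            fit_sinusoid(_trace_from_samples(t, np.full_like(t, 0.05), 60.0), "F_ET")


class TestInversionRoundTrip:
    # longer validation traces: the decay transient shrinks as
    # ((ELV+V_D)/(ELV+VT))^n and is slowest for large, poorly perfused lungs
    ROUNDTRIP_SETTINGS = SimSettings(
        n_periods={180.0: 4.0, 60.0: 8.0},
        warmup_periods={180.0: 2.0, 60.0: 4.0},
    )

    @pytest.mark.parametrize("elv", [500.0, 800.0, 1200.0])
    @pytest.mark.parametrize("qp", [1500.0, 3400.0, 6000.0])
    @pytest.mark.parametrize("T", [180.0, 60.0])
    def test_one_compartment_round_trip(self, elv, qp, T):
        """Noiseless one-compartment data invert back to the generating
        (ELV, Qp) to better than 0.1% relative error."""
        s = self.ROUNDTRIP_SETTINGS
        lung = build_lung(elv, 150.0, qp, 0.0, 0.0, 1, s.lambda_b)
        tr = simulate(lung, s.forcing(T, 300.0, 25.0))
        res = recover_ist(tr, s.lambda_b, warmup_periods=s.warmup_periods[T])
        assert abs(res.ELV - elv) / elv < 1e-3
        assert abs(res.Qp - qp) / qp < 1e-3
        assert abs(res.Qp_mean - qp) / qp < 1e-3

    def test_perfusionless_lung_recovered_near_zero_flow(self, sim_settings):
        # relative error is undefined at Qp = 0; the residual decay
        # transient leaves only a few mL/min of spurious flow
        s = sim_settings
        lung = build_lung(1200.0, 150.0, 0.0, 0.0, 0.0, 1, s.lambda_b)
        for T in (180.0, 60.0):
            tr = simulate(lung, s.forcing(T, 300.0, 25.0))
            res = recover_ist(tr, s.lambda_b, warmup_periods=s.warmup_periods[T])
            assert abs(res.ELV - 1200.0) / 1200.0 < 1e-3
            assert res.Qp < 20.0
            assert res.Qp_mean < 20.0

    def test_no_uptake_matches_pure_dilution_closed_form(self):
        # with Qp = 0 the recursion is pure dilution of an effective volume
        # ELV + V_D by VT - V_D of fresh gas per breath; the inversion must
        # land exactly on the generating ELV
        elv, vd, vt, RR, T = 800.0, 150.0, 300.0, 25.0, 60.0
        tau = 60.0 / RR
        lam = (elv + vd) / (elv + vt)  # geometric pole of the recursion
        w = 2 * np.pi / T
        # analytic gain of the dilution recursion, measurement convention
        u = np.exp(-1j * w * tau)
        H = u * ((vt - vd) / (elv + vt)) / (1 - lam * u)
        t_end = tau * (1 + np.arange(400))
        t_insp = t_end - tau
        F_I = 0.05 + np.real(0.02 * np.exp(1j * w * t_insp))
        F_ET = 0.05 + np.real(H * 0.02 * np.exp(1j * w * t_end))
        tr = BreathTrace(
            t_insp=t_insp, t_end=t_end, F_I=F_I, F_ET=F_ET,
            period_T=T, VT=vt, RR=RR, V_D=vd,
        )
        res = recover_ist(tr, warmup_periods=1.0)
        assert res.ELV == pytest.approx(elv, rel=1e-9)
        assert res.Qp == pytest.approx(0.0, abs=1e-6)

    def test_homogeneous_lung_ratio_near_unity(self, sim_settings):
        s = sim_settings
        lung = build_lung(900, 150, 3400, 0.0, 0.0, 50)
        res = {}
        for T in (180.0, 60.0):
            tr = simulate(lung, s.forcing(T, 300, 25))
            res[T] = recover_ist(tr, warmup_periods=s.warmup_periods[T])
        h = heterogeneity_ratios(res[180.0], res[60.0])
        assert 0.98 <= h.h_ratio_v <= 1.02
        assert 0.98 <= h.h_ratio_p <= 1.02

    def test_infeasible_amplitude_ratio_rejected(self):
        big = SineFit(mean=0.05, amplitude=0.02, phase=0.0, residual_rms=0, n_used=100)
        small = SineFit(mean=0.05, amplitude=0.01, phase=0.0, residual_rms=0, n_used=100)
        with pytest.raises(ValueError, match="no solution"):
            invert_single_compartment(small, big, VT=300, V_D=150, RR=25)

    def test_dc_gain_above_one_rejected(self):
        with pytest.raises(ValueError, match="no solution"):
            invert_dc(1.2, 800.0, VT=300, V_D=150, RR=25)


class TestHeterogeneityRatios:
    def test_equal_volumes_give_unity(self, sim_settings):
        r = _fake_result(180.0, 900.0, 3000.0)
        r2 = _fake_result(60.0, 900.0, 3000.0)
        h = heterogeneity_ratios(r, r2)
        assert h.h_ratio_v == pytest.approx(1.0)
        assert h.h_ratio_p == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        h = heterogeneity_ratios(
            _fake_result(180.0, 900.0, 2000.0), _fake_result(60.0, 600.0, 3000.0)
        )
        assert h.h_ratio_v == pytest.approx(1.5)
        assert h.h_ratio_p == pytest.approx(1.5)

    def test_argument_order_enforced(self):
        with pytest.raises(ValueError):
            heterogeneity_ratios(
                _fake_result(60.0, 900.0, 3000.0), _fake_result(180.0, 900.0, 3000.0)
            )

    def test_ratio_strictly_increases_with_true_heterogeneity(self, sim_settings):
        s = sim_settings
        ratios = []
        for lsv in (0.0, 0.5, 1.0, 1.5):
            lung = build_lung(900, 150, 3400, lsv, 0.0, 50)
            res = {}
            for T in (180.0, 60.0):
                tr = simulate(lung, s.forcing(T, 300, 25))
                res[T] = recover_ist(tr, warmup_periods=s.warmup_periods[T])
            ratios.append(heterogeneity_ratios(res[180.0], res[60.0]).h_ratio_v)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_noisy_repeats_within_ten_percent(self, measure_ist):
        """Test-retest: repeated noisy measurements of the same lung differ
        by < 10% in recovered ELV."""
        elvs = [
            measure_ist(1.0, 1.5, noise=0.005, seed=seed).y180[0]
            for seed in range(6)
        ]
        m = np.mean(elvs)
        assert np.ptp(elvs) / m < 0.10


def _fake_result(T, elv, qp):
    fit = SineFit(mean=0.05, amplitude=0.01, phase=0.0, residual_rms=0.0, n_used=100)
    from istct.ist import ISTResult

    return ISTResult(
        period_T=T, ELV=elv, Qp=qp, V_D=150.0, insp_fit=fit, exp_fit=fit, Qp_mean=qp
    )
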