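"""Tests of the multi-compartment tidal tracer simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from istct.ist import recover_ist
from istct.lung import (
    SineForcing,
    build_lung,
    discretize_lognormal,
    frequency_response,
    mean_gain,
    simulate,
)
from istct.settings import SimSettings


class TestDiscretizeLognormal:
    def test_degenerate_distribution_gives_equal_weights(self):
        assert np.allclose(discretize_lognormal(0.0, 10), np.ones(10))

    def test_log_weight_spread_matches_requested_sigma(self):
        # quantile midpoints slightly truncate the tails, so the sd of the
        # log-weights sits just below the nominal sigma
        w = discretize_lognormal(0.7, 200)
        sd = np.std(np.log(w) - np.mean(np.log(w)))
        assert abs(sd - 0.7) / 0.7 < 0.05

    @settings(derandomize=True, max_examples=40)
    @given(
        log_sd=st.floats(0.0, 3.0, allow_nan=False),
        n=st.integers(1, 400),
    )
    def test_weights_always_average_to_one(self, log_sd, n):
        w = discretize_lognormal(log_sd, n)
        assert w.shape == (n,)
        assert np.all(w > 0)
        assert abs(w.mean() - 1.0) < 1e-9

    @pytest.mark.parametrize("bad", [(-0.1, 5), (0.5, 0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            discretize_lognormal(*bad)


class TestBuildLung:
    def test_homogeneous_lung_has_identical_compartments(self):
        lung = build_lung(900, 150, 3400, 0.0, 0.0, 50)
        assert np.ptp(lung.V_i) == 0
        assert np.ptp(lung.s_i) == 0
        assert np.ptp(lung.q_i) == 0

    def test_totals_conserved_exactly(self):
        lung = build_lung(900, 150, 3400, 1.0, 1.5, 50)
        assert lung.elv_true == pytest.approx(900, abs=1e-9)
        assert lung.qp_true == pytest.approx(3400, abs=1e-9)
        assert np.sum(lung.s_i * lung.V_i) == pytest.approx(1.0, abs=1e-12)

    def test_ventilation_spread_monotone_in_log_sd_v(self):
        cvs = []
        for lsv in (0.0, 0.5, 1.0):
            lung = build_lung(900, 150, 3400, lsv, 0.0, 50)
            cvs.append(np.std(lung.s_i) / np.mean(lung.s_i))
        assert cvs[0] < cvs[1] < cvs[2]

    def test_perfusion_weights_decorrelated_from_ventilation(self):
        lung = build_lung(900, 150, 3400, 1.0, 1.0, 200)
        r = np.corrcoef(np.log(lung.s_i), np.log(lung.q_i))[0, 1]
        assert abs(r) < 0.2

    def test_vq_correlation_parameter_couples_the_weights(self):
        lung = build_lung(900, 150, 3400, 1.0, 1.0, 200, vq_correlation=1.0)
        r = np.corrcoef(np.log(lung.s_i), np.log(lung.q_i))[0, 1]
        assert r > 0.99


class TestSimulate:
    def test_washin_approaches_inspired_fraction_without_uptake(self):
        # constant forcing at F0 (tiny amplitude), no perfusion: the lung
        # washes in to the inspired fraction
        lung = build_lung(800, 150, 0.0, 0.0, 0.0, 1)
        f = SineForcing(period_T=1e9, F0=0.05, A=1e-12, RR=25, VT=300, n_breaths=400)
        tr = simulate(lung, f, init="zero")
        assert tr.F_ET[-1] == pytest.approx(0.05, rel=1e-6)

    def test_step_washin_follows_geometric_recursion(self):
        # with deadspace gas re-inspired at the previous end-tidal fraction,
        # the one-compartment step response is geometric with per-breath
        # ratio (ELV + V_D) / (ELV + VT)
        elv, vd, vt = 800.0, 150.0, 300.0
        lung = build_lung(elv, vd, 0.0, 0.0, 0.0, 1)
        f = SineForcing(period_T=1e9, F0=0.05, A=1e-12, RR=25, VT=vt, n_breaths=60)
        tr = simulate(lung, f, init="zero")
        ratio = (elv + vd) / (elv + vt)
        dev = 0.05 - tr.F_ET
        assert np.allclose(dev[1:] / dev[:-1], ratio, rtol=1e-9)

    def test_mass_conserved_every_breath(self):
        lung = build_lung(900, 150, 3400, 1.0, 1.5, 50)
        f = SineForcing(period_T=60, F0=0.05, A=0.02, RR=25, VT=300, n_breaths=100)
        tr = simulate(lung, f, init="zero", track_balance=True)
        b = tr.balance
        store_prev = np.concatenate([[b["store0"]], b["store"][:-1]])
        lhs = b["moles_in"] - b["moles_out"] - b["uptake"]
        rhs = b["store"] - store_prev
        scale = np.abs(b["moles_in"]).max()
        assert np.max(np.abs(lhs - rhs)) / scale < 1e-9

    def test_response_linear_in_forcing_amplitude(self):
        lung = build_lung(900, 150, 3400, 1.0, 1.5, 50)
        amps = []
        for A in (0.01, 0.02):
            f = SineForcing(period_T=60, F0=0.05, A=A, RR=25, VT=300, n_breaths=250)
            tr = simulate(lung, f)
            steady = tr.F_ET[125:]
            amps.append(np.ptp(steady))
        assert amps[1] / amps[0] == pytest.approx(2.0, abs=1e-6)

    def test_homogeneous_many_compartments_equal_single_compartment(self):
        f = SineForcing(period_T=60, F0=0.05, A=0.02, RR=25, VT=300, n_breaths=150)
        tr50 = simulate(build_lung(900, 150, 3400, 0.0, 0.0, 50), f)
        tr1 = simulate(build_lung(900, 150, 3400, 0.0, 0.0, 1), f)
        assert np.max(np.abs(tr50.F_ET - tr1.F_ET)) < 1e-9

    def test_ventilation_rejected_when_tidal_volume_below_deadspace(self):
        lung = build_lung(900, 350, 3400, 0.0, 0.0, 10)
        f = SineForcing(period_T=60, F0=0.05, A=0.02, RR=25, VT=300, n_breaths=10)
        with pytest.raises(ValueError, match="alveolar ventilation"):
            simulate(lung, f)

    @pytest.mark.parametrize("lsv", [0.5, 1.0, 1.5])
    def test_apparent_volume_grows_with_forcing_period(self, lsv, sim_settings):
        # the frequency signature of heterogeneity: the single-compartment
        # inversion sees more of the lung at slower forcing
        s = sim_settings
        lung = build_lung(900, 150, 3400, lsv, 0.0, 50)
        res = {}
        for T in (180.0, 60.0):
            tr = simulate(lung, s.forcing(T, 300, 25))
            res[T] = recover_ist(tr, warmup_periods=s.warmup_periods[T])
        assert res[180.0].ELV >= res[60.0].ELV


class TestFrequencyResponse:
    """Closed-form steady-state gains against the time-domain recursion."""

    @pytest.mark.parametrize("lsv,lsp", [(0.0, 0.0), (1.0, 1.5)])
    def test_complex_gain_matches_simulated_sinusoid_fit(self, lsv, lsp, sim_settings):
        from istct.ist import fit_sinusoid

        s = sim_settings
        lung = build_lung(900, 150, 3400, lsv, lsp, 50)
        for T in (180.0, 60.0):
            tr = simulate(lung, s.forcing(T, 300, 25))
            insp = fit_sinusoid(tr, "F_I", warmup_periods=s.warmup_periods[T])
            expf = fit_sinusoid(tr, "F_ET", warmup_periods=s.warmup_periods[T])
            H_sim = expf.complex_amp / insp.complex_amp
            H = frequency_response(lung, T, 300, 25)
            assert abs(H - H_sim) < 2e-4

    def test_mean_gain_matches_simulated_expired_mean(self, sim_settings):
        s = sim_settings
        lung = build_lung(900, 150, 3400, 1.0, 1.5, 50)
        tr = simulate(lung, s.forcing(180.0, 300, 25))
        from istct.ist import fit_sinusoid

        insp = fit_sinusoid(tr, "F_I", warmup_periods=1.0)
        expf = fit_sinusoid(tr, "F_ET", warmup_periods=1.0)
        # finite fitting window over non-integer period counts leaves a
        # small projection of the oscillation onto the mean
        assert mean_gain(lung, 300, 25) == pytest.approx(
            expf.mean / insp.mean, abs=5e-5
        )


class TestBreathTraceIO:
    def test_csv_round_trip(self, tmp_path, sim_settings):
        s = sim_settings
        lung = build_lung(900, 150, 3400, 0.5, 0.5, 20)
        tr = simulate(lung, s.forcing(60.0, 300, 25))
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = type(tr).from_csv(path, period_T=60.0, VT=300, RR=25, V_D=150)
        assert np.allclose(back.F_ET, tr.F_ET)
        assert np.allclose(back.t_end, tr.t_end)
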