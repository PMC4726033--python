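"""Curve fits: Boltzmann, biphasic decomposition, C-O rise, k_b, global MWC."""

import itertools

import numpy as np
import pytest

from bksensor.errors import DegenerateInputError, FitFailureError, InvalidArgumentError
from bksensor.fitting import (
    TraceRecord,
    average_rising_calcium,
    biphasic_model,
    decompose_biphasic,
    estimate_kb,
    fit_boltzmann,
    fit_co_rise,
    fit_mwc_global,
)
from bksensor.mwc import TenStateRates, equilibrium_open_probability
from bksensor.qmatrix import (
    ChannelEnsemble,
    Waveform,
    macroscopic_current,
    propagate,
    stationary_distribution,
)


def boltzmann(v, y_max, v_half, slope):
    return y_max / (1.0 + np.exp((v_half - v) / slope))


class TestBoltzmann:
    # generator values follow the reported mSlo1 Rf-V fit (V0.5 = 22.5 mV, s = 18.7 mV)
    V_HALF, SLOPE = 22.5, 18.7

    def test_noiseless_recovery_to_machine_tolerance(self):
        v = np.linspace(-60, 100, 12)
        y = boltzmann(v, 0.6, self.V_HALF, self.SLOPE)
        fit = fit_boltzmann(v, y, form="RfV")
        assert fit.v_half == pytest.approx(self.V_HALF, abs=1e-6)
        assert fit.slope == pytest.approx(self.SLOPE, abs=1e-6)
        assert fit.y_max == pytest.approx(0.6, abs=1e-6)

    def test_half_activation_definition(self):
        v = np.linspace(-60, 100, 15)
        fit = fit_boltzmann(v, boltzmann(v, 2.0, 10.0, 12.0))
        assert fit.predict(fit.v_half) == pytest.approx(fit.y_max / 2, rel=1e-9)

    def test_shift_equivariance(self):
        v = np.linspace(-60, 100, 12)
        y = boltzmann(v, 1.0, self.V_HALF, self.SLOPE)
        base = fit_boltzmann(v, y)
        for delta in (-35.0, 12.5):
            shifted = fit_boltzmann(v + delta, y)
            assert shifted.v_half == pytest.approx(base.v_half + delta, abs=1e-6)
            assert shifted.slope == pytest.approx(base.slope, abs=1e-6)

    def test_noisy_recovery_within_two_millivolts(self):
        rng = np.random.default_rng(5)
        v = np.linspace(-60, 100, 12)
        y = boltzmann(v, 1.0, self.V_HALF, self.SLOPE) + rng.normal(0, 0.02, v.size)
        fit = fit_boltzmann(v, y)
        assert fit.v_half == pytest.approx(self.V_HALF, abs=2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_boltzmann(np.array([0.0, 10, 20]), np.array([0.1, 0.5, 0.9]))


class TestBiphasicDecomposition:
    def _synthetic_trace(self, h1, h2, tau_f=0.2, tau_off=2.4, tau_s=10.0, baseline=50.0):
        t = np.arange(0.0, 80.0001, 0.02)
        flash = 10.0
        s = np.clip(t - flash, 0.0, None)
        y = baseline + np.where(t >= flash, biphasic_model(s, h1, h2, tau_f, tau_off, tau_s), 0.0)
        return Waveform(t, y, "current"), flash

    def test_exact_form_recovers_fast_fraction(self):
        # target proportion matches the reported mSlo1 fast fraction of 0.60
        trace, flash = self._synthetic_trace(h1=600.0, h2=400.0)
        d = decompose_biphasic(trace, flash)
        assert d.r_f == pytest.approx(0.60, abs=0.01)
        assert d.tau_f == pytest.approx(0.2, rel=0.05)
        assert d.tau_f_off == pytest.approx(2.4, rel=0.05)
        assert d.tau_s == pytest.approx(10.0, rel=0.05)
        assert d.r_f + d.r_s == pytest.approx(1.0, abs=1e-12)

    def test_pure_fast_component_gives_unit_fraction(self):
        trace, flash = self._synthetic_trace(h1=500.0, h2=0.0)
        d = decompose_biphasic(trace, flash)
        assert d.r_f == pytest.approx(1.0, abs=0.01)

    def test_matches_grid_search_oracle_on_model_current(self, flash_current_30mV, uncaging_spec):
        I, _ = flash_current_30mV
        trace = Waveform(I.t[::4], I.y[::4], "current")
        d = decompose_biphasic(trace, uncaging_spec.t_flash)

        # brute-force oracle: coarse grid over the three time constants,
        # linear least squares for the two amplitudes at each node
        pre = trace.y[trace.t < uncaging_spec.t_flash].mean()
        s = trace.t[trace.t >= uncaging_spec.t_flash] - uncaging_spec.t_flash
        dI = trace.y[trace.t >= uncaging_spec.t_flash] - pre
        best = (np.inf, None)
        for tf, toff, ts in itertools.product(
            np.geomspace(0.05, 1.5, 10), np.geomspace(0.5, 20.0, 10), np.geomspace(3.0, 40.0, 10)
        ):
            X = np.column_stack([
                biphasic_model(s, 1.0, 0.0, tf, toff, ts),
                1.0 - np.exp(-s / ts),
            ])
            coef, res, *_ = np.linalg.lstsq(X, dI, rcond=None)
            if np.any(coef < 0):
                continue
            sse = float(((X @ coef - dI) ** 2).sum())
            if sse < best[0]:
                best = (sse, coef)
        rf_oracle = best[1][0] / best[1].sum()
        assert d.r_f == pytest.approx(rf_oracle, abs=0.05)

    def test_no_flash_response_is_degenerate(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 80.0001, 0.05)
        trace = Waveform(t, 100.0 + rng.normal(0, 1.0, t.size), "current")
        with pytest.raises(DegenerateInputError):
            decompose_biphasic(trace, 10.0)

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 30.0001, 0.05)
        trace = Waveform(t, np.ones(t.size), "current")
        with pytest.raises(InvalidArgumentError):
            decompose_biphasic(trace, 10.0)


class TestCORise:
    def _rise(self, tau=0.15, i0=100.0, a=900.0, t_end=0.8, noise=0.0, seed=0):
        t = np.arange(0.0, t_end + 1e-9, 0.02)  # 50 kHz digitisation
        y = i0 + a * (1.0 - np.exp(-t / tau))
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise * a, t.size)
        return Waveform(t, y, "current")

    def test_noiseless_recovery(self):
        fit = fit_co_rise(self._rise(tau=0.15))
        assert fit.tau == pytest.approx(0.15, abs=1e-8)
        assert fit.i_max == pytest.approx(1000.0, rel=1e-8)

    def test_noisy_recovery_within_ten_percent(self):
        fit = fit_co_rise(self._rise(tau=0.15, noise=0.02, seed=11))
        assert fit.tau == pytest.approx(0.15, rel=0.10)

    def test_decaying_segment_rejected(self):
        t = np.arange(0.0, 1.0001, 0.02)
        falling = Waveform(t, 1000.0 * np.exp(-t / 0.3), "current")
        with pytest.raises(FitFailureError):
            fit_co_rise(falling)

    def test_window_including_hook_flagged_by_runs_test(self):
        # deliberately misused window: rise followed by decay (the hook)
        t = np.arange(0.0, 1.5001, 0.02)
        y = 100.0 + 900.0 * (1.0 - np.exp(-t / 0.15)) * np.exp(-t / 2.4)
        fit = fit_co_rise(Waveform(t, y, "current"))
        assert fit.runs_pvalue < 0.05


class TestAverageRisingCalcium:
    def test_linear_ramp_averages_to_midpoint(self):
        t = np.linspace(0.0, 1.0, 201)
        ca = Waveform(t, 48.30 * t, "calcium")  # ramp up to the reported peak
        assert average_rising_calcium(ca, (0.0, 1.0)) == pytest.approx(24.15, abs=1e-6)

    def test_constant_waveform(self):
        t = np.linspace(0.0, 2.0, 101)
        ca = Waveform(t, np.full(t.size, 10.0), "calcium")
        assert average_rising_calcium(ca, (0.2, 1.7)) == pytest.approx(10.0)

    def test_concave_rise_lies_between_start_and_peak(self):
        t = np.linspace(0.0, 1.0, 400)
        ca = Waveform(t, 30.0 * (1.0 - np.exp(-t / 0.2)), "calcium")
        avg = average_rising_calcium(ca, (0.0, 1.0))
        assert ca.y[0] < avg < ca.y[-1]

    def test_empty_window_rejected(self):
        t = np.linspace(0.0, 1.0, 50)
        ca = Waveform(t, np.ones(50), "calcium")
        with pytest.raises(InvalidArgumentError):
            average_rising_calcium(ca, (0.5, 0.5))


class TestEstimateKb:
    def test_round_trip_identity_holds_to_machine_precision(self):
        est = estimate_kb(tau=0.23, ca_a=14.2, k_d=9.7)
        assert est.k_b * est.tau * (est.ca_a + est.k_d) == pytest.approx(1.0, abs=1e-15)

    def test_reported_msol1_triple_is_consistent(self):
        # tau = 0.15 ms and [Ca]_a = 20.89 uM with the back-solved k_d
        # reproduce the reported k_b = 0.18 uM^-1 ms^-1
        est = estimate_kb(tau=0.15, ca_a=20.89, k_d=16.15)
        assert est.k_b == pytest.approx(0.18, abs=0.001)

    def test_saturating_ligand_limit(self):
        est = estimate_kb(tau=0.5, ca_a=40.0, k_d=0.0)
        assert est.k_b == pytest.approx(1.0 / (0.5 * 40.0), rel=1e-12)

    def test_halving_tau_doubles_kb(self):
        a = estimate_kb(tau=0.3, ca_a=20.0, k_d=5.0)
        b = estimate_kb(tau=0.15, ca_a=20.0, k_d=5.0)
        assert b.k_b == pytest.approx(2 * a.k_b, rel=1e-12)


def _make_record(truth, constants, ens, ca, v_step, noise=0.0, seed=0):
    t = np.arange(0.0, 5.0001, 0.05)
    V = Waveform(np.array([0.0, 1.0, 1.05, 5.0]), np.array([-80.0, -80.0, v_step, v_step]), "voltage")
    caw = Waveform(np.array([0.0, 5.0]), np.array([ca, ca], float), "calcium")
    p0 = stationary_distribution(truth.generator(constants, -80.0, ca))
    traj = propagate(truth, constants, V, caw, p0, dt_max=0.05)
    y = macroscopic_current(traj, ens, V).value_at(t)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise * np.max(np.abs(y)), t.size)
    return TraceRecord(ca_uM=ca, voltage=V, current=Waveform(t, y, "current"))


@pytest.fixture(scope="module")
def mwc_fit_setup(constants):
    truth = TenStateRates()
    ens = ChannelEnsemble(n=1000, g_single=258.0, e_rev=-80.0)
    init = TenStateRates(
        k_b=0.25, K_C=8.0, K_O=1.5, alpha0=0.005, beta0=11.0,
        q_alpha=1.7, q_beta=-0.3, phi=0.4,
    )
    return truth, ens, init


class TestGlobalMWCFit:
    def _surface_error(self, truth, constants, report):
        eq = truth.to_equilibrium()
        expected = np.array(
            [[equilibrium_open_probability(eq, constants, v, ca) for ca in report.po_surface_ca]
             for v in report.po_surface_v]
        )
        return float(np.max(np.abs(expected - report.po_surface)))

    def test_noiseless_round_trip_recovers_po_surface(self, constants, mwc_fit_setup):
        truth, ens, init = mwc_fit_setup
        dataset = [
            _make_record(truth, constants, ens, ca, v)
            for ca in (1.0, 10.0) for v in (-20.0, 20.0, 60.0)
        ]
        rep = fit_mwc_global(dataset, ens, init, seed=1, global_maxiter=5, global_popsize=6)
        assert self._surface_error(truth, constants, rep) < 1e-3

    def test_single_calcium_level_warns_nonidentifiable(self, constants, mwc_fit_setup):
        truth, ens, init = mwc_fit_setup
        dataset = [_make_record(truth, constants, ens, 10.0, v) for v in (-20.0, 20.0, 60.0)]
        with pytest.warns(UserWarning, match="Ca2"):
            rep = fit_mwc_global(dataset, ens, init, seed=1, global_maxiter=2, global_popsize=4)
        assert any("Ca2+" in w for w in rep.warnings)

    def test_noisy_round_trip_within_two_percent_po(self, constants, mwc_fit_setup):
        truth, ens, init = mwc_fit_setup
        dataset = [
            _make_record(truth, constants, ens, ca, v, noise=0.02, seed=7 + i)
            for i, (ca, v) in enumerate((c, v) for c in (1.0, 10.0) for v in (-20.0, 20.0, 60.0))
        ]
        rep = fit_mwc_global(dataset, ens, init, seed=2, global_maxiter=5, global_popsize=6)
        assert self._surface_error(truth, constants, rep) < 0.02
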