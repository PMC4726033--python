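"""Stepwise inverse reconstruction of local Ca2+ from BK currents."""

import numpy as np
import pytest

from bksensor.errors import IllConditionedError, InvalidArgumentError
from bksensor.mwc import MWCParameters
from bksensor.qmatrix import ChannelEnsemble, Waveform, macroscopic_current, propagate, stationary_distribution
from bksensor.reconstruction import (
    ReconstructionConfig,
    channel_number_from_steady_state,
    condition_current,
    reconstruct_ca_timecourse,
    solve_ca_at_step,
)
from bksensor.synthetic import standard_ap_scenario


@pytest.fixture(scope="module")
def scenario(constants):
    return standard_ap_scenario(constants=constants)


class TestChannelNumber:
    def test_published_cav_arithmetic(self, constants):
        # 1529 pA / (2.4 pS * 60 mV * P_o=1) -> 10618 channels
        p = MWCParameters()
        n = channel_number_from_steady_state(
            1529.0, 2.4, v_mV=100.0, e_rev=40.0, ca_steady=1000.0, model=p, constants=constants
        )
        po = 1.0  # saturating Ca at +100 mV: P_o ~ 1 in this model
        assert n == pytest.approx(10618 / po, abs=15)

    def test_single_channel_identity(self, rates, constants):
        p = stationary_distribution(rates.generator(constants, 30.0, 10.0))
        po = float(p[rates.open_indices].sum())
        i = 258e-3 * po * (30.0 - (-80.0))
        n = channel_number_from_steady_state(i, 258.0, 30.0, -80.0, 10.0, rates, constants)
        assert n == 1

    def test_round_trip_within_rounding_bound(self, rates, constants):
        p = stationary_distribution(rates.generator(constants, 30.0, 10.0))
        po = float(p[rates.open_indices].sum())
        true_n = 1234
        i_steady = true_n * 258e-3 * po * 110.0
        n = channel_number_from_steady_state(i_steady, 258.0, 30.0, -80.0, 10.0, rates, constants)
        recomputed = n * 258e-3 * po * 110.0
        assert abs(recomputed - i_steady) <= 258e-3 * 110.0 / 2

    def test_silent_ensemble_is_ill_conditioned(self, rates, constants):
        with pytest.raises(IllConditionedError):
            channel_number_from_steady_state(5.0, 258.0, -150.0, -100.0, 0.0, rates, constants)


class TestSolveStep:
    def _setup(self, rates, constants, v=20.0, ca_true=8.0, dt=0.05):
        ens = ChannelEnsemble(n=1662, g_single=258.0, e_rev=-80.0)
        p0 = stationary_distribution(rates.generator(constants, v, 2.0))
        from bksensor.reconstruction import _advance

        p1 = _advance(rates, constants, p0, v, ca_true, dt)
        target = ens.n * ens.single_channel_current(v) * float(p1[rates.open_indices].sum())
        return ens, p0, target

    @pytest.mark.parametrize("method", ["bisection", "es"])
    def test_forward_inverse_round_trip(self, rates, constants, method):
        ens, p0, target = self._setup(rates, constants)
        cfg = ReconstructionConfig(dt=0.05, method=method, tol=1e-4, ca_bounds=(1e-3, 60.0), seed=2)
        ca, p1, resid, flagged, at_bound = solve_ca_at_step(
            p0, target, 20.0, ens, rates, 0.05, cfg, constants=constants,
            rng=np.random.default_rng(2), ca_init=5.0,
        )
        assert ca == pytest.approx(8.0, rel=0.01)
        assert not flagged

    def test_zero_target_with_silent_floor_hits_lower_bound(self, rates, constants):
        ens, p0, _ = self._setup(rates, constants)
        cfg = ReconstructionConfig(dt=0.05, method="bisection", tol=1e-4, ca_bounds=(1e-3, 60.0))
        ca, _, _, _, at_bound = solve_ca_at_step(
            p0, 0.0, 20.0, ens, rates, 0.05, cfg, constants=constants
        )
        assert ca == pytest.approx(1e-3)
        assert at_bound

    def test_es_and_bisection_agree_on_random_steps(self, rates, constants):
        # cross-method oracle over 100 seeded random operating points
        rng = np.random.default_rng(42)
        ens = ChannelEnsemble(n=1662, g_single=258.0, e_rev=-80.0)
        lo, hi = 1e-3, 60.0
        diffs = []
        for _ in range(100):
            v = rng.uniform(-10.0, 60.0)
            ca_prev = rng.uniform(0.5, 30.0)
            ca_true = np.clip(ca_prev * rng.uniform(0.8, 1.25), lo, hi)
            p0 = stationary_distribution(rates.generator(constants, v, ca_prev))
            from bksensor.reconstruction import _advance

            p1 = _advance(rates, constants, p0, v, float(ca_true), 0.05)
            target = ens.n * ens.single_channel_current(v) * float(p1[rates.open_indices].sum())
            out = {}
            for method in ("bisection", "es"):
                cfg = ReconstructionConfig(dt=0.05, method=method, tol=1e-4,
                                           ca_bounds=(lo, hi), seed=7)
                out[method], *_ = solve_ca_at_step(
                    p0, target, v, ens, rates, 0.05, cfg, constants=constants,
                    rng=np.random.default_rng(7), ca_init=float(ca_prev),
                )
            diffs.append(abs(out["es"] - out["bisection"]) / max(out["bisection"], 1.0))
        assert np.quantile(diffs, 0.98) < 0.02


class TestReconstructTimecourse:
    def test_constant_calcium_returns_constant(self, rates, constants):
        ens = ChannelEnsemble(n=1662, g_single=258.0, e_rev=-80.0)
        t = np.arange(0.0, 5.0001, 0.02)
        V = Waveform(np.array([0.0, 5.0]), np.array([30.0, 30.0]), "voltage")
        Ca = Waveform(np.array([0.0, 5.0]), np.array([10.0, 10.0]), "calcium")
        p0 = stationary_distribution(rates.generator(constants, 30.0, 10.0))
        I = macroscopic_current(propagate(rates, constants, V, Ca, p0, dt_max=0.02), ens, V)
        cfg = ReconstructionConfig(dt=0.04, method="bisection", tol=1e-3, ca_bounds=(1e-3, 60.0))
        res = reconstruct_ca_timecourse(I, V, ens, rates, cfg, ca0=10.0, constants=constants)
        assert np.max(np.abs(res.ca.y - 10.0)) < 0.1

    def test_ap_round_trip_rmse_under_five_percent(self, scenario, rates, constants):
        cfg = ReconstructionConfig(dt=0.04, method="bisection", tol=1e-3, ca_bounds=(1e-3, 40.0))
        res = reconstruct_ca_timecourse(
            scenario.bk_current, scenario.voltage, scenario.ensemble, rates, cfg,
            ca0=scenario.ca0, constants=constants,
            t_start=scenario.t_start, t_stop=scenario.t_stop,
        )
        truth = scenario.local_ca.value_at(res.ca.t)
        rmse = np.sqrt(np.mean((res.ca.y - truth) ** 2))
        assert scenario.ca_peak > 20.0
        assert rmse < 0.05 * scenario.ca_peak

    def test_same_seed_reproducible_and_seed_robust(self, scenario, rates, constants):
        def run(seed):
            cfg = ReconstructionConfig(dt=0.04, method="es", tol=1e-3,
                                       ca_bounds=(1e-3, 40.0), seed=seed)
            return reconstruct_ca_timecourse(
                scenario.bk_current, scenario.voltage, scenario.ensemble, rates, cfg,
                ca0=scenario.ca0, constants=constants,
                t_start=scenario.t_start, t_stop=scenario.t_stop,
            )

        a, b, c = run(5), run(5), run(6)
        assert np.array_equal(a.ca.y, b.ca.y)
        rms = np.sqrt(np.mean((a.ca.y - c.ca.y) ** 2))
        assert rms < 0.01 * scenario.ca_peak

    def test_forward_of_inverse_reproduces_current(self, scenario, rates, constants):
        # the defining contract: replaying the forward model under the
        # accepted per-step Ca2+ values reproduces the measured current
        # within tol on every unflagged step
        from bksensor.reconstruction import _advance

        cfg = ReconstructionConfig(dt=0.04, method="bisection", tol=1e-3, ca_bounds=(1e-3, 40.0))
        res = reconstruct_ca_timecourse(
            scenario.bk_current, scenario.voltage, scenario.ensemble, rates, cfg,
            ca0=scenario.ca0, constants=constants,
            t_start=scenario.t_start, t_stop=scenario.t_stop,
        )
        times = res.ca.t
        dt = times[1] - times[0]
        p = stationary_distribution(
            rates.generator(constants, float(scenario.voltage.value_at(times[0])), scenario.ca0)
        )
        ens = scenario.ensemble
        scale = float(np.max(np.abs(scenario.bk_current.y)))
        for k in range(times.size - 1):
            v_mid = float(scenario.voltage.value_at(times[k] + dt / 2))
            p = _advance(rates, constants, p, v_mid, res.ca.y[k + 1], dt)
            i_model = ens.n * ens.single_channel_current(
                float(scenario.voltage.value_at(times[k + 1]))
            ) * float(p[rates.open_indices].sum())
            if not res.flags[k]:
                target = float(scenario.bk_current.value_at(times[k + 1]))
                assert abs(i_model - target) / max(abs(target), scale) <= cfg.tol

    def test_excessive_flagging_raises_with_partial_result(self, rates, constants):
        from bksensor.errors import ReconstructionQualityError

        ens = ChannelEnsemble(n=1662, g_single=258.0, e_rev=-80.0)
        t = np.arange(0.0, 3.0001, 0.02)
        V = Waveform(np.array([0.0, 3.0]), np.array([30.0, 30.0]), "voltage")
        # a current far above what the model can produce at any admissible Ca
        I = Waveform(t, np.full(t.size, 1e6), "current")
        cfg = ReconstructionConfig(dt=0.05, method="bisection", tol=1e-3, ca_bounds=(1e-3, 60.0))
        with pytest.raises(ReconstructionQualityError) as exc:
            reconstruct_ca_timecourse(I, V, ens, rates, cfg, ca0=1.0, constants=constants)
        assert exc.value.result is not None
        assert exc.value.result.flagged_fraction > 0.2


class TestConditionCurrent:
    def test_smoothing_attenuates_multiplicative_noise(self, scenario):
        rng = np.random.default_rng(3)
        noisy = Waveform(
            scenario.bk_current.t,
            scenario.bk_current.y * (1 + rng.normal(0, 0.02, scenario.bk_current.t.size)),
            "current",
        )
        sm = condition_current(noisy, window=25)
        m = (sm.t > 6.0) & (sm.t < 15.0)  # the steady test-step stretch
        raw_err = np.std((noisy.y - scenario.bk_current.y)[m])
        sm_err = np.std((sm.y - scenario.bk_current.y)[m])
        assert sm_err < 0.4 * raw_err

    def test_rejects_non_current(self):
        wf = Waveform(np.linspace(0, 1, 30), np.ones(30), "calcium")
        with pytest.raises(InvalidArgumentError):
            condition_current(wf)
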