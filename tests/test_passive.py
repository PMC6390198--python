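"""Passive properties: quadratic I-V fit, tau, sag/rebound, V_m."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entophys.exceptions import InsufficientDataError, UndefinedSagError
from entophys.passive import (
    average_sweeps,
    fit_input_resistance,
    membrane_time_constant,
    resting_potential,
    sag_and_rebound,
)

from conftest import make_sweep

SR = 20000.0


class TestInputResistance:
    def test_linear_cell_recovers_slope_and_zero_curvature(self):
        di = np.array([-300, -200, -100, 100.0])
        fit = fit_input_resistance(list(zip(di, 0.05 * di)))
        assert fit.r_n0 == pytest.approx(50.0, rel=1e-12)
        assert fit.c_ar == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_cell_recovered_to_machine_precision(self):
        """Slope 0.138 mV/pA (138 MOhm) with a small rectification term is
        reproduced exactly; cross-checked against the closed-form normal
        equations."""
        di = np.arange(-300.0, 101.0, 50.0)
        r_mv_per_pa, c = 0.138, 1e-4
        dv = r_mv_per_pa * di + c * di**2
        fit = fit_input_resistance(list(zip(di, dv)))
        assert fit.r_n0 == pytest.approx(138.0, rel=1e-9)
        assert fit.c_ar == pytest.approx(c, rel=1e-9)

        design = np.column_stack([di, di**2])
        beta = np.linalg.solve(design.T @ design, design.T @ dv)
        assert fit.r_n0 / 1000.0 == pytest.approx(beta[0], rel=1e-9)
        assert fit.c_ar == pytest.approx(beta[1], rel=1e-9)

    def test_noisy_points_stay_within_three_standard_errors(self):
        """Monte-Carlo: estimates stay within 3 SE of truth (the SE taken
        from the closed-form least-squares covariance)."""
        rng = np.random.default_rng(7)
        di = np.arange(-300.0, 101.0, 50.0)
        r, c, sigma = 0.138, 1e-4, 0.5
        design = np.column_stack([di, di**2])
        cov = sigma**2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        bad = 0
        for _ in range(100):
            dv = r * di + c * di**2 + rng.normal(0, sigma, len(di))
            fit = fit_input_resistance(list(zip(di, dv)))
            if (abs(fit.r_n0 / 1000.0 - r) > 3 * se[0]
                    or abs(fit.c_ar - c) > 3 * se[1]):
                bad += 1
        assert bad <= 5  # 3 SE ~ 99.7 % coverage per coefficient

    def test_insufficient_points_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_input_resistance([(-100.0, -5.0), (100.0, 5.0)])
        with pytest.raises(InsufficientDataError):
            fit_input_resistance([(-100.0, -5.0)] * 5)


def _biexp_step_sweep(taus_ms, amps_mv, v0=-70.0, sr=SR, onset=0.1,
                      dur=1.0):
    """Hyperpolarizing onset following a sum of exponential relaxations."""
    n = int((onset + dur + 0.4) * sr)
    t = np.arange(n) / sr
    v = np.full(n, v0)
    onset_i = int(onset * sr)
    tt = (t[onset_i:] - onset) * 1000.0
    resp = np.zeros_like(tt)
    for tau, a in zip(taus_ms, amps_mv):
        resp += a * (1.0 - np.exp(-tt / tau))
    v[onset_i:] = v0 + resp
    return make_sweep(v, sample_rate=sr, stim_onset=onset,
                      stim_offset=onset + dur, step_amplitude=-300.0)


class TestTau:
    def test_single_exponential_recovers_its_tau(self):
        sweep = _biexp_step_sweep([20.0], [-13.0])
        fit = membrane_time_constant(sweep)
        assert fit.tau == pytest.approx(20.0, rel=0.02)

    def test_double_exponential_returns_the_larger_component(self):
        """tau = {5, 25} ms with amplitudes {-3, -10} mV -> 25 ms."""
        sweep = _biexp_step_sweep([5.0, 25.0], [-3.0, -10.0])
        fit = membrane_time_constant(sweep)
        assert fit.tau == pytest.approx(25.0, rel=0.02)

    def test_depolarizing_step_is_rejected(self):
        sweep = _biexp_step_sweep([20.0], [-13.0])
        sweep.step_amplitude = 100.0
        with pytest.raises(ValueError):
            membrane_time_constant(sweep)


class TestSagRebound:
    def _sag_sweep(self, v_base, v_min, v_ss, rebound_to=None, sr=SR):
        n = int(1.8 * sr)
        t = np.arange(n) / sr
        v = np.full(n, v_base)
        on, off = int(0.2 * sr), int(1.2 * sr)
        # fast drop to v_min, relax to v_ss
        seg = np.arange(on, off)
        tt = (seg - on) / sr * 1000.0
        v[seg] = v_ss + (v_min - v_ss) * np.exp(-np.maximum(tt - 30, 0)
                                                / 80.0)
        v[on:on + int(0.03 * sr)] = np.linspace(v_base, v_min,
                                                int(0.03 * sr))
        if rebound_to is not None:
            post = np.arange(off, off + int(0.2 * sr))
            v[post] = rebound_to
            v[off + int(0.2 * sr):] = v_base
        else:
            v[off:] = v_base
        return make_sweep(v, sample_rate=sr, stim_onset=0.2,
                          stim_offset=1.2, step_amplitude=-300.0)

    def test_hand_computed_sag_ratio(self):
        """Baseline -65, minimum -95, steady state -80: sag = 15/30."""
        res = sag_and_rebound(self._sag_sweep(-65.0, -95.0, -80.0))
        assert res.sag_ratio == pytest.approx(0.5, abs=0.01)

    def test_no_sag_gives_ratio_one_and_flat_return_gives_zero_rebound(self):
        res = sag_and_rebound(self._sag_sweep(-65.0, -95.0, -95.0))
        assert res.sag_ratio == pytest.approx(1.0, abs=0.01)
        assert res.rebound == pytest.approx(0.0, abs=0.01)

    def test_rebound_is_overshoot_above_baseline(self):
        res = sag_and_rebound(self._sag_sweep(-65.0, -95.0, -80.0,
                                              rebound_to=-60.0))
        assert res.rebound == pytest.approx(5.0, abs=0.05)

    def test_depolarized_step_has_undefined_sag(self):
        n = int(1.8 * SR)
        v = np.full(n, -65.0)
        v[int(0.2 * SR):int(1.2 * SR)] = -55.0  # above baseline
        sweep = make_sweep(v, stim_onset=0.2, stim_offset=1.2,
                           step_amplitude=-300.0)
        with pytest.raises(UndefinedSagError):
            sag_and_rebound(sweep)


class TestRestingPotential:
    def test_constant_trace(self):
        sweep = make_sweep(np.full(int(2 * SR), -70.0),
                           sweep_kind="spontaneous", stim_onset=0.0)
        assert resting_potential(sweep) == pytest.approx(-70.0)

    def test_zero_mean_sine_does_not_shift_vm(self):
        n = int(2 * SR)
        t = np.arange(n) / SR
        v = -70.0 + np.sin(2 * np.pi * 5.0 * t)  # integer periods over 2 s
        sweep = make_sweep(v, sweep_kind="spontaneous", stim_onset=0.0)
        assert resting_potential(sweep) == pytest.approx(-70.0, abs=1e-6)

    def test_nonzero_current_is_rejected(self):
        sweep = make_sweep(np.full(int(SR), -70.0),
                           sweep_kind="spontaneous", stim_onset=0.0,
                           current=np.full(int(SR), 50.0))
        with pytest.raises(ValueError):
            resting_potential(sweep)


class TestAverageSweeps:
    @given(st.integers(min_value=1, max_value=6))
    @settings(max_examples=10, deadline=None)
    def test_average_of_identical_sweeps_is_identity(self, k):
        sweep = _biexp_step_sweep([20.0], [-13.0])
        avg = average_sweeps([sweep] * k)
        assert np.allclose(avg.voltage, sweep.voltage)

    def test_paired_perturbations_cancel(self):
        base = _biexp_step_sweep([20.0], [-13.0])
        noise = np.sin(np.arange(len(base.voltage)))
        up = make_sweep(base.voltage + noise, stim_onset=base.stim_onset,
                        stim_offset=base.stim_offset, step_amplitude=-300.0)
        dn = make_sweep(base.voltage - noise, stim_onset=base.stim_onset,
                        stim_offset=base.stim_offset, step_amplitude=-300.0)
        avg = average_sweeps([up, dn])
        assert np.allclose(avg.voltage, base.voltage, atol=1e-12)
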