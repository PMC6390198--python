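"""AP detection, waveform features and train statistics."""

import numpy as np
import pytest

from entophys.config import AnalysisConfig
from entophys.exceptions import NonUniformSamplingError
from entophys.recording import Sweep
from entophys.spikes import (
    ap_waveform_features,
    detect_action_potentials,
    spike_train_features,
)

from conftest import make_sweep

SR = 20000.0
DT = 1.0 / SR


def _insert_spike(v, t, sr, at_s, peak=40.0, base=-70.0, width_ms=1.0):
    """Paste a triangular spike with its apex at ``at_s``."""
    half = int(round(width_ms / 1000.0 * sr))
    apex = int(round(at_s * sr))
    for k in range(-half, half + 1):
        frac = 1.0 - abs(k) / half
        idx = apex + k
        if 0 <= idx < len(v):
            v[idx] = max(v[idx], base + frac * (peak - base))
    return apex


class TestDetection:
    def test_flat_trace_has_no_spikes(self):
        sweep = make_sweep(np.full(int(SR), -70.0))
        assert len(detect_action_potentials(sweep)) == 0

    def test_inserted_spikes_are_found_at_their_apices(self):
        v = np.full(int(SR), -70.0)
        times = [0.1, 0.25, 0.4, 0.62, 0.9]
        apices = [_insert_spike(v, None, SR, at) for at in times]
        peaks = detect_action_potentials(make_sweep(v))
        assert len(peaks) == 5
        assert np.all(np.abs(peaks - np.array(apices)) <= 1)

    def test_refractory_window_merges_near_coincident_spikes(self):
        v = np.full(int(SR), -70.0)
        _insert_spike(v, None, SR, 0.5, width_ms=0.4)
        _insert_spike(v, None, SR, 0.501, width_ms=0.4)  # 1 ms later
        peaks = detect_action_potentials(make_sweep(v))
        assert len(peaks) == 1

    def test_subthreshold_bump_is_not_a_spike(self):
        v = np.full(int(SR), -70.0)
        _insert_spike(v, None, SR, 0.5, peak=-30.0)  # below min_peak
        assert len(detect_action_potentials(make_sweep(v))) == 0

    def test_non_uniform_sampling_is_rejected(self):
        t = np.cumsum(np.r_[0.0, np.full(999, DT)])
        t[500:] += 5 * DT  # a gap
        with pytest.raises(NonUniformSamplingError):
            Sweep(time=t, voltage=np.full(1000, -70.0),
                  current=np.zeros(1000), sample_rate=SR,
                  stim_onset=0.01, stim_offset=0.04)


class TestWaveform:
    def _logistic_sweep(self, scale_ms=0.25):
        """Sigmoid upstroke with an analytically known curvature maximum."""
        n = int(0.2 * SR)
        t = np.arange(n) / SR
        t0 = 0.1
        s = scale_ms / 1000.0
        amp = 118.32  # so the curvature-max voltage sits near -45 mV
        v = -70.0 + amp / (1.0 + np.exp(-(t - t0) / s))
        # add a decay after the plateau so the peak is a local maximum
        after = t > t0 + 10 * s
        v[after] = v[after][0] - (t[after] - t[after][0]) * 2000.0
        return make_sweep(v), t0, s, amp

    def test_threshold_sits_at_the_analytic_curvature_maximum(self):
        """For a logistic upstroke the second derivative peaks where the
        logistic equals (3 - sqrt(3))/6 of its amplitude, at
        t* = t0 - ln((3+sqrt(3))/(3-sqrt(3))) * s below the midpoint."""
        sweep, t0, s, amp = self._logistic_sweep()
        sigma_star = (3.0 - np.sqrt(3.0)) / 6.0
        t_star = t0 + s * np.log(sigma_star / (1.0 - sigma_star))
        v_star = -70.0 + amp * sigma_star

        feats = ap_waveform_features(sweep, 0, region="LEC")
        assert abs(feats.threshold_time - t_star) <= 1.0 / SR
        # the smoothed voltage at the curvature maximum carries a small
        # local-polynomial bias on this slow logistic rise
        assert feats.threshold == pytest.approx(v_star, abs=2.0)

    def test_half_width_of_triangular_spike_is_its_half_base(self):
        """A symmetric triangular spike rising over 1 ms and falling over
        1 ms has width 1.0 ms at 50 % of its threshold-to-peak height."""
        v = np.full(int(0.4 * SR), -70.0)
        _insert_spike(v, None, SR, 0.2, peak=40.0, width_ms=1.0)
        feats = ap_waveform_features(make_sweep(v), 0, region="LEC")
        assert feats.half_width == pytest.approx(1.0, abs=0.15)
        assert feats.amplitude == pytest.approx(40.0 - feats.threshold,
                                                abs=1e-9)

    def test_fahp_and_dap_read_from_a_constructed_trace(self):
        """Post-spike trough at -53 mV followed by a hump at -50.8 mV gives
        fAHP -53 and DAP 2.2 mV."""
        sr = SR
        v = np.full(int(0.4 * sr), -70.0)
        apex = _insert_spike(v, None, sr, 0.2, peak=40.0, width_ms=0.8)
        # repolarize from the peak straight into a trough at -53 mV 2 ms
        # after the peak, hump to -50.8 mV by 8 ms, then decay
        trough = apex + int(0.002 * sr)
        hump = apex + int(0.008 * sr)
        v[apex + 1:trough] = np.linspace(40.0, -53.0, trough - apex - 1)
        v[trough:hump] = np.linspace(-53.0, -50.8, hump - trough)
        v[hump:hump + int(0.01 * sr)] = np.linspace(
            -50.8, -65.0, int(0.01 * sr))
        v[hump + int(0.01 * sr):] = -65.0
        feats = ap_waveform_features(make_sweep(v), 0, region="MEC")
        assert feats.fahp == pytest.approx(-53.0, abs=0.1)
        assert feats.dap == pytest.approx(2.2, abs=0.1)

    def test_dap_absent_when_a_doublet_follows(self):
        v = np.full(int(0.4 * SR), -70.0)
        _insert_spike(v, None, SR, 0.2, width_ms=0.8)
        _insert_spike(v, None, SR, 0.208, width_ms=0.8)  # 8 ms later
        feats = ap_waveform_features(make_sweep(v), 0, region="MEC")
        assert feats.dap is None
        assert "dap_obscured_by_doublet" in feats.flags

    def test_fahp_not_measured_outside_mec(self):
        v = np.full(int(0.4 * SR), -70.0)
        _insert_spike(v, None, SR, 0.2)
        feats = ap_waveform_features(make_sweep(v), 0, region="LEC")
        assert feats.fahp is None and feats.dap is None


class TestTrains:
    def _train(self, isis_ms, start=0.2):
        v = np.full(int(1.2 * SR), -70.0)
        at = start
        times = [at]
        for isi in isis_ms:
            at += isi / 1000.0
            times.append(at)
        for tt in times:
            _insert_spike(v, None, SR, tt, width_ms=0.8)
        return make_sweep(v, step_amplitude=200.0)

    def test_regular_train_has_unit_ratios(self):
        tf = spike_train_features(self._train([20] * 8))
        assert tf.isi1_over_isi2 == pytest.approx(1.0, abs=0.01)
        assert tf.adaptation_ratio == pytest.approx(1.0, abs=0.01)

    def test_geometric_isis_give_expected_ratios(self):
        """ISIs 10, 20, 40, 80 ms: ISI1/ISI2 = 0.5, first/last = 0.125."""
        tf = spike_train_features(self._train([10, 20, 40, 80]))
        assert tf.isi1_over_isi2 == pytest.approx(0.5, abs=0.01)
        assert tf.adaptation_ratio == pytest.approx(0.125, abs=0.005)
        assert np.allclose(tf.isi, [10, 20, 40, 80], atol=0.2)

    def test_subzero_spike_has_no_width_at_0mV(self):
        v = np.full(int(1.2 * SR), -70.0)
        _insert_spike(v, None, SR, 0.3, peak=-5.0)  # detected, stays < 0
        _insert_spike(v, None, SR, 0.5)
        cfg = AnalysisConfig()
        tf = spike_train_features(make_sweep(v, step_amplitude=200.0), cfg)
        assert tf.n_spikes == 2
        assert np.isnan(tf.per_ap_width_at_0mv[0])
        assert np.isfinite(tf.per_ap_width_at_0mv[1])

    def test_too_few_spikes_yield_an_empty_result_with_reason(self):
        tf = spike_train_features(self._train([]))
        assert tf.n_spikes == 1
        assert tf.reason is not None
        assert tf.isi1_over_isi2 is None
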