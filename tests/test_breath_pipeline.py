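"""Breath pipeline: calibration, flow reconstruction, segmentation, metrics."""

import dataclasses

import numpy as np
import pytest

from frugalspiro.breath_pipeline import (
    CalibrationError,
    NoBreathError,
    PipelineConfig,
    RawTrace,
    calibrate_offset,
    compute_metrics,
    counts_to_flow,
    measure_duration,
    process_trace,
    segment_exhalation,
)
from frugalspiro.synthetic_data import (
    NoiseModel,
    StrokeSpec,
    Waveform,
    pump_stroke_flow,
    simulate_acquisition,
)
from frugalspiro.venturi_core import M3S_PER_LPM

from conftest import make_flow_trace

CLEAN = NoiseModel(voltage_noise_sigma=0.0, quantization=False, seed=0)


def forward(waveform, noise=CLEAN):
    """Run a waveform through the default forward chain."""
    return simulate_acquisition(waveform, noise=noise)


class TestCalibration:
    def test_constant_trace_offset(self):
        from frugalspiro.acquisition_model import counts_to_voltage

        trace = RawTrace(np.full(2000, 200))
        assert calibrate_offset(trace) == pytest.approx(counts_to_voltage(200))

    def test_noisy_baseline_recovered_within_1_mv(self):
        wave = pump_stroke_flow(StrokeSpec(duration_s=1.0))
        trace = forward(wave, NoiseModel(voltage_noise_sigma=0.005,
                                         quantization=False, seed=42))
        assert calibrate_offset(trace) == pytest.approx(0.2, abs=1e-3)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="baseline window"):
            calibrate_offset(RawTrace(np.zeros(100)))

    def test_breathing_during_baseline_fails(self):
        # no quiet lead-in: the stroke starts immediately
        wave = pump_stroke_flow(StrokeSpec(duration_s=1.2, lead_in_s=0.0))
        trace = forward(wave)
        with pytest.raises(CalibrationError):
            calibrate_offset(trace)


class TestCountsToFlow:
    def test_all_baseline_trace_is_zero_flow(self):
        zero_wave = Waveform(np.arange(3000) / 1000.0, np.zeros(3000), 1000.0)
        trace = forward(zero_wave)
        flow = counts_to_flow(trace)
        assert np.allclose(flow.flow_lpm, 0.0)

    def test_constant_plateau_round_trip_within_half_percent(self):
        # 1 s quiet, then a 200 L/min plateau pushed through the exact
        # forward chain (no noise/quantization/filter): chain inversion
        # plus one friction fixed-point pass recovers the plateau
        q = np.concatenate([np.zeros(1000), np.full(3000, 200.0 * M3S_PER_LPM)])
        wave = Waveform(np.arange(q.size) / 1000.0, q, 1000.0)
        trace = forward(wave)
        cfg = PipelineConfig(filter_enabled=False)
        flow = counts_to_flow(trace, cfg=cfg)
        plateau = flow.flow_lpm[2000:3500]
        assert np.max(np.abs(plateau - 200.0)) / 200.0 < 0.005

    def test_disabling_drag_correction_biases_plateau_high(self):
        q = np.concatenate([np.zeros(1000), np.full(3000, 200.0 * M3S_PER_LPM)])
        wave = Waveform(np.arange(q.size) / 1000.0, q, 1000.0)
        trace = forward(wave)
        with_drag = counts_to_flow(trace, cfg=PipelineConfig(filter_enabled=False))
        without = counts_to_flow(
            trace, cfg=PipelineConfig(filter_enabled=False, drag_correction=False)
        )
        assert np.mean(without.flow_lpm[2000:3500]) > np.mean(
            with_drag.flow_lpm[2000:3500]
        )

    def test_clamped_samples_recorded(self):
        rng = np.random.default_rng(1)
        zero_wave = Waveform(np.arange(3000) / 1000.0, np.zeros(3000), 1000.0)
        trace = forward(zero_wave, NoiseModel(voltage_noise_sigma=0.005,
                                              quantization=False, seed=1))
        flow = counts_to_flow(trace, cfg=PipelineConfig(filter_enabled=False))
        # baseline noise straddles the offset: about half the samples clamp
        assert flow.clamped_sample_count > 0


def triangle_flow():
    """Symmetric triangle: peak 100 L/min at sample 1000, 500-sample flanks."""
    i = np.arange(2001)
    f = np.maximum(0.0, 100.0 * (1.0 - np.abs(i - 1000) / 500.0))
    return make_flow_trace(f)


class TestSegmentation:
    def test_triangle_crossings_match_brute_force(self):
        flow = triangle_flow()
        (start, end), peak = segment_exhalation(flow)
        # oracle: scan every sample against the 4% threshold
        f = flow.flow_lpm
        thr = 0.04 * f.max()
        keep = np.nonzero(f >= thr)[0]
        assert peak == 1000
        assert abs(start - keep[0]) <= 1
        assert abs(end - keep[-1]) <= 1

    def test_all_zero_flow_is_no_breath(self):
        with pytest.raises(NoBreathError):
            segment_exhalation(make_flow_trace(np.zeros(1000)))

    def test_higher_threshold_shrinks_segment_symmetrically(self):
        flow = triangle_flow()
        cfg = PipelineConfig(segmentation_threshold_fraction=0.5)
        (start, end), _ = segment_exhalation(flow, cfg)
        # f >= 50 iff |i - 1000| <= 250
        assert start == 750
        assert end == 1250

    def test_boundary_touch_warns(self):
        f = np.full(1000, 50.0)  # never falls below threshold
        with pytest.warns(UserWarning, match="boundary"):
            segment_exhalation(make_flow_trace(f))

    def test_first_peak_wins_on_ties(self):
        f = np.zeros(1000)
        f[300:320] = 100.0
        f[600:620] = 100.0
        _, peak = segment_exhalation(make_flow_trace(f))
        assert peak == 300


class TestMetrics:
    def test_rectangle_one_second(self):
        f = np.zeros(3000)
        f[1000:2000] = 120.0  # 2 L/s
        flow = make_flow_trace(f)
        seg, peak = segment_exhalation(flow)
        res = compute_metrics(flow, seg, peak)
        assert res.pef_lpm == pytest.approx(120.0)
        assert res.fvc_l == pytest.approx(2.0, rel=3e-3)
        assert res.fev1_l == res.fvc_l  # duration just under 1 s
        assert res.duration_s == pytest.approx(1.0, abs=2e-3)

    def test_rectangle_half_second_clamps_fev1(self):
        f = np.zeros(3000)
        f[1000:1500] = 180.0  # 3 L/s
        flow = make_flow_trace(f)
        seg, peak = segment_exhalation(flow)
        res = compute_metrics(flow, seg, peak)
        assert res.fvc_l == pytest.approx(1.5, rel=3e-3)
        assert res.fev1_l == res.fvc_l
        assert res.pef_lpm == pytest.approx(180.0)

    def test_half_sine_closed_form(self):
        # FVC = 2 Qp T / pi, FEV1 = Qp (T/pi) (1 - cos(pi/T)) at Qp = 4 L/s
        T = 1.5
        t = np.arange(int(T * 1000) + 1) / 1000.0
        f_ls = 4.0 * np.sin(np.pi * t / T)
        flow = make_flow_trace(f_ls * 60.0)
        res = compute_metrics(flow, (0, f_ls.size - 1))
        assert res.fvc_l == pytest.approx(2 * 4.0 * T / np.pi, rel=1e-3)
        expected_fev1 = 4.0 * (T / np.pi) * (1 - np.cos(np.pi * 1.0 / T))
        assert res.fev1_l == pytest.approx(expected_fev1, rel=1e-3)
        assert res.fev1_l < res.fvc_l

    def test_invalid_segment_rejected(self):
        flow = triangle_flow()
        with pytest.raises(ValueError):
            compute_metrics(flow, (500, 5000))


class TestDuration:
    def test_rectangle_duration(self):
        f = np.zeros(3000)
        f[1000:2000] = 100.0
        assert measure_duration(make_flow_trace(f)) == pytest.approx(1.0, abs=2e-3)

    def test_simulated_stroke_duration_within_10_percent(self):
        wave = pump_stroke_flow(StrokeSpec(duration_s=0.8))
        flow = make_flow_trace(wave.flow_lpm)
        assert measure_duration(flow) == pytest.approx(0.8, rel=0.10)

    def test_duration_invariant_to_flow_scaling(self):
        wave = pump_stroke_flow(StrokeSpec(duration_s=1.1))
        d1 = measure_duration(make_flow_trace(wave.flow_lpm))
        d2 = measure_duration(make_flow_trace(wave.flow_lpm * 3.0))
        assert d1 == d2


class TestEndToEnd:
    @pytest.mark.parametrize("volume", [0.5, 1.0, 2.0, 4.0])
    def test_noise_free_volume_recovery_within_half_percent(self, volume):
        wave = pump_stroke_flow(StrokeSpec(volume_l=volume, duration_s=1.2))
        res = process_trace(forward(wave))
        assert res.fvc_l == pytest.approx(volume, rel=5e-3)

    def test_fev1_never_exceeds_fvc(self):
        for dur, seed in [(0.4, 1), (1.0, 2), (1.8, 3), (2.4, 4)]:
            wave = pump_stroke_flow(StrokeSpec(duration_s=dur))
            res = process_trace(forward(wave, NoiseModel(seed=seed)))
            assert res.fev1_l <= res.fvc_l
            if res.duration_s > 1.0:
                assert res.fev1_l < res.fvc_l

    def test_filter_is_zero_phase(self):
        wave = pump_stroke_flow(StrokeSpec(duration_s=1.2))
        trace = forward(wave)
        res_f = process_trace(trace, cfg=PipelineConfig(filter_enabled=True))
        res_u = process_trace(trace, cfg=PipelineConfig(filter_enabled=False))
        assert abs(res_f.peak_index - res_u.peak_index) < 2

    def test_volume_linearity(self):
        cfg = PipelineConfig(filter_enabled=False)
        base = pump_stroke_flow(StrokeSpec(volume_l=1.0, duration_s=1.5))
        scaled = dataclasses.replace(base, flow_m3s=base.flow_m3s * 2.0)
        r1 = process_trace(forward(base), cfg=cfg)
        r2 = process_trace(forward(scaled), cfg=cfg)
        assert r2.fvc_l == pytest.approx(2.0 * r1.fvc_l, rel=1e-2)
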