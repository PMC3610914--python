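"""Generator module: event process, rendering, dose model, calibration."""

from dataclasses import replace

import numpy as np
import pytest

from calcosc import (
    DetectionParams,
    DoseModulation,
    PhaseProtocol,
    SimulationConfig,
    TransientKernel,
    analyze_trace,
    apply_modulations,
    calibrate_peak,
    hill_multiplier,
    render_trace,
    sample_event_times,
    simulate_condition,
    simulate_recordings,
    split_phases,
)

EXPECTED_PRESETS = {
    "baseline_d5",
    "nmda_100",
    "mk801_40",
    "ketamine_1",
    "ketamine_3",
    "ketamine_10",
    "ketamine_30",
    "ketamine_100",
    "ketamine_300",
    "ketamine_1000",
    "ketamine_3000",
    "reversal_nmda_100",
    "reversal_nmda_300",
    "reversal_nmda_1000",
}


class TestSampleEventTimes:
    def test_zero_rate_yields_no_events(self):
        assert sample_event_times(0.0, 1000.0, 15.0, 1) == []

    def test_poisson_mean_count_without_dead_time(self):
        # mean count over many seeds must match the Poisson expectation
        rate, duration = 0.042, 1e5
        counts = [
            len(sample_event_times(rate, duration, 0.0, seed)) for seed in range(100)
        ]
        expected = rate * duration
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_refractory_enforced(self):
        for seed in range(10):
            times = sample_event_times(0.5, 2000.0, 30.0, seed)
            gaps = np.diff(times)
            assert (gaps >= 30.0).all()

    def test_times_strictly_increasing_within_duration(self):
        times = sample_event_times(0.1, 500.0, 5.0, 3)
        assert all(0 <= t < 500.0 for t in times)
        assert (np.diff(times) > 0).all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_event_times(-1.0, 10.0, 0.0, 0)


class TestRenderTrace:
    def test_quiet_noiseless_trace_is_flat(self):
        cfg = SimulationConfig(duration=50, noise_sd=0.0, drift_amp=0.0)
        tr = render_trace([], cfg)
        assert np.allclose(tr.values, cfg.f_base)

    def test_single_transient_peak_height(self):
        cfg = SimulationConfig(
            duration=100, noise_sd=0.0, drift_amp=0.0,
            kernel=TransientKernel(peak_df=50.0),
        )
        tr = render_trace([40.0], cfg)
        peak = tr.values.max()
        # sampled maximum within one sample's discretization of the true peak
        s_peak = cfg.kernel.peak_time
        lower = cfg.f_base + min(
            cfg.kernel.evaluate(np.array([np.floor(s_peak)]))[0],
            cfg.kernel.evaluate(np.array([np.ceil(s_peak)]))[0],
        )
        assert lower <= peak <= cfg.f_base + 50.0

    def test_kernel_zero_at_onset_and_decays(self):
        k = TransientKernel(peak_df=10.0)
        assert k.evaluate(np.array([0.0]))[0] == 0.0
        assert k.evaluate(np.array([-5.0]))[0] == 0.0
        assert k.evaluate(np.array([200.0]))[0] < 1e-9

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(duration=120, seed=42)
        a = render_trace([10.0, 60.0], cfg)
        b = render_trace([10.0, 60.0], cfg)
        assert np.array_equal(a.values, b.values)


class TestHillMultiplier:
    MOD = DoseModulation(half_conc=100.0, hill_slope=1.0, max_effect=1.0)

    def test_zero_concentration_is_neutral(self):
        assert hill_multiplier(0.0, self.MOD) == 1.0

    def test_midpoint_identity(self):
        assert hill_multiplier(100.0, self.MOD) == pytest.approx(0.5)

    def test_inhibition_monotone_to_floor(self):
        concs = [1, 10, 100, 1000, 1e5, 1e7]
        vals = [hill_multiplier(c, self.MOD) for c in concs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1 - self.MOD.max_effect, abs=1e-4)

    def test_potentiation_bounded_above(self):
        mod = DoseModulation(100.0, 2.0, 3.0, direction="potentiate")
        vals = [hill_multiplier(c, mod) for c in [1, 100, 1e6]]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] <= 1 + mod.max_effect

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_multiplier(-1.0, self.MOD)


class TestApplyModulations:
    def test_empty_modulations_leave_config_unchanged(self, presets):
        base = presets["baseline_d5"]
        assert apply_modulations(base) == base.base_config

    def test_complete_abolition_preset_has_zero_rate(self, presets):
        cfg = apply_modulations(presets["ketamine_3000"])
        assert cfg.event_rate == 0.0

    def test_full_reversal_restores_rate_and_peak(self, presets):
        base = presets["baseline_d5"].base_config
        cfg = apply_modulations(presets["reversal_nmda_1000"])
        assert cfg.event_rate >= base.event_rate
        assert cfg.kernel.peak_df >= base.kernel.peak_df

    def test_drugs_compose_multiplicatively(self, presets):
        ket = apply_modulations(presets["ketamine_1000"])
        rev = presets["reversal_nmda_300"]
        only_nmda = replace(rev, modulations=tuple(m for m in rev.modulations if m[0] == "nmda"))
        nmda_cfg = apply_modulations(only_nmda)
        both = apply_modulations(rev)
        base = presets["baseline_d5"].base_config
        expected_rate = ket.event_rate * nmda_cfg.event_rate / base.event_rate
        assert both.event_rate == pytest.approx(expected_rate)


class TestCalibratePeak:
    def test_fixed_point_at_target(self, baseline, params):
        cfg = baseline.base_config
        peak = calibrate_peak(2.01, cfg, params)
        probe = replace(
            cfg, duration=120.0, noise_sd=0.0, drift_amp=0.0,
            kernel=replace(cfg.kernel, peak_df=peak),
        )
        s = analyze_trace(render_trace([60.0], probe), params)
        assert s.amplitude == pytest.approx(2.01, abs=1e-3)

    def test_target_at_threshold_rejected(self, baseline, params):
        with pytest.raises(ValueError, match="threshold"):
            calibrate_peak(params.threshold, baseline.base_config, params)

    def test_monotone_in_target(self, baseline, params):
        peaks = [
            calibrate_peak(t, baseline.base_config, params)
            for t in (1.5, 2.0, 2.5, 3.0)
        ]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))


class TestSimulateCondition:
    def test_master_seed_determinism(self, presets, protocol):
        a = simulate_recordings(presets["mk801_40"], 3, protocol, seed=9,
                                baseline=presets["baseline_d5"])
        b = simulate_recordings(presets["mk801_40"], 3, protocol, seed=9,
                                baseline=presets["baseline_d5"])
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.trace.values, rb.trace.values)
            assert ra.onsets == rb.onsets

    def test_null_condition_has_no_systematic_shift(self, baseline, params, protocol):
        # pre and post phases of the baseline preset share one distribution
        diffs = []
        for seed in range(25):
            for pre, post in simulate_condition(baseline, 5, protocol, seed):
                diffs.append(
                    analyze_trace(post, params).frequency
                    - analyze_trace(pre, params).frequency
                )
        mean, se = np.mean(diffs), np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean) < 3 * se + 1e-12

    def test_phase_windows_and_truth_labels(self, baseline, protocol):
        recs = simulate_recordings(baseline, 2, protocol, seed=5)
        for rec in recs:
            assert rec.trace.duration == protocol.total
            for t, phase in rec.onsets:
                if t < 0:
                    assert phase == "burnin"
                elif t < protocol.pre_duration:
                    assert phase == "pre"
                elif t < protocol.pre_duration + protocol.wash_duration:
                    assert phase == "wash"
                else:
                    assert phase == "post"

    def test_ground_truth_count_recovered_noiselessly(self, baseline, params):
        # sparse noiseless regime: every generated onset is one detected event
        cfg = replace(
            baseline.base_config, noise_sd=0.0, drift_amp=0.0, event_rate=0.01,
            refractory=25.0,
        )
        for seed in range(5):
            onsets = sample_event_times(cfg.event_rate, 280.0, cfg.refractory, seed)
            onsets = [t for t in onsets if t < 280.0 - 15.0]
            tr = render_trace(onsets, replace(cfg, duration=300.0))
            assert analyze_trace(tr, params).n_events == len(onsets)


def test_preset_table_covers_all_conditions(presets):
    assert EXPECTED_PRESETS <= set(presets)


def test_dose_monotonicity_of_modulated_parameters(presets):
    doses = ["ketamine_30", "ketamine_100", "ketamine_300", "ketamine_1000", "ketamine_3000"]
    cfgs = [apply_modulations(presets[d]) for d in doses]
    rates = [c.event_rate for c in cfgs]
    peaks = [c.kernel.peak_df for c in cfgs]
    assert all(a >= b for a, b in zip(rates, rates[1:]))
    assert all(a >= b for a, b in zip(peaks, peaks[1:]))
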