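"""Detector and metrics: baseline, hysteresis events, the five metrics."""

import dataclasses
import math

import numpy as np
import pytest

from cpmcassay import (
    ConfigurationError,
    DetectionParams,
    GeneratorConfig,
    PressureTrace,
    detect_cpmcs,
    estimate_baseline,
    phase_metrics,
    quantify_phase,
    simulate_phase,
)
from cpmcassay.simulate import _pulse_shape


def _flat_trace(value=5.0, duration=900.0, rate=100.0):
    return PressureTrace(
        samples=np.full(int(duration * rate), value), sample_rate=rate
    )


def _pulse_train(onsets, amplitude=40.0, width=30.0, baseline=5.0,
                 duration=900.0, rate=100.0, config=None):
    """Noise-free trace with raised-cosine-pedestal pulses at given onsets."""
    cfg = config or GeneratorConfig(noise_sd=0.0)
    t = np.arange(int(duration * rate)) / rate
    s = np.full(t.size, baseline)
    for onset in onsets:
        u = (t - onset) / width
        mask = (u >= 0) & (u <= 1)
        s[mask] += amplitude * _pulse_shape(
            u[mask], cfg.pedestal_frac, cfg.crest_frac
        )
    return PressureTrace(samples=s, sample_rate=rate)


class TestBaseline:
    def test_constant_trace(self, default_params):
        assert estimate_baseline(_flat_trace(5.0), default_params) == 5.0

    def test_tracks_generator_ground_truth(self, default_config,
                                           default_params):
        rng = np.random.default_rng(41)
        estimates = [
            estimate_baseline(
                simulate_phase(default_config, 900.0, child)[0],
                default_params,
            )
            for child in rng.spawn(100)
        ]
        assert abs(np.mean(estimates) - default_config.baseline_pressure) < (
            2 * default_config.noise_sd
        )

    def test_saturated_trace_warns(self, default_params):
        # one long event: pressure high throughout, baseline unreliable
        trace = _flat_trace(60.0)
        trace.samples[:100] = 5.0  # < 5% quiescent samples
        with pytest.warns(UserWarning, match="quiescence"):
            estimate_baseline(trace, default_params)

    def test_empty_trace_rejected(self, default_params):
        with pytest.raises(ConfigurationError):
            estimate_baseline(
                PressureTrace(samples=np.array([]), sample_rate=100.0),
                default_params,
            )


class TestDetect:
    def test_flat_trace_has_no_events(self, default_params):
        assert detect_cpmcs(_flat_trace(), default_params) == []

    def test_pulses_one_second_apart_merge(self, default_params):
        # two 10-s square pulses separated by a 1-s dip: gap < merge_gap=2 s
        rate = 100.0
        s = np.full(9000, 5.0)
        s[1000:2000] = 45.0
        s[2100:3100] = 45.0
        trace = PressureTrace(samples=s, sample_rate=rate)
        events = detect_cpmcs(trace, default_params, baseline=5.0)
        assert len(events) == 1

    def test_separated_pulses_not_merged(self, default_params):
        s = np.full(9000, 5.0)
        s[1000:2000] = 45.0
        s[2600:3600] = 45.0  # 6-s gap > merge_gap
        trace = PressureTrace(samples=s, sample_rate=100.0)
        assert len(detect_cpmcs(trace, default_params, baseline=5.0)) == 2

    def test_short_blips_dropped(self, default_params):
        s = np.full(9000, 5.0)
        s[1000:1200] = 45.0  # 2 s < min_event_duration
        trace = PressureTrace(samples=s, sample_rate=100.0)
        assert detect_cpmcs(trace, default_params, baseline=5.0) == []

    def test_subthreshold_bump_not_an_event(self, default_params):
        # crosses the offset threshold but never the onset threshold
        s = np.full(9000, 5.0)
        s[1000:3000] = 12.0  # 7 mmHg above baseline: between 5 and 10
        trace = PressureTrace(samples=s, sample_rate=100.0)
        assert detect_cpmcs(trace, default_params, baseline=5.0) == []

    def test_oracle_equivalence_on_noise_free_phase(self, quiet_config,
                                                    default_params):
        trace, ann = simulate_phase(quiet_config, 900.0, rng_seed=43)
        full = [
            a for a in ann
            if a.offset - a.onset >= quiet_config.event_duration - 1e-6
        ]
        events = detect_cpmcs(trace, default_params)
        assert len(events) >= len(full)
        for a, e in zip(full, events):
            assert abs(e.onset - a.onset) <= quiet_config.event_duration / 2
            assert e.amplitude == pytest.approx(a.true_amplitude, rel=0.01)


class TestPhaseMetrics:
    def test_flat_trace_metrics(self, default_params):
        trace = _flat_trace(5.0)
        m = phase_metrics(trace, [], default_params, baseline=5.0)
        assert m.frequency == 0
        assert m.tiq == pytest.approx(900.0)
        assert m.auc == pytest.approx(0.0)
        assert math.isnan(m.ti_mean) and math.isnan(m.amplitude_mean)

    def test_six_pulses_at_150s_spacing(self, default_params):
        onsets = [50 + 150 * k for k in range(6)]
        trace = _pulse_train(onsets)
        m = quantify_phase(trace, default_params)
        assert m.frequency == 6
        assert m.ti_mean == pytest.approx(150.0, abs=0.1)

    def test_tiq_above_band_conservation(self, default_config,
                                         default_params):
        """TIQ plus time above the quiescence band equals the phase duration."""
        trace, _ = simulate_phase(default_config, 900.0, rng_seed=47)
        baseline = estimate_baseline(trace, default_params)
        m = phase_metrics(trace, [], default_params, baseline=baseline)
        above = np.sum(
            trace.samples > baseline + default_params.quiescence_band
        ) / trace.sample_rate
        assert m.tiq + above == pytest.approx(900.0, abs=1e-9)

    def test_auc_additive_over_subintervals(self, default_config,
                                            default_params):
        trace, _ = simulate_phase(default_config, 900.0, rng_seed=53)
        baseline = estimate_baseline(trace, default_params)
        whole = phase_metrics(trace, [], default_params, baseline=baseline).auc
        half = trace.samples.size // 2
        parts = 0.0
        for chunk in (trace.samples[: half + 1], trace.samples[half:]):
            sub = PressureTrace(samples=chunk, sample_rate=trace.sample_rate)
            parts += phase_metrics(sub, [], default_params, baseline=baseline).auc
        assert parts == pytest.approx(whole, rel=1e-9)

    def test_extra_pulse_never_decreases_frequency_or_auc(self,
                                                          default_params):
        onsets = [100, 300, 500]
        base_trace = _pulse_train(onsets)
        more_trace = _pulse_train(onsets + [700])
        m0 = quantify_phase(base_trace, default_params)
        m1 = quantify_phase(more_trace, default_params)
        assert m1.frequency >= m0.frequency
        assert m1.auc >= m0.auc

    def test_event_outside_phase_rejected(self, default_params):
        trace = _flat_trace(5.0, duration=100.0)
        from cpmcassay import CPMCEvent

        bad = CPMCEvent(onset=90.0, offset=150.0, peak_time=95.0,
                        amplitude=30.0)
        with pytest.raises(ConfigurationError):
            phase_metrics(trace, [bad], default_params, baseline=5.0)


class TestBaselineCohortCalibration:
    def test_default_pipeline_recovers_assay_baseline_statistics(
        self, default_config, default_params
    ):
        """Small cohort sanity check of the five metrics at default settings.

        (The full 99-phase calibration check lives in the acceptance suite.)
        """
        rng = np.random.default_rng(59)
        rows = []
        for child in rng.spawn(30):
            trace, _ = simulate_phase(default_config, 900.0, child)
            m = quantify_phase(trace, default_params)
            rows.append((m.frequency, m.ti_mean, m.tiq, m.amplitude_mean,
                         m.auc))
        means = np.nanmean(np.asarray(rows, dtype=float), axis=0)
        targets = (5.6, 161.4, 661.0, 49.0, 6410.0)
        for got, want in zip(means, targets):
            assert got == pytest.approx(want, rel=0.10)
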