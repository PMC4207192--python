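"""Generator: renewal statistics, pulse shape, Hill scaling, determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpmcassay import (
    ConfigurationError,
    DrugEffect,
    DrugEffectModel,
    ExperimentDesign,
    GeneratorConfig,
    apply_drug_effect,
    simulate_control_cohort,
    simulate_experiment,
    simulate_phase,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_pressure": -1.0},
            {"noise_sd": -0.5},
            {"mean_interval": 30.0},  # <= event_duration
            {"event_amplitude": -1.0},
            {"drift_per_phase": -1.0},
            {"mean_interval": float("nan")},
            {"interval_shape": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**kwargs)

    def test_design_requires_increasing_concentrations(self):
        with pytest.raises(ConfigurationError):
            ExperimentDesign(concentrations=(3.0, 0.3, 30.0))

    def test_design_phase_concentrations(self):
        design = ExperimentDesign()
        assert [design.phase_concentration(i) for i in range(5)] == [
            0.0, 0.3, 3.0, 30.0, 0.0,
        ]


class TestSimulatePhase:
    def test_same_seed_bit_identical(self, default_config):
        t1, a1 = simulate_phase(default_config, 900.0, rng_seed=7)
        t2, a2 = simulate_phase(default_config, 900.0, rng_seed=7)
        assert np.array_equal(t1.samples, t2.samples)
        assert a1 == a2

    def test_zero_amplitude_gives_flat_trace(self):
        cfg = GeneratorConfig(noise_sd=0.0, event_amplitude=0.0)
        trace, annotations = simulate_phase(cfg, 900.0, rng_seed=0)
        assert annotations == []
        assert np.allclose(trace.samples, cfg.baseline_pressure)
        assert trace.samples.size == 90_000

    def test_renewal_calibration(self, default_config):
        """Mean event count over many phases equals duration/mean_interval within 2%."""
        cfg = dataclasses.replace(default_config, noise_sd=0.0)
        rng = np.random.default_rng(11)
        counts = [
            len(simulate_phase(cfg, 900.0, rng_seed=child)[1])
            for child in rng.spawn(500)
        ]
        expected = 900.0 / cfg.mean_interval
        assert np.mean(counts) == pytest.approx(expected, rel=0.02)

    def test_amplitude_calibration(self, default_config):
        """Mean annotated amplitude matches the configured peak within MC error."""
        rng = np.random.default_rng(13)
        amps = []
        for child in rng.spawn(200):
            _, ann = simulate_phase(default_config, 900.0, rng_seed=child)
            # final events may be truncated at the edge; their recorded peak
            # is the visible one, so exclude them from the calibration check
            amps.extend(
                a.true_amplitude
                for a in ann
                if a.offset - a.onset >= default_config.event_duration - 1e-6
            )
        tol = 3 * default_config.amplitude_cv / np.sqrt(len(amps))
        assert np.mean(amps) == pytest.approx(
            default_config.event_amplitude, rel=tol
        )

    def test_events_non_overlapping_and_ordered(self, default_config):
        rng = np.random.default_rng(17)
        for child in rng.spawn(50):
            _, ann = simulate_phase(default_config, 900.0, rng_seed=child)
            onsets = [a.onset for a in ann]
            assert onsets == sorted(onsets)
            gaps = np.diff(onsets)
            assert np.all(gaps >= default_config.event_duration)

    def test_annotation_geometry(self, default_config):
        _, ann = simulate_phase(default_config, 900.0, rng_seed=3)
        for a in ann:
            assert a.onset < a.peak_time < a.offset <= 900.0


class TestDrugEffect:
    AMP_EFFECT = DrugEffectModel(
        (DrugEffect("event_amplitude", emax=3.0, ec50=1.0, hill_n=1.0,
                    direction="excitatory"),)
    )

    def test_zero_concentration_is_identity(self, default_config):
        assert (
            apply_drug_effect(default_config, self.AMP_EFFECT, 0.0)
            == default_config
        )

    def test_half_maximal_point_doubles_amplitude(self, default_config):
        out = apply_drug_effect(default_config, self.AMP_EFFECT, 1.0)
        assert out.event_amplitude == pytest.approx(
            2 * default_config.event_amplitude
        )

    def test_saturation_approaches_emax(self, default_config):
        out = apply_drug_effect(default_config, self.AMP_EFFECT, 1e6)
        assert out.event_amplitude == pytest.approx(
            3 * default_config.event_amplitude, rel=1e-3
        )

    def test_inhibitory_effect_keeps_parameter_positive(self, default_config):
        model = DrugEffectModel(
            (DrugEffect("event_amplitude", emax=100.0, ec50=0.1, hill_n=2.0,
                        direction="inhibitory"),)
        )
        out = apply_drug_effect(default_config, model, 1e9)
        assert out.event_amplitude > 0

    @given(
        conc=st.lists(
            st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=2
        ),
        emax=st.floats(min_value=1.0, max_value=50.0),
        ec50=st.floats(min_value=1e-3, max_value=1e3),
        hill_n=st.floats(min_value=0.3, max_value=4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_hill_scaling_monotone_in_concentration(
        self, conc, emax, ec50, hill_n
    ):
        eff = DrugEffect("event_amplitude", emax=emax, ec50=ec50,
                         hill_n=hill_n, direction="excitatory")
        lo, hi = sorted(conc)
        assert eff.scaling(lo) <= eff.scaling(hi) + 1e-12

    def test_invalid_effect_rejected(self):
        with pytest.raises(ConfigurationError):
            DrugEffect("noise_sd", emax=2.0, ec50=1.0, hill_n=1.0)
        with pytest.raises(ConfigurationError):
            DrugEffect("event_amplitude", emax=2.0, ec50=-1.0, hill_n=1.0)


class TestExperiment:
    def test_fixed_seed_reproducible(self, default_config):
        design = ExperimentDesign()
        model = DrugEffectModel.null()
        run1 = simulate_experiment(design, default_config, model, rng_seed=5)
        run2 = simulate_experiment(design, default_config, model, rng_seed=5)
        for (t1, _), (t2, _) in zip(run1, run2):
            assert np.array_equal(t1.samples, t2.samples)

    def test_drift_tracks_phase_index(self, default_config):
        """Under a null drug model, annotated amplitudes follow (1+drift)^phase."""
        cfg = dataclasses.replace(default_config, amplitude_cv=0.0)
        design = ExperimentDesign()
        rng = np.random.default_rng(23)
        per_phase = [[] for _ in design.phase_labels]
        for child in rng.spawn(40):
            run = simulate_experiment(
                design, cfg, DrugEffectModel.null(), rng_seed=child
            )
            for i, (_, ann) in enumerate(run):
                per_phase[i].extend(
                    a.true_amplitude
                    for a in ann
                    if a.offset - a.onset >= cfg.event_duration - 1e-6
                )
        for i, amps in enumerate(per_phase):
            expected = cfg.event_amplitude * (1 + cfg.drift_per_phase) ** i
            assert np.mean(amps) == pytest.approx(expected, rel=1e-6)

    def test_inhibitory_model_reduces_event_counts_monotonically(
        self, default_config
    ):
        """A strong interval-prolonging drug yields non-increasing mean counts."""
        model = DrugEffectModel(
            (DrugEffect("mean_interval", emax=4.0, ec50=1.0, hill_n=1.0,
                        direction="excitatory"),)
        )
        design = ExperimentDesign()
        rng = np.random.default_rng(29)
        counts = np.zeros(3)
        n_runs = 100
        for child in rng.spawn(n_runs):
            run = simulate_experiment(design, default_config, model, child)
            counts += [len(run[i][1]) for i in (1, 2, 3)]
        means = counts / n_runs
        assert means[0] >= means[1] >= means[2]

    def test_control_cohort_size_and_null_drift_centering(self):
        cfg = GeneratorConfig(drift_per_phase=0.0)
        design = ExperimentDesign()
        cohort = simulate_control_cohort(4, design, cfg, rng_seed=31)
        assert len(cohort) == 4
        assert all(len(exp) == 5 for exp in cohort)

    def test_control_cohort_rejects_n_below_two(self, default_config):
        with pytest.raises(ConfigurationError):
            simulate_control_cohort(1, ExperimentDesign(), default_config)
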