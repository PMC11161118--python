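"""Synthetic generators: determinism, parameter recovery, constraints, cohorts."""

import numpy as np
import pytest

from spikeprofile import (
    GenerationError,
    InvalidParameterError,
    coefficient_of_variation,
    compute_isi,
)
from spikeprofile.synthetic import (
    CohortSpec,
    GeneratorSpec,
    gen_burst_train,
    gen_cohort,
    gen_renewal_train,
    gen_rhythmic_train,
    gen_waveform,
)


class TestDeterminism:
    def test_renewal_bitwise_reproducible(self):
        a = gen_renewal_train(5.0, 2.0, 500, seed=42)
        b = gen_renewal_train(5.0, 2.0, 500, seed=42)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_rhythmic_bitwise_reproducible(self):
        a = gen_rhythmic_train(10.0, 6.0, 0.8, 30.0, seed=42)
        b = gen_rhythmic_train(10.0, 6.0, 0.8, 30.0, seed=42)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_burst_bitwise_reproducible(self):
        a = gen_burst_train(3.0, duration=30.0, seed=42)
        b = gen_burst_train(3.0, duration=30.0, seed=42)
        assert np.array_equal(a.timestamps, b.timestamps)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_waveform_bitwise_reproducible(self):
        a = gen_waveform(2.0, seed=42)
        b = gen_waveform(2.0, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_cohort_manifest_reproducible(self):
        spec = CohortSpec(n_animals=4, seed=11)
        m1 = gen_cohort(spec).manifest
        m2 = gen_cohort(spec).manifest
        assert m1.equals(m2)


class TestRenewal:
    def test_exponential_cv_is_unity(self):
        train = gen_renewal_train(10.0, 1.0, 10_000, seed=0)
        cv = coefficient_of_variation(compute_isi(train))
        # CV of the exponential is 1; allow 3 standard errors at n = 10,000
        assert cv == pytest.approx(1.0, abs=0.03)

    def test_gamma_shape_four_cv_recovery(self):
        train = gen_renewal_train(10.0, 4.0, 10_000, seed=1)
        assert coefficient_of_variation(compute_isi(train)) == pytest.approx(0.5, rel=0.05)

    def test_timestamps_strictly_increasing(self):
        train = gen_renewal_train(50.0, 0.5, 5000, seed=2)
        assert np.all(np.diff(train.timestamps) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_renewal_train(-1.0, 1.0, 100, seed=0)
        with pytest.raises(InvalidParameterError):
            gen_renewal_train(1.0, 0.0, 100, seed=0)
        with pytest.raises(InvalidParameterError):
            gen_renewal_train(1.0, 1.0, 1, seed=0)


class TestRhythmic:
    def test_mean_count_matches_base_rate(self):
        # zero-mean modulation: expected count = base_rate * duration
        counts = [
            gen_rhythmic_train(10.0, 6.0, 0.9, 60.0, seed=s).n_spikes for s in range(20)
        ]
        mean = float(np.mean(counts))
        se = np.sqrt(600 / 20)
        assert abs(mean - 600) < 4 * se

    def test_ach_peak_spacing_matches_modulation_period(self):
        from spikeprofile import autocorrelation_histogram, classify_rhythmicity

        spacings = []
        for s in range(20):
            train = gen_rhythmic_train(15.0, 6.0, 0.9, 120.0, seed=s)
            r = classify_rhythmicity(autocorrelation_histogram(train, 0.01, 1.0))
            if r.label == "rhythmic":
                spacings.append(1.0 / r.rhythm_freq_hz)
        assert len(spacings) >= 18
        assert abs(np.mean(spacings) - 1 / 6) / (1 / 6) < 0.10

    def test_depth_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_rhythmic_train(10.0, 6.0, 1.5, 10.0, seed=0)


class TestBurst:
    def test_triplet_amplitudes_decay_geometrically(self):
        train = gen_burst_train(3.0, (3, 3), amplitude_decrement=0.3, duration=30.0, seed=0)
        amps = train.amplitudes.reshape(-1, 3)
        assert np.allclose(amps, [1.0, 0.7, 0.49])

    def test_intra_burst_intervals_below_threshold(self):
        for s in range(5):
            train = gen_burst_train(4.0, duration=30.0, seed=s)
            isis = np.diff(train.timestamps)
            # every interval is either intra-burst (< 20 ms) or a burst gap
            intra = isis[isis < 0.04]
            assert np.all(intra < 0.020)

    def test_overlapping_rate_raises_diagnostic(self):
        with pytest.raises(GenerationError, match="burst_rate"):
            gen_burst_train(10.0, duration=30.0, seed=0)


class TestWaveform:
    def test_sixty_samples_span_standard_apd(self):
        # 3 ms at 20 kHz = 60 samples across the first two phases
        from spikeprofile import measure_apd

        wave = gen_waveform(3.0, sample_rate=20000.0, seed=0)
        assert measure_apd(wave) == pytest.approx(60 * wave.sample_period_ms, abs=0.05)

    def test_under_resolved_apd_rejected(self):
        with pytest.raises(InvalidParameterError, match="8"):
            gen_waveform(0.1, sample_rate=20000.0, seed=0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(InvalidParameterError, match="20 kHz"):
            gen_waveform(2.0, sample_rate=5000.0, seed=0)


class TestCohort:
    def test_neuron_count_bounds(self):
        cohort = gen_cohort(CohortSpec(n_animals=16, seed=0), min_spikes=230)
        n = len(cohort.manifest)
        assert 16 <= n <= 16 * 7
        assert cohort.manifest["animal_id"].nunique() == 16

    def test_every_neuron_supports_standard_isi_length(self):
        cohort = gen_cohort(CohortSpec(n_animals=4, seed=3))
        for train in cohort.trains:
            assert train.n_spikes >= 226

    def test_ground_truth_and_waveforms_attached(self):
        cohort = gen_cohort(CohortSpec(n_animals=4, seed=5))
        assert set(cohort.manifest["true_class"]) <= {
            "renewal_gamma", "rhythmic_modulated", "bursting", "clock_like",
        }
        assert set(cohort.manifest["neuron_id"]) == set(cohort.waveforms)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(InvalidParameterError, match="sums to"):
            CohortSpec(n_animals=4, class_mixture={"DRN": {"renewal_gamma": 0.5}})
        with pytest.raises(InvalidParameterError, match="unknown process"):
            CohortSpec(n_animals=4, class_mixture={"DRN": {"bogus": 1.0}})

    def test_clock_like_class_meets_rate_and_regularity_criteria(self):
        # slow regular generator: FR < 5 Hz and CV < 0.30 in >= 95% of runs
        mix = {"DRN": {"clock_like": 1.0}}
        ok = total = 0
        for seed in range(5):
            cohort = gen_cohort(CohortSpec(n_animals=4, class_mixture=mix, seed=seed))
            for train in cohort.trains:
                isi = compute_isi(train)
                fr = (train.n_spikes - 1) / train.duration
                total += 1
                ok += fr < 5.0 and coefficient_of_variation(isi) < 0.30
        assert ok / total >= 0.95


class TestGeneratorSpec:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            GeneratorSpec(process_kind="bogus")
        with pytest.raises(InvalidParameterError):
            GeneratorSpec(process_kind="renewal_gamma", rate=0.0)
        with pytest.raises(InvalidParameterError):
            GeneratorSpec(process_kind="bursting", burst_size_range=(2, 5))

    def test_generate_dispatches_and_meets_minimum(self):
        for kind in ("renewal_gamma", "rhythmic_modulated", "bursting", "clock_like"):
            spec = GeneratorSpec(process_kind=kind, rate=4.0, gamma_shape=16.0, seed=1)
            train = spec.generate(min_spikes=250, min_duration=30.0)
            assert train.n_spikes >= 250
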