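"""Cohort statistics: pairwise fits and hierarchical permutation tests."""

import numpy as np
import pandas as pd
import pytest

from spikeprofile import (
    InvalidParameterError,
    group_compare,
    pairwise_fit,
    redundancy_matrix,
)
from spikeprofile.stats import redundancy_table


class TestPairwiseFit:
    def test_exact_square_law_found_on_loglog_scale(self):
        x = np.arange(1.0, 51.0)
        fit = pairwise_fit(x, x**2)
        assert fit.scale == "loglog"
        assert fit.coefficient == pytest.approx(2.0, abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_linear_relation_prefers_linear_scale(self, rng):
        x = rng.uniform(1, 10, 200)
        y = 3.0 * x + rng.normal(0, 0.1, 200)
        fit = pairwise_fit(x, y)
        assert fit.linear.coefficient == pytest.approx(3.0, rel=0.05)
        assert abs(fit.linear.pearson_r) >= abs(fit.loglog.pearson_r)

    def test_null_calibration_of_best_fit_p_value(self):
        rng = np.random.default_rng(3)
        false_pos = 0
        for _ in range(100):
            x = rng.uniform(1, 10, 100)
            y = rng.uniform(1, 10, 100)
            false_pos += pairwise_fit(x, y).p_value <= 0.05
        assert false_pos <= 10  # p > 0.05 in >= 90% of independent-data runs

    def test_entropy_ceiling_transform_recovers_planted_exponent(self, rng):
        # y follows (1 - op_entropy)^beta: the log fit must use 1 - x
        x = rng.uniform(0.95, 0.999, 200)
        y = (1.0 - x) ** 0.5 * np.exp(rng.normal(0, 0.01, 200))
        fit = pairwise_fit(x, y, x_name="op_entropy", y_name="apd_ms")
        assert fit.scale == "loglog"
        assert fit.coefficient == pytest.approx(0.5, rel=0.05)

    def test_planted_power_law_recovery_with_small_noise(self, rng):
        x = rng.uniform(1, 20, 200)
        y = 2.5 * x**-1.3 * np.exp(rng.normal(0, 0.01, 200))
        fit = pairwise_fit(x, y)
        assert fit.scale == "loglog"
        assert fit.coefficient == pytest.approx(-1.3, rel=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidParameterError):
            pairwise_fit(np.arange(5.0), np.arange(5.0))


def _hierarchical_values(rng, n_animals, neurons_per_animal=3, shift=0.0):
    animals = np.repeat([f"a{i}" for i in range(n_animals)], neurons_per_animal)
    labels = np.repeat(
        ["G1"] * (n_animals // 2) + ["G2"] * (n_animals - n_animals // 2),
        neurons_per_animal,
    )
    values = (
        rng.normal(0, 0.01, animals.size)
        + np.repeat(rng.normal(0, 0.005, n_animals), neurons_per_animal)
        + np.where(labels == "G2", -shift, 0.0)
    )
    return values, labels, animals


class TestGroupCompare:
    def test_statistic_sign_matches_mean_difference(self, rng):
        values, labels, animals = _hierarchical_values(rng, 10, shift=0.05)
        res = group_compare(values, labels, animals, n_perm=199, seed=0)
        assert np.sign(res.statistic) == np.sign(res.group_means[0] - res.group_means[1])

    def test_null_calibration_at_animal_level(self):
        rng = np.random.default_rng(9)
        false_pos = 0
        for k in range(200):
            values, labels, animals = _hierarchical_values(rng, 16, shift=0.0)
            res = group_compare(values, labels, animals, n_perm=499, seed=k)
            false_pos += res.p_value <= 0.05
        assert 0.01 <= false_pos / 200 <= 0.10

    def test_power_for_small_entropy_shift(self):
        # 0.02 shift at 20 animals/group is detected in >= 80% of runs
        rng = np.random.default_rng(10)
        hits = 0
        for k in range(50):
            values, labels, animals = _hierarchical_values(rng, 40, shift=0.02)
            res = group_compare(values, labels, animals, n_perm=499, seed=k)
            hits += res.p_value < 0.05
        assert hits >= 40

    def test_invariant_under_positive_rescaling(self, rng):
        values, labels, animals = _hierarchical_values(rng, 12, shift=0.02)
        a = group_compare(values, labels, animals, n_perm=299, seed=4)
        b = group_compare(values * 1000.0, labels, animals, n_perm=299, seed=4)
        assert a.p_value == b.p_value

    def test_mixed_animal_requires_neuron_unit(self, rng):
        values = rng.normal(0, 1, 12)
        labels = np.array(["G1", "G2"] * 6)  # every animal spans both groups
        animals = np.repeat([f"a{i}" for i in range(6)], 2)
        with pytest.raises(InvalidParameterError, match="both groups"):
            group_compare(values, labels, animals, n_perm=99, seed=0)
        res = group_compare(values, labels, animals, n_perm=99, seed=0, permute_unit="neuron")
        assert 0 < res.p_value <= 1

    def test_single_animal_group_rejected(self, rng):
        values = rng.normal(0, 1, 9)
        labels = np.array(["G1"] * 3 + ["G2"] * 6)
        animals = np.array(["a1"] * 3 + ["a2"] * 3 + ["a3"] * 3)
        with pytest.raises(InvalidParameterError, match="animal"):
            group_compare(values, labels, animals, n_perm=99, seed=0)


class TestRedundancyMatrix:
    def _measure_table(self, rng, n=60):
        return pd.DataFrame(
            {
                "fr_hz": rng.uniform(1, 20, n),
                "cv": rng.uniform(0.1, 1.5, n),
                "apd_ms": rng.uniform(0.8, 3.5, n),
                "op_entropy": rng.uniform(0.95, 0.999, n),
                "bins_entropy": rng.uniform(0.3, 0.9, n),
                "plzc": rng.uniform(0.6, 1.0, n),
            }
        )

    def test_fifteen_unordered_pairs(self, rng):
        fits = redundancy_matrix(self._measure_table(rng))
        assert len(fits) == 15
        pairs = {frozenset((f.x_name, f.y_name)) for f in fits}
        assert len(pairs) == 15

    def test_table_carries_holm_extension_column(self, rng):
        table = redundancy_table(redundancy_matrix(self._measure_table(rng)))
        assert "p_holm_extension" in table.columns
        assert (table["p_holm_extension"] >= table["p_value"] - 1e-15).all()

    def test_cv_fr_power_law_has_negative_exponent_on_heterogeneous_cohort(self):
        # cohort in which slow neurons fire irregularly and fast neurons
        # regularly: CV falls with FR as a power law
        from spikeprofile import coefficient_of_variation, compute_isi, firing_rate
        from spikeprofile.synthetic import gen_renewal_train

        rng = np.random.default_rng(17)
        fr, cv = [], []
        for k in range(60):
            rate = float(np.exp(rng.uniform(np.log(2), np.log(20))))
            shape = 0.5 * rate**0.8
            train = gen_renewal_train(rate, shape, 400, seed=1000 + k)
            fr.append(firing_rate(train, train.recording_window))
            cv.append(coefficient_of_variation(compute_isi(train)))
        fit = pairwise_fit(np.array(fr), np.array(cv), x_name="fr_hz", y_name="cv")
        assert fit.scale == "loglog"
        assert fit.coefficient < 0
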