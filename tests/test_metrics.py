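"""Agreement statistics, Bland–Altman, MAB, diversity and shift measures,
each cross-checked against independent textbook implementations."""

import numpy as np
import pandas as pd
import pytest

from sleepcascade import metrics
from sleepcascade.metrics import (ad_shift, bland_altman, cohens_kappa,
                                  confusion_matrix, correcting_power,
                                  correlate_performance, delta_improvement,
                                  mab, make_bias_table, mmcc,
                                  over_correcting_rate, per_epoch_accuracy,
                                  shannon_diversity, stage_durations)

from oracles import (ad_ksample_oracle, binary_mcc_oracle, kappa_oracle,
                     mmcc_oracle, one_sample_t_oracle, pearson_oracle)

DEVICE = np.array([4, 4, 2, 2, 3, 3])
TRUTH = np.array([4, 4, 4, 4, 2, 3])


class TestAccuracy:
    def test_identical_is_one(self):
        assert per_epoch_accuracy([1, 2, 3], [1, 2, 3]) == 1.0

    def test_disjoint_is_zero(self):
        assert per_epoch_accuracy([1, 1, 1], [2, 2, 2]) == 0.0

    def test_worked_example_half(self):
        assert per_epoch_accuracy(DEVICE, TRUTH) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            per_epoch_accuracy([1], [1, 2])


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_constant_prediction_against_balanced_truth_is_zero(self):
        assert cohens_kappa([1, 1, 1, 1], [1, 1, 2, 2]) == pytest.approx(0.0)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(5, 50)
            p = rng.integers(1, 5, n)
            t = rng.integers(1, 5, n)
            assert cohens_kappa(p, t) == pytest.approx(kappa_oracle(p, t),
                                                       abs=1e-12)


class TestMMCC:
    def test_perfect_classification(self):
        assert mmcc([1, 2, 3, 4, 2], [1, 2, 3, 4, 2]) == pytest.approx(1.0)

    def test_binary_case_equals_binary_mcc(self, rng):
        for _ in range(25):
            n = rng.integers(6, 40)
            p = rng.integers(1, 3, n)
            t = rng.integers(1, 3, n)
            assert mmcc(p, t) == pytest.approx(
                binary_mcc_oracle(p, t, positive=1), abs=1e-10)

    def test_matches_contingency_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(8, 60)
            p = rng.integers(1, 5, n)
            t = rng.integers(1, 5, n)
            assert mmcc(p, t) == pytest.approx(mmcc_oracle(p, t), abs=1e-10)

    def test_independent_predictions_average_to_zero(self):
        """Random guessing yields MMCC ~ 0 under a realistic imbalanced
        stage distribution (light 0.5, REM 0.2, deep 0.15, wake 0.15)."""
        probs = [0.15, 0.5, 0.2, 0.15]  # codes 1..4
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.choice([1, 2, 3, 4], size=10_000, p=probs)
            p = rng.choice([1, 2, 3, 4], size=10_000, p=probs)
            vals.append(mmcc(p, t))
        assert abs(np.mean(vals)) < 0.02

    def test_degenerate_single_class_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert mmcc([2, 2], [2, 2]) == 0.0


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        cm = confusion_matrix([1, 2, 3, 4], [1, 2, 3, 4])
        np.testing.assert_allclose(np.diag(cm.to_numpy()), 100)
        assert cm.to_numpy().sum() == pytest.approx(400)

    def test_worked_example_light_column(self):
        """The single truth-light epoch was predicted REM, so the light
        column reads (deep 0, light 0, REM 100, wake 0)."""
        cm = confusion_matrix(DEVICE, TRUTH)
        np.testing.assert_allclose(cm["light"].to_numpy(),
                                   [0, 0, 100, 0])  # deep, light, rem, wake
        assert cm.loc["rem", "light"] == 100

    def test_columns_sum_to_100(self, rng):
        p = rng.integers(1, 5, 500)
        t = rng.integers(1, 5, 500)
        cm = confusion_matrix(p, t)
        np.testing.assert_allclose(cm.sum(axis=0), 100, atol=1e-9)


class TestCorrectionMeasures:
    def test_cp_bounds(self):
        assert correcting_power(DEVICE, TRUTH, TRUTH) == 1.0
        assert correcting_power(DEVICE, DEVICE, TRUTH) == 0.0

    def test_cp_worked_example(self):
        """Three device-wrong epochs; a model fixing two of them has
        CP = 2/3."""
        pred = np.array([4, 4, 4, 4, 3, 3])  # fixes epochs 3,4, misses epoch 5
        assert correcting_power(DEVICE, pred, TRUTH) == pytest.approx(2 / 3)

    def test_or_bounds(self):
        assert over_correcting_rate(DEVICE, DEVICE, TRUTH) == 0.0
        assert over_correcting_rate(DEVICE, TRUTH, TRUTH) == 0.0

    def test_or_worked_example(self):
        """Three device-correct epochs; flipping one away gives OR = 1/3."""
        pred = np.array([4, 4, 2, 2, 3, 1])
        assert over_correcting_rate(DEVICE, pred, TRUTH) == pytest.approx(1 / 3)

    def test_undefined_strata_signalled_as_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(correcting_power(TRUTH, TRUTH, TRUTH))
        with pytest.warns(UserWarning):
            dev = 5 - TRUTH  # never agrees (codes 1..4)
            assert np.isnan(over_correcting_rate(dev, TRUTH, TRUTH))

    def test_conservation_identity(self, rng):
        """Total model errors split exactly into broken device-correct
        epochs (OR stratum) and unfixed device-wrong epochs (CP stratum)."""
        for _ in range(20):
            n = int(rng.integers(20, 100))
            d = rng.integers(1, 5, n)
            p = rng.integers(1, 5, n)
            t = rng.integers(1, 5, n)
            if (d == t).all() or (d != t).all():
                continue
            cp = correcting_power(d, p, t)
            orr = over_correcting_rate(d, p, t)
            n_right, n_wrong = (d == t).sum(), (d != t).sum()
            assert n_right * orr + n_wrong * (1 - cp) \
                == pytest.approx((p != t).sum())


class TestDelta:
    def test_mab_reduction_examples(self):
        assert delta_improvement(0.179, 0.617) == pytest.approx(-71.0, abs=0.05)
        assert delta_improvement(0.010, 0.617) == pytest.approx(-98.4, abs=0.05)

    def test_identity_and_scale_invariance(self, rng):
        for _ in range(10):
            x, y = rng.uniform(0.1, 2, 2)
            a = rng.uniform(0.5, 3)
            assert delta_improvement(x, x) == 0.0
            assert delta_improvement(a * x, a * y) \
                == pytest.approx(delta_improvement(x, y))

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            delta_improvement(0.5, 0.0)


class TestDurations:
    def test_full_night(self):
        d = stage_durations(np.full(1176, 2))
        assert sum(d.values()) == 588.0  # 9.8 h

    def test_empty_all_zero(self):
        assert set(stage_durations(np.empty(0, int)).values()) == {0.0}

    def test_hand_example(self):
        d = stage_durations(np.array([2, 2, 4]))
        assert d == {"deep": 0.0, "light": 1.0, "rem": 0.0, "wake": 0.5}

    def test_durations_conserve(self, rng):
        s = rng.integers(1, 5, 333)
        assert sum(stage_durations(s).values()) == pytest.approx(0.5 * 333)


class TestBlandAltman:
    def test_identical_methods(self):
        res = bland_altman([10, 20, 30], [10, 20, 30])
        assert res.bias == 0 and res.loa_lower == 0 and res.loa_upper == 0
        assert res.trend_slope == 0

    def test_hand_computed_loa(self):
        """Differences (1,2,3): bias 2, SD 1, LOA 2 +/- 1.96."""
        res = bland_altman([9, 18, 27], [10, 20, 30])
        assert res.bias == pytest.approx(2.0)
        assert res.loa_lower == pytest.approx(0.04)
        assert res.loa_upper == pytest.approx(3.96)

    def test_t_statistic_matches_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            m = rng.normal(300, 40, n)
            t = m + rng.normal(5, 10, n)
            res = bland_altman(m, t)
            t_ref, p_ref = one_sample_t_oracle(t - m)
            assert res.t_stat == pytest.approx(t_ref, abs=1e-8)
            assert res.t_pvalue == pytest.approx(p_ref, abs=1e-8)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])


class TestMAB:
    def _table(self, *models):
        return make_bias_table({f"m{i}": dict(zip(metrics.STAGE_ORDER, e))
                                for i, e in enumerate(models)})

    def test_extremes(self):
        table = self._table((1, 1, 1, 1), (3, 3, 3, 3))
        assert mab(table, "m0") == 0.0
        assert mab(table, "m1") == 1.0

    def test_three_model_hand_example(self):
        table = self._table((1, 1, 1, 1), (3, 3, 3, 3), (2, 2, 2, 2))
        assert [mab(table, m) for m in ("m0", "m1", "m2")] == [0.0, 1.0, 0.5]

    def test_degenerate_stage_contributes_zero(self):
        table = self._table((1, 2, 5, 5), (1, 4, 5, 9))
        # stages wake and deep tie across models -> 0 terms
        assert mab(table, "m0") == pytest.approx(0.0)
        assert mab(table, "m1") == pytest.approx(0.5)

    def test_interior_model_leaves_others_unchanged(self):
        small = self._table((1, 1, 1, 1), (3, 3, 3, 3))
        big = self._table((1, 1, 1, 1), (3, 3, 3, 3), (2, 2.5, 1.5, 2))
        for m in ("m0", "m1"):
            assert mab(big, m) == mab(small, m)

    def test_missing_model_errors(self):
        with pytest.raises(ValueError):
            mab(self._table((1, 1, 1, 1), (2, 2, 2, 2)), "nope")


class TestDiversityAndShift:
    def test_single_class_zero(self):
        assert shannon_diversity([2, 2, 2]) == 0.0

    def test_uniform_is_ln4(self):
        assert shannon_diversity([1, 2, 3, 4]) == pytest.approx(np.log(4))

    def test_two_even_classes(self):
        assert shannon_diversity([1, 1, 2, 2]) == pytest.approx(np.log(2))

    def test_uniform_is_unique_maximum(self, rng):
        for _ in range(10):
            counts = rng.integers(1, 20, 4)
            labels = np.repeat([1, 2, 3, 4], counts)
            h = shannon_diversity(labels)
            assert h <= np.log(4) + 1e-12
            if len(set(counts)) > 1:
                assert h < np.log(4)

    def test_identical_samples_below_separated(self):
        a = np.repeat([1, 2, 3, 4], 50)
        same = ad_shift(a, a.copy())
        apart = ad_shift(np.full(100, 2), np.full(100, 4))
        assert apart > same

    def test_matches_scholz_stephens_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(10, 60, 2)
            a = rng.integers(1, 5, n1)
            b = rng.integers(1, 5, n2)
            assert ad_shift(a, b) == pytest.approx(
                ad_ksample_oracle([a, b]), abs=1e-8)


class TestCorrelation:
    def test_perfect_lines(self):
        r, _ = correlate_performance([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = correlate_performance([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = correlate_performance(x, y)
            r_ref, p_ref = pearson_oracle(x, y)
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            correlate_performance([1, 1, 1], [1, 2, 3])
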