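"""Adjusted-count correction, rate estimation and the condition sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfmotion.classifier import EnsembleParams
from calfmotion.quantification import (
    PLAY,
    QuantifyConfig,
    RateEstimates,
    TrainingCondition,
    adjust_prevalence,
    estimate_rates,
    overestimation,
    quantify,
    split_even,
    sweep_conditions,
)

PARAMS = EnsembleParams(n_learners=10, max_splits=8, seed=0)


def binary_frame(n_pos, n_neg, sep=5.0, seed=0, n_files=4):
    """Feature table with a positive class shifted by `sep` along f0."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.normal(size=(n, 3))
    labels = np.array(["locomotor play"] * n_pos + ["other"] * n_neg)
    X[labels == "locomotor play", 0] += sep
    return pd.DataFrame(
        {
            "animal_id": [f"f{i % n_files}" for i in range(n)],
            "behaviour": labels,
            "f0": X[:, 0], "f1": X[:, 1], "f2": X[:, 2],
        }
    )


class TestAdjustPrevalence:
    def test_perfect_classifier_identity(self):
        assert adjust_prevalence(0.5, 1.0, 0.0) == pytest.approx(0.5)

    def test_all_positives_explained_by_false_alarms(self):
        assert adjust_prevalence(0.001, 0.8, 0.001) == 0.0

    def test_worked_arithmetic(self):
        assert adjust_prevalence(0.0032, 0.8, 0.001) == pytest.approx(
            (0.0032 - 0.001) / 0.799
        )

    def test_uninformative_classifier_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            adjust_prevalence(0.5, 0.3, 0.3)
        with pytest.raises(ValueError, match="uninformative"):
            adjust_prevalence(0.5, 0.2, 0.4)

    def test_clipping_to_unit_interval(self):
        assert adjust_prevalence(0.0005, 0.9, 0.001) == 0.0
        assert adjust_prevalence(1.0, 0.7, 0.1) == 1.0

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.05, 1.0),
        st.floats(0.0, 0.9),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_left_inverse_of_forward_corruption(self, p, tpr, fpr):
        """Adjusting the forward-corrupted rate recovers p to precision."""
        if tpr <= fpr + 1e-6:
            return
        p0 = p * tpr + (1 - p) * fpr  # expected classify-and-count rate
        assert adjust_prevalence(p0, tpr, fpr) == pytest.approx(p, abs=1e-9)

    def test_strictly_increasing_in_p0(self):
        vals = [adjust_prevalence(p0, 0.85, 0.05) for p0 in np.linspace(0.06, 0.8, 20)]
        assert np.all(np.diff(vals) > 0)


class TestOverestimation:
    def test_printed_worked_example(self):
        absolute, percent = overestimation(195, 232)
        assert absolute == 37
        assert percent == pytest.approx(18.97, abs=0.01)

    def test_exact_and_underestimate(self):
        assert overestimation(200, 200) == (0, 0.0)
        absolute, percent = overestimation(200, 150)
        assert (absolute, percent) == (-50, -25.0)

    def test_zero_observed_flagged_infinite(self):
        absolute, percent = overestimation(0, 5)
        assert absolute == 5 and np.isinf(percent)
        assert overestimation(0, 0) == (0, 0.0)


class TestEstimateRates:
    def test_separable_classes_near_perfect_rates(self):
        frame = binary_frame(60, 600, sep=8.0)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = np.where(frame["behaviour"] == "locomotor play", PLAY, "non-play")
        rates = estimate_rates(X, y, TrainingCondition(40, 400, seed=0), PARAMS)
        assert rates.tpr > 0.95
        assert rates.fpr < 0.02

    def test_pooled_counts_match_fold_sums(self):
        frame = binary_frame(50, 500, sep=2.0, seed=3)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = np.where(frame["behaviour"] == "locomotor play", PLAY, "non-play")
        rates = estimate_rates(X, y, TrainingCondition(30, 300, seed=1), PARAMS)
        assert rates.tp + rates.fn == 30
        assert rates.fp + rates.tn == 300
        assert rates.tpr == pytest.approx(rates.tp / 30)
        assert rates.fpr == pytest.approx(rates.fp / 300)

    def test_label_noise_drives_rates_to_chance(self):
        """With labels independent of features, tpr ~ fpr (no signal)."""
        rng = np.random.default_rng(5)
        n = 800
        X = rng.normal(size=(n, 3))
        y = np.where(rng.random(n) < 0.15, PLAY, "non-play")
        rates = estimate_rates(
            X, y, TrainingCondition(80, 500, seed=2), PARAMS
        )
        assert abs(rates.tpr - rates.fpr) < 0.25

    def test_insufficient_positives_rejected(self):
        frame = binary_frame(5, 100)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = np.where(frame["behaviour"] == "locomotor play", PLAY, "non-play")
        with pytest.raises(ValueError, match="positives"):
            estimate_rates(X, y, TrainingCondition(50, 100, seed=0), PARAMS)


class TestSweep:
    def test_argmax_and_consistency_with_table(self):
        frame = binary_frame(250, 3000, sep=4.0, seed=4)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = np.where(frame["behaviour"] == "locomotor play", PLAY, "non-play")
        config = QuantifyConfig(p_grid=(20, 60, 120), np_negatives=1000,
                                ensemble=PARAMS, seed=4)
        cond, rates, table = sweep_conditions(X, y, config)
        feasible = table.dropna(subset=["tpr_minus_fpr"])
        assert rates.tpr - rates.fpr == pytest.approx(feasible["tpr_minus_fpr"].max())
        winners = feasible[feasible["tpr_minus_fpr"]
                           == feasible["tpr_minus_fpr"].max()]
        assert cond.p == winners["p"].min()  # tie -> smallest p

    def test_infeasible_conditions_skipped_not_fatal(self):
        frame = binary_frame(25, 1500, sep=6.0, seed=5)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = np.where(frame["behaviour"] == "locomotor play", PLAY, "non-play")
        config = QuantifyConfig(p_grid=(20, 400), np_negatives=1000,
                                ensemble=PARAMS, seed=5)
        cond, _, table = sweep_conditions(X, y, config)
        assert cond.p == 20
        assert table["tpr"].isna().sum() == 1

    def test_all_infeasible_is_an_error(self):
        frame = binary_frame(5, 50)
        X = frame[["f0", "f1", "f2"]].to_numpy()
        y = np.where(frame["behaviour"] == "locomotor play", PLAY, "non-play")
        config = QuantifyConfig(p_grid=(100,), np_negatives=10_000, ensemble=PARAMS)
        with pytest.raises(ValueError, match="no feasible"):
            sweep_conditions(X, y, config)


class TestQuantify:
    def test_per_file_over_under_sums_to_overall(self):
        frame = binary_frame(160, 16000, sep=5.0, seed=6, n_files=5)
        train_f, test_f = split_even(frame, seed=6)
        config = QuantifyConfig(p_grid=(30, 60), np_negatives=2000,
                                ensemble=PARAMS, seed=6)
        res = quantify(train_f, test_f, config, ["f0", "f1", "f2"])
        assert res.per_file is not None
        assert res.per_file["observed"].sum() == res.observed_count
        assert res.per_file["n_windows"].sum() == res.n_test

    def test_adjusted_count_definition(self):
        frame = binary_frame(160, 16000, sep=5.0, seed=7, n_files=5)
        train_f, test_f = split_even(frame, seed=7)
        config = QuantifyConfig(p_grid=(40,), np_negatives=2000,
                                ensemble=PARAMS, seed=7)
        res = quantify(train_f, test_f, config, ["f0", "f1", "f2"])
        assert res.adjusted_count == round(res.adjusted_prevalence * res.n_test)
        assert 0.0 <= res.adjusted_prevalence <= 1.0

    def test_split_even_is_stratified_partition(self):
        frame = binary_frame(30, 5000, seed=8)
        a, b = split_even(frame, seed=8)
        assert len(a) + len(b) == len(frame)
        assert set(a.index).isdisjoint(b.index)
        pos_a = (a["behaviour"] == "locomotor play").sum()
        pos_b = (b["behaviour"] == "locomotor play").sum()
        assert abs(pos_a - pos_b) <= 1


class TestAcUnbiasedness:
    def test_oracle_rates_recover_true_prevalence(self):
        """With exact tpr/fpr, the adjusted estimate is unbiased over
        replicated test draws at several true prevalences."""
        rng = np.random.default_rng(9)
        tpr, fpr, n = 0.85, 0.02, 4000
        for p_true in (0.001, 0.0027, 0.01, 0.05):
            estimates = []
            for _ in range(200):
                pos = rng.random(n) < p_true
                pred = np.where(pos, rng.random(n) < tpr, rng.random(n) < fpr)
                p0 = pred.mean()
                estimates.append((p0 - fpr) / (tpr - fpr))  # no clipping: bias check
            mean_est = np.mean(estimates)
            se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
            assert abs(mean_est - p_true) <= 3 * se + 1e-5

    def test_ac_dominates_classify_and_count_with_oracle_rates(self):
        rng = np.random.default_rng(10)
        tpr, fpr, n = 0.9, 0.03, 4000
        for p_true in (0.0027, 0.01, 0.05):
            ac_err, cc_err = [], []
            for _ in range(200):
                pos = rng.random(n) < p_true
                pred = np.where(pos, rng.random(n) < tpr, rng.random(n) < fpr)
                p0 = pred.mean()
                cc_err.append(abs(p0 - p_true))
                ac_err.append(abs(np.clip((p0 - fpr) / (tpr - fpr), 0, 1) - p_true))
            assert np.mean(ac_err) < np.mean(cc_err)
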