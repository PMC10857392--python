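"""Standardization, post-processing, accuracy, tables and curve fits."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from semgcal import (ClassifierSpec, Standardizer, accuracy,
                     average_accuracy_curves, fit_log_curve,
                     improvement_from_accuracies, mode_postprocess,
                     train_predict)
from semgcal.protocol import DatasetAssembly


class TestStandardizer:
    def test_train_rows_become_standard(self, rng):
        X = rng.standard_normal((50, 4)) * 3.0 + 5.0
        Z = Standardizer().fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_test_row_at_training_mean(self, rng):
        X = rng.standard_normal((50, 4))
        sc = Standardizer().fit(X)
        np.testing.assert_allclose(sc.transform(X.mean(axis=0)[None, :]), 0.0,
                                   atol=1e-10)

    def test_location_invariance(self, rng):
        X = rng.standard_normal((30, 3))
        np.testing.assert_allclose(Standardizer().fit_transform(X),
                                   Standardizer().fit_transform(X + 100.0),
                                   atol=1e-8)

    def test_constant_feature_floored(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        Z = Standardizer().fit_transform(X)
        assert np.all(np.isfinite(Z))


class TestModePostprocess:
    @pytest.mark.parametrize("seq,expected", [
        (list("AABAA"), list("AAAAA")),
        (list("BBBBB"), list("BBBBB")),
        (list("ABC"), list("ABC")),  # causal windows with most-recent tie-break
    ])
    def test_examples(self, seq, expected):
        assert list(mode_postprocess(seq)) == expected

    def test_agreeing_neighbors_never_flipped(self, rng):
        preds = rng.integers(0, 3, size=200)
        out = mode_postprocess(preds)
        for i in range(2, len(preds)):
            if preds[i - 2] == preds[i - 1] == preds[i]:
                assert out[i] == preds[i]

    def test_even_group_rejected(self):
        with pytest.raises(ValueError):
            mode_postprocess([1, 2], group=2)


class TestAccuracy:
    def test_basic_values(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 100.0
        assert accuracy([1, 1], [2, 2]) == 0.0
        assert accuracy([1, 2, 3, 4], [1, 2, 3, 0]) == 75.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


def _toy_features(rng, n_per_class=30, sep=6.0):
    """Linearly separable 2-gesture features spread over two sessions."""
    rows = []
    for session in (1, 2):
        for gesture in (1, 2):
            for trial in (1, 2, 3):
                for frame in range(n_per_class // 6):
                    x = rng.standard_normal(3) + sep * (gesture - 1)
                    rows.append({"session": session, "gesture": gesture,
                                 "trial": trial, "frame": frame,
                                 "f0": x[0], "f1": x[1], "f2": x[2]})
    return pd.DataFrame(rows)


def _toy_assembly():
    train = tuple((1, g, t) for g in (1, 2) for t in (1, 2, 3))
    test = tuple((2, g, t) for g in (1, 2) for t in (1, 2, 3))
    return DatasetAssembly(variant="baseline", test_session=2, n_calib=1,
                           train=train, test=test)


class TestTrainPredict:
    def test_separable_data_perfect(self, rng):
        preds = train_predict(_toy_assembly(), _toy_features(rng), ClassifierSpec())
        assert accuracy(preds["y_pred"], preds["y_true"]) == 100.0

    def test_row_order_insensitive(self, rng):
        feats = _toy_features(rng)
        shuffled = feats.sample(frac=1.0, random_state=1).reset_index(drop=True)
        p1 = train_predict(_toy_assembly(), feats, ClassifierSpec())
        p2 = train_predict(_toy_assembly(), shuffled, ClassifierSpec())
        merged = p1.merge(p2, on=["session", "gesture", "trial", "frame"])
        assert (merged["y_pred_x"] == merged["y_pred_y"]).all()

    def test_single_class_rejected(self, rng):
        feats = _toy_features(rng)
        feats = feats[feats["gesture"] == 1]
        with pytest.raises(ValueError):
            train_predict(_toy_assembly(), feats, ClassifierSpec())

    def test_spec_hash_frozen(self):
        assert ClassifierSpec().config_hash() == ClassifierSpec().config_hash()
        assert ClassifierSpec(seed=1).config_hash() != ClassifierSpec().config_hash()


class TestImprovementArithmetic:
    def test_identical_accuracies_zero(self):
        imp = improvement_from_accuracies(80.0, [80.0] * 5)
        assert imp["average"] == 0.0
        assert imp["per_n_calib"] == [0.0] * 5


class TestCurves:
    def test_average_accuracy_marginals(self):
        grid = pd.DataFrame({
            "n_sessions": [1, 1, 2, 2], "n_trials": [1, 2, 1, 2],
            "accuracy": [0.5, 0.7, 0.6, 0.8],
        })
        aa_trials, aa_sessions = average_accuracy_curves(grid)
        np.testing.assert_allclose(aa_trials.values, [0.55, 0.75])
        np.testing.assert_allclose(aa_sessions.values, [0.6, 0.7])

    def test_constant_grid(self):
        grid = pd.DataFrame({"n_sessions": [1, 1, 2, 2], "n_trials": [1, 2, 1, 2],
                             "accuracy": [0.9] * 4})
        aa_t, aa_s = average_accuracy_curves(grid)
        assert set(aa_t) == set(aa_s) == {0.9}

    def test_incomplete_grid_rejected(self):
        grid = pd.DataFrame({"n_sessions": [1, 1, 2], "n_trials": [1, 2, 1],
                             "accuracy": [0.5, 0.7, 0.6]})
        with pytest.raises(ValueError):
            average_accuracy_curves(grid)


class TestLogFit:
    def test_exact_recovery(self):
        x = np.arange(1, 11, dtype=float)
        fit = fit_log_curve(x, 2.0 * np.log(x) + 3.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_y_convention(self):
        fit = fit_log_curve([1, 2, 3], [5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == 1.0

    def test_noisy_recovery(self, rng):
        x = np.arange(1, 21, dtype=float)
        slopes = []
        for _ in range(100):
            y = 2.0 * np.log(x) + 3.0 + rng.normal(0, 0.01, size=x.size)
            slopes.append(fit_log_curve(x, y).slope)
        assert all(1.9 <= s <= 2.1 for s in slopes)

    def test_matches_closed_form_oracle(self, rng):
        x = np.arange(1, 9, dtype=float)
        y = rng.standard_normal(8)
        fit = fit_log_curve(x, y)
        slope, intercept, r2 = oracle.ols_log_fit(list(x), list(y))
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_log_curve([2, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_log_curve([0.5, 2], [1, 2])
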