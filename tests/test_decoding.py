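import numpy as np
import pytest

from depthpop.decoding import (
    GNBClassifier,
    calibration_curve,
    compare_classifiers,
    decode_choice_timecourse,
    decode_position,
    error_sign_ratio,
    gnb_fit,
    gnb_log_posterior,
    gnb_predict,
    relative_positions,
)


def _two_gaussian_problem(rng, n=200, mu=2.0):
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 1)) + mu * y[:, None]
    return X, y


class TestGaussianNB:
    def _symmetric_model(self):
        # 1 feature, classes with mean 0 / 2, ML variance exactly 1,
        # equal priors
        x0 = np.array([-np.sqrt(2.0), 0.0, 0.0, np.sqrt(2.0)])
        x1 = x0 + 2.0
        X = np.concatenate([x0, x1])[:, None]
        y = np.array([0] * 4 + [1] * 4)
        return gnb_fit(X, y)

    def test_midpoint_posterior_half(self):
        model = self._symmetric_model()
        _, proba = gnb_predict(model, np.array([[1.0]]))
        assert proba[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_closed_form_posterior(self):
        # P(class0 | x) = 1 / (1 + exp(-2 (1 - x))) for unit variances,
        # means 0 and 2, equal priors (hand-derived log-odds)
        model = self._symmetric_model()
        for x in (-1.0, 0.0, 0.5, 1.7, 3.0):
            _, proba = gnb_predict(model, np.array([[x]]))
            expected = 1.0 / (1.0 + np.exp(-2.0 * (1.0 - x)))
            assert proba[0, 0] == pytest.approx(expected, rel=1e-6)
        pred, proba = gnb_predict(model, np.array([[0.0]]))
        assert pred[0] == 0 and proba[0, 0] > 0.5

    def test_single_class_always_predicted(self, rng):
        X = rng.normal(size=(10, 2))
        model = gnb_fit(X, np.zeros(10, int))
        pred, proba = gnb_predict(model, rng.normal(size=(5, 2)))
        assert np.all(pred == 0)
        assert np.allclose(proba, 1.0)

    def test_zero_variance_feature_floored(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = np.arange(20) % 2
        model = gnb_fit(X, y)
        assert np.all(model.var_ > 0)
        logp = gnb_log_posterior(model, X)
        assert np.all(np.isfinite(logp))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.naive_bayes import GaussianNB

        for _ in range(10):
            n_feat = int(rng.integers(1, 5))
            X = rng.normal(size=(60, n_feat)) * rng.uniform(0.5, 3.0)
            y = rng.integers(0, 3, size=60)
            ours = gnb_fit(X, y)
            ref = GaussianNB().fit(X, y)
            Xt = rng.normal(size=(30, n_feat))
            ours_lp = gnb_log_posterior(ours, Xt)
            ref_lp = ref.predict_log_proba(Xt)
            assert np.max(np.abs(ours_lp - ref_lp)) < 1e-9
            assert np.array_equal(gnb_predict(ours, Xt)[0], ref.predict(Xt))

    def test_too_few_per_class(self):
        with pytest.raises(ValueError):
            gnb_fit(np.zeros((3, 1)), np.array([0, 0, 1]))


class TestCalibration:
    def test_calibrated_predictions_on_diagonal(self, rng):
        p = rng.uniform(0, 1, size=20_000)
        labels = (rng.uniform(size=p.size) < p).astype(int)
        curve = calibration_curve(p, labels, n_bins=10)
        assert np.all(np.abs(curve["mean_predicted"]
                             - curve["observed_fraction"]) < 0.05)

    def test_constant_half_single_point(self):
        p = np.full(100, 0.5)
        labels = np.array([0, 1] * 50)
        curve = calibration_curve(p, labels)
        assert len(curve) == 1
        assert curve["mean_predicted"][0] == pytest.approx(0.5)
        assert curve["observed_fraction"][0] == pytest.approx(0.5)

    def test_overconfident_crosses_diagonal(self, rng):
        p = rng.uniform(0, 1, size=30_000)
        labels = (rng.uniform(size=p.size) < p).astype(int)
        sharp = np.where(p > 0.5, 1 - (1 - p) ** 2, p ** 2)  # pushed outward
        curve = calibration_curve(sharp, labels, n_bins=10)
        diff = curve["observed_fraction"] - curve["mean_predicted"]
        assert diff.iloc[0] > 0 and diff.iloc[-1] < 0

    def test_empty_bins_omitted(self):
        curve = calibration_curve(np.full(50, 0.95), np.ones(50))
        assert len(curve) == 1


class TestChoiceTimecourse:
    def test_separable_choices_decoded(self, rng):
        n_trials, n_cells, n_t = 40, 6, 5
        choices = rng.integers(0, 2, size=n_trials)
        aligned = rng.normal(size=(n_trials, n_cells, n_t)) * 0.1
        aligned[:, 0, :] += 3.0 * choices[:, None]
        acc, peak = decode_choice_timecourse(aligned, choices, seed=0)
        assert peak > 0.9

    def test_shuffled_labels_near_chance(self, rng):
        n_trials = 40
        choices = np.array([0, 1] * (n_trials // 2))
        aligned = rng.normal(size=(n_trials, 4, 4))
        acc, peak = decode_choice_timecourse(aligned, choices, seed=0)
        assert np.nanmean(acc) == pytest.approx(0.5, abs=0.15)

    def test_majority_rule(self):
        # 3 of 5 nearest neighbors share a class -> that class wins
        from sklearn.neighbors import KNeighborsClassifier

        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [9.0], [9.1]])
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        clf = KNeighborsClassifier(n_neighbors=5).fit(X, y)
        assert clf.predict([[0.05]])[0] == 1

    def test_too_few_trials(self, rng):
        with pytest.raises(ValueError):
            decode_choice_timecourse(rng.normal(size=(5, 3, 4)),
                                     np.array([0, 1, 0, 1, 0]))

    def test_imbalance_warns(self, rng):
        choices = np.array([0] * 19 + [1])
        aligned = rng.normal(size=(20, 3, 2))
        with pytest.warns(UserWarning):
            decode_choice_timecourse(aligned, choices, seed=0)


class TestDecodePosition:
    def test_single_bin_track_zero_error(self, rng):
        feats = rng.normal(size=(60, 3))
        pos = rng.uniform(0, 2, size=60)
        result, summary = decode_position(feats, pos,
                                          np.array([0.0, 2.0]), n_iter=2,
                                          seed=0)
        assert summary["median_abs_error_cm"] == 0.0
        assert np.all(result["signed_error"] == 0)

    def test_informative_features_recovered(self, rng):
        pos = np.tile(np.linspace(0, 19.9, 100), 4)
        feats = np.column_stack([pos + rng.normal(0, 0.3, pos.size),
                                 rng.normal(size=pos.size)])
        _, summary = decode_position(feats, pos, np.arange(0.0, 20.1, 2.0),
                                     n_iter=3, seed=1)
        assert summary["median_abs_error_cm"] <= 2.0

    def test_probability_in_unit_interval(self, rng):
        feats = rng.normal(size=(80, 3))
        pos = rng.uniform(0, 10, size=80)
        result, _ = decode_position(feats, pos, np.arange(0.0, 10.1, 2.0),
                                    n_iter=1, seed=0)
        assert result["probability"].between(0, 1).all()

    def test_bad_split_mode(self, rng):
        with pytest.raises(ValueError):
            decode_position(rng.normal(size=(30, 2)),
                            rng.uniform(0, 10, 30),
                            np.arange(0.0, 10.1, 2.0), split="bogus")


class TestRelativePositions:
    def test_examples(self):
        # steady rightward run on a 40 cm track
        x = np.linspace(0, 40, 200)
        rel, direction, valid = relative_positions(x, 40.0)
        assert np.all(direction == 1.0)
        assert rel[-1] == pytest.approx(0.0)                    # at the goal
        mid = np.argmin(np.abs(x - 20.0))
        assert rel[mid] == pytest.approx(20.0, abs=0.5)         # L/2 mid-track
        ten = np.argmin(np.abs(x - 10.0))
        assert rel[ten] == pytest.approx(30.0, abs=0.5)         # 40 - 10

    def test_leftward_direction(self):
        x = np.linspace(40, 0, 200)
        rel, direction, _ = relative_positions(x, 40.0)
        assert np.all(direction == -1.0)
        assert rel[0] == pytest.approx(40.0)
        assert rel[-1] == pytest.approx(0.0)

    def test_dwell_flagged_invalid(self):
        x = np.concatenate([np.linspace(0, 40, 100), np.full(50, 40.0),
                            np.linspace(40, 0, 100)])
        _, _, valid = relative_positions(x, 40.0)
        assert not valid[120]  # parked at the end
        assert valid[50]


class TestErrorSignRatio:
    def test_symmetric(self, rng):
        e = rng.normal(size=10_000)
        out = error_sign_ratio(e)
        assert out["positive_fraction"] == pytest.approx(0.5, abs=0.02)
        assert out["positive_fraction"] + out["negative_fraction"] == 1.0

    def test_zeros_counted_separately(self):
        out = error_sign_ratio(np.array([0.0, 0.0, 1.0, -2.0, 3.0]))
        assert out["n_zero"] == 2
        assert out["n_nonzero"] == 3
        assert out["positive_fraction"] == pytest.approx(2 / 3)

    def test_all_zero_flagged(self):
        with pytest.warns(UserWarning):
            out = error_sign_ratio(np.zeros(5))
        assert np.isnan(out["positive_fraction"])


class TestCompareClassifiers:
    def test_roster_of_one(self, rng):
        X, y = _two_gaussian_problem(rng)
        out = compare_classifiers(X, y, roster={"gnb": GNBClassifier()},
                                  seed=0)
        assert set(out) == {"gnb"}
        assert out["gnb"]["accuracy"] > 0.7

    def test_failing_classifier_recorded(self, rng):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("nope")

        X, y = _two_gaussian_problem(rng)
        with pytest.warns(UserWarning):
            out = compare_classifiers(
                X, y, roster={"bad": Broken(), "gnb": GNBClassifier()},
                seed=0)
        assert np.isnan(out["bad"]["accuracy"])
        assert out["gnb"]["accuracy"] > 0.7

    def test_shuffled_labels_chance(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(400, 3))
        y = rng.integers(0, 2, size=400)
        out = compare_classifiers(
            X, y, roster={"gnb": GNBClassifier(),
                          "knn": KNeighborsClassifier(5)}, seed=0)
        for rec in out.values():
            assert rec["accuracy"] == pytest.approx(0.5, abs=0.15)
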