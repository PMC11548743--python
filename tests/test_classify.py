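"""Random-forest ethogram classifiers: PR curves, thresholds, prediction."""

import numpy as np
import pandas as pd
import pytest

from ethousv.classify import (
    BEHAVIORS,
    machine_results,
    pr_curve,
    predict_frames,
    select_threshold,
    train_classifiers,
)


def brute_force_max_f1(scores, truth):
    """Exhaustive max F1 over all strict-> thresholds (independent oracle)."""
    best = 0.0
    for t in np.concatenate(([0.0], np.unique(scores))):
        pred = scores > t
        tp = np.sum(pred & (truth == 1))
        fp = np.sum(pred & (truth == 0))
        fn = np.sum(~pred & (truth == 1))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        best = max(best, f1)
    return best


class TestPrCurve:
    def test_perfect_scores_reach_f1_one(self):
        truth = np.array([0, 1, 0, 1, 1])
        curve = pr_curve(truth.astype(float), truth)
        t, f1 = select_threshold(curve)
        assert f1 == pytest.approx(1.0)
        # with strict-> semantics any threshold below the lowest positive
        # score is perfect; the curve's evaluated points include 0
        assert 0 <= t < 1

    def test_four_point_example_against_enumeration(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        truth = np.array([1, 0, 1, 0])
        curve = pr_curve(scores, truth)
        # enumerate: t<0.3 predicts {0.9, 0.8, 0.3}: P=2/3, R=1, F1=0.8 is
        # the maximum; the all-positive threshold gives 2/3
        assert brute_force_max_f1(scores, truth) == pytest.approx(0.8)
        _, f1 = select_threshold(curve)
        assert f1 == pytest.approx(0.8)
        all_pos = curve[curve["threshold"] == 0.0].iloc[0]
        assert all_pos["f1"] == pytest.approx(2 / 3)

    def test_anticorrelated_scores_best_is_all_positive(self):
        truth = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        scores = 1.0 - truth * 0.5  # positives get the lowest scores
        curve = pr_curve(scores, truth)
        prev = truth.mean()
        _, f1 = select_threshold(curve)
        assert f1 == pytest.approx(2 * prev / (1 + prev))
        assert f1 == pytest.approx(brute_force_max_f1(scores, truth))

    def test_matches_exhaustive_counting_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = rng.random(n).round(2)
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            curve = pr_curve(scores, truth)
            _, f1 = select_threshold(curve)
            assert f1 == pytest.approx(brute_force_max_f1(scores, truth))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.1, 0.9]), np.array([1, 1]))


class TestSelectThreshold:
    def test_plateau_tie_breaks_to_highest_threshold(self):
        curve = pd.DataFrame(
            {
                "threshold": [0.1, 0.2, 0.3, 0.4],
                "precision": [1, 1, 1, 0.5],
                "recall": [0.5, 0.5, 0.5, 0.5],
                "f1": [0.6, 0.6, 0.6, 0.4],
            }
        )
        t, f1 = select_threshold(curve)
        assert (t, f1) == (0.3, 0.6)

    def test_monotone_decreasing_f1_returns_first_point(self):
        curve = pd.DataFrame(
            {
                "threshold": [0.0, 0.5, 0.9],
                "precision": [1, 1, 1],
                "recall": [1, 0.5, 0.1],
                "f1": [1.0, 2 / 3, 0.18],
            }
        )
        t, _ = select_threshold(curve)
        assert t == 0.0


def _toy_features(n, rng):
    return pd.DataFrame(
        rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)]
    )


class TestTraining:
    def test_separable_feature_reaches_f1_one(self):
        rng = np.random.default_rng(0)
        X = _toy_features(400, rng)
        y = pd.DataFrame({"nosing": (X["f0"] > 0.3).astype(int)})
        bundle = train_classifiers(X, y, seed=0)
        assert bundle.classifiers["nosing"].max_f1 == pytest.approx(1.0)

    def test_shuffled_labels_f1_near_prevalence(self):
        """Permutation baseline: with labels independent of features the
        held-out F1 hovers around the positive prevalence."""
        rng = np.random.default_rng(1)
        f1s = []
        prev = 0.3
        for rep in range(20):
            X = _toy_features(300, rng)
            y = pd.DataFrame({"b": (rng.random(300) < prev).astype(int)})
            bundle = train_classifiers(X, y, seed=rep)
            f1s.append(bundle.classifiers["b"].max_f1)
        # max-F1 selection biases upward relative to prevalence; it must
        # stay far below a real signal
        assert prev - 0.1 < np.mean(f1s) < prev + 0.25

    def test_eleven_behaviors_eleven_models(self, trained_bundle):
        assert set(trained_bundle.classifiers) == set(BEHAVIORS)
        assert sum(
            not c.untrainable for c in trained_bundle.classifiers.values()
        ) == 11

    def test_single_class_behavior_marked_untrainable(self):
        rng = np.random.default_rng(2)
        X = _toy_features(100, rng)
        y = pd.DataFrame(
            {"never": np.zeros(100, dtype=int), "real": (X["f1"] > 0).astype(int)}
        )
        bundle = train_classifiers(X, y, seed=0)
        assert bundle.classifiers["never"].untrainable
        assert not bundle.classifiers["real"].untrainable

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        X = _toy_features(200, rng)
        y = pd.DataFrame({"b": (X["f0"] + 0.3 * rng.normal(size=200) > 0).astype(int)})
        b1 = train_classifiers(X, y, seed=7)
        b2 = train_classifiers(X, y, seed=7)
        assert b1.classifiers["b"].detection_threshold == b2.classifiers["b"].detection_threshold
        p1, _ = predict_frames(b1, X)
        p2, _ = predict_frames(b2, X)
        pd.testing.assert_frame_equal(p1, p2)


class TestPrediction:
    def _bundle_and_features(self, seed=0):
        rng = np.random.default_rng(seed)
        X = _toy_features(300, rng)
        y = pd.DataFrame(
            {"b": ((X["f0"] + 0.5 * rng.normal(size=300)) > 0).astype(int)}
        )
        return train_classifiers(X, y, seed=seed), X

    def test_probability_equal_to_threshold_is_absent(self):
        bundle, X = self._bundle_and_features()
        clf = bundle.classifiers["b"]
        _, proba = predict_frames(bundle, X)
        p = proba["Probability_b"].to_numpy()
        clf.detection_threshold = float(p[0])
        binary, _ = predict_frames(bundle, X)
        assert binary["b"].iloc[0] == 0  # strict >

    def test_zero_threshold_marks_every_nonzero_probability(self):
        bundle, X = self._bundle_and_features()
        bundle.classifiers["b"].detection_threshold = 0.0
        binary, proba = predict_frames(bundle, X)
        assert (
            binary["b"].to_numpy() == (proba["Probability_b"].to_numpy() > 0)
        ).all()

    def test_raising_threshold_never_increases_positives(self):
        bundle, X = self._bundle_and_features()
        counts = []
        for t in np.linspace(0, 1, 11):
            bundle.classifiers["b"].detection_threshold = t
            binary, _ = predict_frames(bundle, X)
            counts.append(binary["b"].sum())
        assert (np.diff(counts) <= 0).all()

    def test_manifest_mismatch_names_missing_columns(self):
        bundle, X = self._bundle_and_features()
        with pytest.raises(ValueError, match="f4"):
            predict_frames(bundle, X.drop(columns=["f4"]))

    def test_machine_results_layout(self):
        bundle, X = self._bundle_and_features()
        mr = machine_results(bundle, X)
        assert list(mr.columns) == ["Probability_b", "b"]
        assert mr["b"].isin([0, 1]).all()

    def test_bundle_round_trip_and_config_override(self, tmp_path):
        import yaml

        from ethousv.classify import ClassifierBundle

        bundle, X = self._bundle_and_features()
        path = tmp_path / "bundle.joblib"
        bundle.save(path)
        back = ClassifierBundle.load(path)
        p1, _ = predict_frames(bundle, X)
        p2, _ = predict_frames(back, X)
        pd.testing.assert_frame_equal(p1, p2)
        bundle.override_thresholds({"b": 0.9})
        assert bundle.classifiers["b"].detection_threshold == 0.9
        with pytest.raises(KeyError):
            bundle.override_thresholds({"ghost": 0.1})
        cfg_path = tmp_path / "cfg.yaml"
        bundle.to_config_yaml(cfg_path)
        cfg = yaml.safe_load(cfg_path.read_text())
        assert cfg["behaviors"]["b"]["detection_threshold"] == 0.9
        assert cfg["behaviors"]["b"]["min_bout_frames"] == 0


class TestEndToEndRecovery:
    def test_scripted_session_f1_above_08_at_zero_noise(
        self, trained_bundle, all_behaviors_session
    ):
        """A clean scripted session is recovered by the trained forests
        with per-behavior frame F1 >= 0.8."""
        from sklearn.metrics import f1_score

        from ethousv.features import extract_features
        from ethousv.pose import interpolate_track

        _, track, truth = all_behaviors_session
        feats = extract_features(interpolate_track(track))
        binary, _ = predict_frames(trained_bundle, feats)
        for b in BEHAVIORS:
            f1 = f1_score(truth.behavior_frames[b], binary[b])
            assert f1 >= 0.8, (b, f1)
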