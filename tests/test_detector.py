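"""Forest classifier: training contracts, prediction, ROC, LOSO protocol,
cost asymmetry, and portable serialization."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import fogkit
from fogkit import (
    FeatureSet,
    FogModel,
    ForestConfig,
    SyntheticConfig,
    extract_features,
    generate_recording,
    leave_one_subject_out,
    predict,
    roc_curve,
    train,
)
from fogkit.core import FogLabel, ValidationError
from fogkit.detector import FogPredictionTrack


def merge(sets):
    return FeatureSet(
        times=np.concatenate([f.times for f in sets]),
        matrix=np.vstack([f.matrix for f in sets]),
        labels=np.concatenate([f.labels for f in sets]),
        subject_id="pooled",
        columns=sets[0].columns,
    )


class TestTrain:
    def test_separable_synthetic_resubstitution(self):
        """Trembling vs walking at default amplitudes is separable once
        windows straddling an episode boundary (mixed content) are
        excluded: resubstitution accuracy 100%."""
        rec, truth = generate_recording(
            SyntheticConfig(duration=180.0, seed=51)
        )
        feats = extract_features(rec, hop=32)
        n = 256
        ends = (feats.times * rec.sampling_rate).round().astype(int)
        pure = np.array(
            [
                truth.fog_mask[e - n + 1: e + 1].all()
                or not truth.fog_mask[e - n + 1: e + 1].any()
                for e in ends
            ]
        )
        sep = FeatureSet(
            feats.times[pure], feats.matrix[pure], feats.labels[pure],
            "sep", feats.columns,
        )
        model = train(sep, ForestConfig(seed=0))
        track = predict(model, sep)
        assert np.array_equal(
            track.labels_pred, sep.labels == int(FogLabel.FOG)
        )

    def test_single_class_error(self, walking_recording):
        rec, _ = walking_recording
        feats = extract_features(rec, hop=32)
        with pytest.raises(ValidationError, match="degenerate"):
            train(feats)

    def test_determinism_and_row_order_invariance(self, small_cohort):
        pooled = merge(list(small_cohort.values()))
        probe = list(small_cohort.values())[0]
        m1 = train(pooled, ForestConfig(seed=3))
        m2 = train(pooled, ForestConfig(seed=3))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pooled))
        shuffled = FeatureSet(
            pooled.times[perm], pooled.matrix[perm], pooled.labels[perm],
            "pooled", pooled.columns,
        )
        m3 = train(shuffled, ForestConfig(seed=3))
        p1 = m1.predict_proba(probe.matrix)
        np.testing.assert_array_equal(p1, m2.predict_proba(probe.matrix))
        np.testing.assert_array_equal(p1, m3.predict_proba(probe.matrix))


class TestPredict:
    def test_duplicate_windows_identical(self, trained_model, small_cohort):
        probe = list(small_cohort.values())[0]
        row = probe.matrix[[5]]
        dup = np.repeat(row, 4, axis=0)
        p = trained_model.predict_proba(dup)
        assert np.all(p == p[0])

    def test_all_walking_low_fog_rate(self, trained_model, walking_recording):
        rec, _ = walking_recording
        feats = extract_features(rec, hop=32)
        track = predict(trained_model, feats)
        assert track.labels_pred.mean() <= 0.05

    def test_threshold_boundaries(self, trained_model, small_cohort):
        probe = list(small_cohort.values())[0]
        cfg0 = ForestConfig(decision_threshold=0.0)
        m = FogModel(trained_model.forest, cfg0, trained_model.columns)
        assert predict(m, probe).labels_pred.all()

    def test_dimension_mismatch(self, trained_model):
        with pytest.raises(ValidationError, match="dimension"):
            trained_model.predict_proba(np.zeros((3, 5)))


class TestRocCurve:
    def make_track(self, probs, truth):
        probs = np.asarray(probs, dtype=float)
        return FogPredictionTrack(
            window_end_times=np.arange(len(probs), dtype=float),
            probabilities=probs,
            labels_pred=probs >= 0.5,
            labels_true=np.asarray(truth, dtype=bool),
        )

    def test_perfect_probabilities(self):
        t = self.make_track([1.0, 1.0, 0.0], [1, 1, 0])
        _, auc = roc_curve(t)
        assert auc == 1.0

    def test_constant_probabilities(self):
        t = self.make_track([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0])
        _, auc = roc_curve(t)
        assert auc == 0.5

    def test_hand_built_four_windows(self):
        """probs .9,.8,.3,.1 / truth 1,1,0,0: every threshold separates
        cleanly, AUC 1 by hand enumeration."""
        t = self.make_track([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        points, auc = roc_curve(t)
        assert auc == 1.0
        assert (points[0] == [0.0, 0.0]).all()
        assert (points[-1] == [1.0, 1.0]).all()

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(size=300)
        truth = rng.uniform(size=300) < probs  # informative labels
        t = self.make_track(probs, truth)
        _, auc = roc_curve(t)
        assert auc == pytest.approx(roc_auc_score(truth, probs), abs=1e-12)

    def test_single_class_error(self):
        t = self.make_track([0.4, 0.6], [1, 1])
        with pytest.raises(ValidationError, match="both classes"):
            roc_curve(t)


class TestLoso:
    def test_requires_two_subjects(self, small_cohort):
        one = dict(list(small_cohort.items())[:1])
        with pytest.raises(ValidationError, match="2 subjects"):
            leave_one_subject_out(one)

    def test_report_consistency(self, small_cohort):
        """Per-subject metrics match a brute-force confusion recount and
        the ROC is monotone."""
        report = leave_one_subject_out(small_cohort, ForestConfig(seed=1))
        for score in report.per_subject:
            assert score.sensitivity is None or 0 <= score.sensitivity <= 1
            assert score.specificity is None or 0 <= score.specificity <= 1
        sens = [
            s.sensitivity for s in report.per_subject
            if s.sensitivity is not None
        ]
        assert report.mean_sensitivity == pytest.approx(np.mean(sens))
        pts = report.roc_points
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()
        assert 0.0 <= report.auc <= 1.0
        # brute-force recount of the pooled confusion at threshold 0.5
        pooled = report.pooled
        tp = fn = tn = fp = 0
        for p, y in zip(pooled.probabilities, pooled.labels_true):
            pred = p >= 0.5
            tp += pred and y
            fn += (not pred) and y
            tn += (not pred) and (not y)
            fp += pred and (not y)
        assert tp + fn == sum(s.n_fog_windows for s in report.per_subject)
        assert tn + fp == sum(s.n_nofog_windows for s in report.per_subject)

    def test_no_leakage_under_permutation(self, small_cohort):
        """Held-out predictions do not change when the *other* subjects'
        window order is permuted."""
        subjects = list(small_cohort)
        r1 = leave_one_subject_out(small_cohort, ForestConfig(seed=2))
        rng = np.random.default_rng(1)
        permuted = {}
        for i, (sid, f) in enumerate(small_cohort.items()):
            perm = rng.permutation(len(f))
            permuted[sid] = FeatureSet(
                f.times[perm], f.matrix[perm], f.labels[perm], sid, f.columns
            )
        r2 = leave_one_subject_out(permuted, ForestConfig(seed=2))
        for s1, s2 in zip(r1.per_subject, r2.per_subject):
            assert s1.subject_id == s2.subject_id
            assert s1.sensitivity == s2.sensitivity
            assert s1.specificity == s2.specificity

    def test_subject_without_fog_flagged_undefined(self, small_cohort):
        rec, _ = generate_recording(
            SyntheticConfig(duration=120.0, fog_episode_rate=0.0, seed=31)
        )
        cohort = dict(small_cohort)
        cohort[rec.subject_id] = extract_features(rec, hop=32)
        report = leave_one_subject_out(cohort, ForestConfig(seed=0))
        score = next(
            s for s in report.per_subject if s.subject_id == rec.subject_id
        )
        assert score.sensitivity is None
        assert score.n_fog_windows == 0
        assert report.mean_sensitivity is not None  # others still counted


class TestCostAsymmetry:
    def test_fn_cost_raises_sensitivity_on_hard_problem(self):
        """On a noisy imbalanced cohort, the 10x false-negative cost does
        not lower held-out sensitivity relative to symmetric cost."""
        def cohort(seed):
            rec, _ = generate_recording(
                SyntheticConfig(
                    duration=120.0, seed=seed,
                    freeze_tremble_amplitude=0.25, noise_sd=0.4,
                )
            )
            return extract_features(rec, hop=32)

        subjects = {f"s{i}": cohort(40 + i) for i in range(3)}
        sens = {}
        for ratio in (1.0, 10.0):
            vals = []
            for rep in range(3):
                cfg = ForestConfig(
                    false_negative_cost_ratio=ratio, seed=rep
                )
                r = leave_one_subject_out(subjects, cfg)
                vals.append(r.mean_sensitivity)
            sens[ratio] = np.mean(vals)
        assert sens[10.0] >= sens[1.0] - 1e-9


class TestSerialization:
    def test_json_round_trip_probabilities(self, trained_model, small_cohort,
                                           tmp_path):
        path = tmp_path / "model.json"
        trained_model.to_json(path)
        loaded = FogModel.from_json(path)
        probe = list(small_cohort.values())[1]
        p_sk = trained_model.predict_proba(probe.matrix)
        p_js = loaded.predict_proba(probe.matrix)
        np.testing.assert_allclose(p_js, p_sk, atol=1e-12)
        assert loaded.config == trained_model.config
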