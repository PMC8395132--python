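"""Feature extraction, classifier training, segmentation, categories."""

from dataclasses import replace

import numpy as np
import pytest

from smtrack import modeclass as mc
from smtrack.msdfit import select_model, compute_msd
from smtrack.trajsim import (SimulationConfig, Trajectory, simulate_brownian,
                             simulate_confined, simulate_directed,
                             simulate_switching)


class TestExtractFeatures:
    def test_window_count_arithmetic(self):
        t = simulate_brownian(SimulationConfig(n_steps=41, seed=0))
        feats = mc.extract_features(t, window=15)
        assert feats.shape == (41 - 15 + 1, len(mc.FEATURE_NAMES))

    def test_scale_invariance(self):
        t = simulate_brownian(SimulationConfig(n_steps=40, seed=1))
        doubled = Trajectory(id=0, frames=t.frames, xy=2.0 * t.xy, dt=t.dt)
        np.testing.assert_allclose(mc.extract_features(t, 15),
                                   mc.extract_features(doubled, 15), rtol=1e-9)

    def test_too_short_trajectory_rejected(self):
        t = simulate_brownian(SimulationConfig(n_steps=10, seed=0))
        with pytest.raises(ValueError):
            mc.extract_features(t, window=15)

    def test_confined_windows_grow_sublinearly(self):
        """Mean lag-8/lag-1 MSD ratio separates confined from Brownian."""
        ratios = {"brownian": [], "confined": []}
        for k in range(300):
            b = simulate_brownian(SimulationConfig(D=0.1, n_steps=15, seed=k))
            c = simulate_confined(SimulationConfig(D=0.1, L=0.3, n_steps=15, seed=k))
            ratios["brownian"].append(mc._window_features(b.xy)[6])
            ratios["confined"].append(mc._window_features(c.xy)[6])
        assert np.mean(ratios["confined"]) < 0.5 * np.mean(ratios["brownian"])


class TestTrainingSet:
    def test_classes_exactly_balanced(self, training_table):
        counts = training_table["label"].value_counts()
        assert set(counts.index) == set(mc.MODES)
        assert counts.nunique() == 1 and counts.iloc[0] == 600

    def test_same_seed_reproduces_table(self, training_table):
        again = mc.build_training_set(n_per_class=600, seed=7)
        assert training_table.equals(again)

    def test_no_constant_feature_column(self, training_table):
        stds = training_table[list(mc.FEATURE_NAMES)].std()
        assert (stds > 0).all()

    def test_degenerate_grid_rejected(self):
        grids = mc.default_training_grids()
        grids["confined"] = []
        with pytest.raises(ValueError, match="degenerate"):
            mc.build_training_set(grids, n_per_class=10)


class TestTraining:
    def test_holdout_accuracy_gate(self, mode_classifier):
        assert mode_classifier.holdout_accuracy >= 0.90

    def test_training_is_deterministic(self):
        t1 = mc.build_training_set(n_per_class=600, seed=7)
        c1 = mc.train_mode_classifier(t1, seed=7)
        c2 = mc.train_mode_classifier(t1.copy(), seed=7)
        assert c1.holdout_accuracy == c2.holdout_accuracy

    def test_permuted_labels_near_chance(self, training_table):
        rng = np.random.default_rng(0)
        shuffled = training_table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        with pytest.raises(RuntimeError, match="accuracy"):
            mc.train_mode_classifier(shuffled, seed=0)
        clf = mc.train_mode_classifier(shuffled, seed=0, min_accuracy=0.0)
        assert clf.holdout_accuracy < 0.45  # ~ 1/3 at chance

    def test_artifact_round_trip(self, mode_classifier, tmp_path):
        path = tmp_path / "clf.joblib"
        mode_classifier.save(path)
        loaded = mc.ModeClassifier.load(path)
        t = simulate_brownian(SimulationConfig(n_steps=30, seed=5))
        feats = mc.extract_features(t, 15)
        np.testing.assert_array_equal(mode_classifier.predict(feats),
                                      loaded.predict(feats))


class TestClassifyPoints:
    def test_pure_brownian_mostly_brownian_labels(self, mode_classifier):
        fracs = []
        for k in range(100):
            t = simulate_brownian(SimulationConfig(D=0.1, n_steps=100, seed=k))
            labels = mc.classify_points(t, mode_classifier)
            fracs.append(np.mean([l == "brownian" for l in labels]))
        assert np.median(fracs) >= 0.90

    def test_no_run_shorter_than_confidence_bound(self, mode_classifier):
        for k in range(30):
            t = simulate_switching(SimulationConfig(D=0.1, L=0.3, n_steps=150,
                                                    seed=k))
            labels = mc.classify_points(t, mode_classifier)
            runs = mc._runs(labels)
            assert all(end - start >= mc.MIN_SEGMENT_FRAMES
                       for start, end, _ in runs)

    def test_degenerate_vote_is_unanimous(self):
        labels = mc._smooth_labels(["confined"] * 50, 15)
        assert labels == ["confined"] * 50

    def test_missing_classifier_rejected(self):
        t = simulate_brownian(SimulationConfig(n_steps=30, seed=0))
        with pytest.raises(ValueError):
            mc.classify_points(t, None)

    @pytest.mark.parametrize("mode,sim,param", [
        ("brownian", simulate_brownian, {}),
        ("confined", simulate_confined, {"L": 0.3}),
        ("directed", simulate_directed, {"v": 1.5}),
    ])
    def test_per_class_trajectory_recall(self, mode_classifier, mode, sim, param):
        """Whole-trajectory recall >= 85% per class at reference parameters
        (D = 0.1 um^2/s, L = 0.3 um, v = 1.5 um/s, 50 nm noise)."""
        hits = 0
        for k in range(60):
            cfg = SimulationConfig(D=0.1, loc_sigma=0.05, n_steps=120,
                                   seed=k, **param)
            labels = mc.classify_points(sim(cfg), mode_classifier)
            if max(set(labels), key=labels.count) == mode:
                hits += 1
        assert hits >= 0.85 * 60

    def test_agreement_with_msd_model_selection(self, mode_classifier):
        """Window-vote labels agree with the MSD model-selection oracle on
        pure-mode whole trajectories."""
        agree = total = 0
        for k in range(40):
            for sim, param in ((simulate_brownian, {}),
                               (simulate_confined, {"L": 0.3}),
                               (simulate_directed, {"v": 1.5})):
                t = sim(SimulationConfig(D=0.1, n_steps=120, seed=k, **param))
                labels = mc.classify_points(t, mode_classifier)
                vote = max(set(labels), key=labels.count)
                oracle = select_model(compute_msd(t, 12)).mode
                agree += vote == oracle
                total += 1
        assert agree / total >= 0.85


class TestSegmentation:
    def test_single_mode_gives_one_segment(self, mode_classifier):
        t = simulate_brownian(SimulationConfig(D=0.2, n_steps=100, seed=3))
        res = mc.segment_and_fit(t, ["brownian"] * 100)
        assert len(res.segments) == 1
        assert res.segments[0].start == 0 and res.segments[0].end == 100
        assert res.category == "brownian"

    def test_segment_fit_schema_by_mode(self, mode_classifier):
        t = simulate_switching(SimulationConfig(D=0.1, L=0.3, n_steps=200,
                                                seed=11, dwell_brownian=4.0,
                                                dwell_confined=4.0))
        res = mc.segment_and_fit(t, t.truth_labels)
        for seg in res.segments:
            if seg.fit is None:
                continue
            if seg.mode == "confined":
                assert seg.fit.L is not None and seg.fit.conf_diameter is not None
            if seg.mode == "brownian":
                assert seg.fit.L is None and seg.fit.v is None

    def test_boundary_error_within_half_window(self, mode_classifier):
        errors = []
        for k in range(60):
            t = simulate_switching(SimulationConfig(
                D=0.1, L=0.3, n_steps=200, seed=k,
                dwell_brownian=4.0, dwell_confined=4.0, min_epoch_frames=30))
            pred = mc.classify_points(t, mode_classifier)
            true_cp = [i for i in range(1, 200)
                       if t.truth_labels[i] != t.truth_labels[i - 1]]
            pred_cp = [i for i in range(1, 200) if pred[i] != pred[i - 1]]
            for cp in true_cp:
                if pred_cp:
                    errors.append(min(abs(cp - p) for p in pred_cp))
        assert np.median(errors) <= 15 / 2

    def test_mislabeled_length_rejected(self):
        t = simulate_brownian(SimulationConfig(n_steps=50, seed=0))
        with pytest.raises(ValueError):
            mc.segment_and_fit(t, ["brownian"] * 49)


class TestTrajectoryCategory:
    def seg(self, mode):
        return mc.Segment(start=0, end=10, mode=mode)

    @pytest.mark.parametrize("modes,expected", [
        (["brownian"], "brownian"),
        (["confined"], "confined"),
        (["brownian", "confined", "brownian"], "mixed"),
        (["brownian", "directed"], "directed"),
        ([], "unclassified"),
    ])
    def test_category_rules(self, modes, expected):
        assert mc.trajectory_category([self.seg(m) for m in modes]) == expected

    def test_switching_simulations_mostly_mixed(self, mode_classifier):
        cats = []
        for k in range(100):
            t = simulate_switching(SimulationConfig(
                D=0.1, L=0.3, n_steps=200, seed=k,
                dwell_brownian=4.0, dwell_confined=4.0, min_epoch_frames=30))
            cats.append(mc.classify_trajectory(t, mode_classifier).category)
        assert np.mean([c == "mixed" for c in cats]) >= 0.80

    def test_mixture_fractions_recovered(self, mode_classifier):
        """A 60/25/15 Brownian/switching/confined population is recovered
        within 10 percentage points per category."""
        from collections import Counter

        cats = []
        base = SimulationConfig(D=0.1, L=0.3, n_steps=120)
        for k in range(300):
            if k < 180:
                t = simulate_brownian(replace(base, seed=k))
            elif k < 255:
                t = simulate_switching(replace(base, seed=k))
            else:
                t = simulate_confined(replace(base, seed=k))
            cats.append(mc.classify_trajectory(t, mode_classifier).category)
        counts = Counter(cats)
        n = len(cats)
        assert abs(counts["brownian"] / n - 0.60) <= 0.10
        assert abs(counts["mixed"] / n - 0.25) <= 0.10
        assert abs(counts["confined"] / n - 0.15) <= 0.10
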