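"""Feature extraction, label schemes, SVM training, CV decoding, significance."""

import numpy as np
import pytest
from scipy import stats

from megbody.decode import (
    CHANCE,
    FeatureSet,
    SchemeResult,
    crossval_decode,
    extract_features,
    make_labels,
    train_classifier,
)
from megbody.decode import test_significance as significance
from megbody.simulate import StimulusSet

from conftest import make_epochs


def toy_featureset(x, image_id, n_windows=1):
    """Wrap a (trials, channels) matrix as a FeatureSet."""
    feats = np.repeat(x[None], n_windows, axis=0)
    stim = StimulusSet.default()
    cat_of = dict(zip(stim.image_ids.tolist(), stim.category.tolist()))
    return FeatureSet(
        features=feats,
        window_starts=np.arange(n_windows, dtype=float) * 10.0 - 100.0,
        window_ms=20.0,
        image_id=np.asarray(image_id),
        category=np.asarray([cat_of[int(i)] for i in image_id], dtype=object),
    )


def clouds(rng, n_per_class, n_features=6, sep=6.0):
    """Three well-separated Gaussian clouds; returns (X, class labels)."""
    centers = sep * np.eye(3, n_features)
    x = np.vstack(
        [centers[k] + rng.standard_normal((n_per_class, n_features)) for k in range(3)]
    )
    y = np.repeat(np.arange(3), n_per_class)
    return x, y


class TestExtractFeatures:
    def test_default_grid_has_59_windows(self):
        ep = make_epochs(np.zeros((2, 8, 1000)), sfreq=1000.0)
        fs = extract_features(ep)
        assert fs.n_windows == 59
        assert fs.window_starts[0] == -100.0
        assert fs.window_starts[-1] == 480.0

    def test_constant_signal_gives_constant_features(self):
        ep = make_epochs(np.full((3, 8, 1000), 4.2), sfreq=1000.0)
        fs = extract_features(ep)
        np.testing.assert_allclose(fs.features, 4.2)

    def test_feature_count_equals_channels(self, clean_subject):
        fs = extract_features(clean_subject)
        assert fs.features.shape[2] == clean_subject.n_channels == 24

    def test_out_of_range_rejected(self):
        ep = make_epochs(np.zeros((2, 8, 100)), sfreq=1000.0, tmin_ms=-50.0)
        with pytest.raises(ValueError):
            extract_features(ep, trange=(-100.0, 500.0))


class TestMakeLabels:
    def test_categorical_matches_true_categories(self):
        stim = StimulusSet.default()
        lab = make_labels(stim, "categorical")
        assert sorted(lab.mapping) == list(range(1, 13))
        sizes = np.bincount(list(lab.mapping.values()))
        assert sizes.tolist() == [4, 4, 4]
        assert lab.mapping[1] == 0 and lab.mapping[5] == 1 and lab.mapping[9] == 2

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_random_partition_never_category_pure(self, seed):
        stim = StimulusSet.default()
        lab = make_labels(stim, "random", seed=seed)
        cat_of = dict(zip(stim.image_ids.tolist(), stim.category.tolist()))
        for k in range(3):
            imgs = [i for i, c in lab.mapping.items() if c == k]
            assert len(imgs) == 4
            assert len({cat_of[i] for i in imgs}) >= 2

    def test_random_partition_deterministic(self):
        stim = StimulusSet.default()
        a = make_labels(stim, "random", seed=5)
        b = make_labels(stim, "random", seed=5)
        assert a.mapping == b.mapping

    def test_object_images_unlabelled(self):
        lab = make_labels(StimulusSet.default(), "categorical")
        y = lab.labels_for(np.array([13, 14, 1]))
        assert y.tolist() == [-1, -1, 0]


class TestTrainClassifier:
    def test_separable_clouds_fit_perfectly(self):
        x, y = clouds(np.random.default_rng(0), 20)
        clf = train_classifier(x, y)
        assert (clf.predict(x) == y).mean() == 1.0
        assert clf.weights.shape == (3, 6)
        assert clf.biases.shape == (3,)

    def test_duplicated_training_set_same_decision(self):
        x, y = clouds(np.random.default_rng(1), 15)
        a = train_classifier(x, y)
        b = train_classifier(np.vstack([x, x]), np.concatenate([y, y]))
        xt = np.random.default_rng(2).standard_normal((50, 6))
        np.testing.assert_array_equal(a.predict(xt), b.predict(xt))

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).standard_normal((10, 4))
        with pytest.raises(ValueError):
            train_classifier(x, np.zeros(10, dtype=int))


class TestCrossvalDecode:
    def test_separable_features_decode_perfectly(self):
        rng = np.random.default_rng(3)
        x, y = clouds(rng, 40)
        image_id = np.concatenate(
            [rng.permutation(np.repeat(np.arange(1 + 4 * k, 5 + 4 * k), 10))
             for k in range(3)]
        )
        fs = toy_featureset(x, image_id, n_windows=3)
        res = crossval_decode(fs, make_labels(StimulusSet.default()), seed=0)
        np.testing.assert_allclose(res.accuracy, 1.0)

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(4)
        x, _ = clouds(rng, 40)
        image_id = rng.permutation(np.repeat(np.arange(1, 13), 10))
        fs = toy_featureset(x, image_id, n_windows=8)
        res = crossval_decode(fs, make_labels(StimulusSet.default()), seed=0)
        se = np.sqrt(CHANCE * (1 - CHANCE) / 120)
        assert abs(res.accuracy.mean() - CHANCE) < 3 * se

    def test_full_design_fold_arithmetic(self):
        """480 body trials with 10 stratified folds: 48 per fold, 16 per class."""
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat(np.arange(3), 160)
        folds = list(
            StratifiedKFold(n_splits=10, shuffle=True, random_state=0).split(
                np.zeros(480), y
            )
        )
        for _, te in folds:
            assert len(te) == 48
            assert np.bincount(y[te]).tolist() == [16, 16, 16]

    def test_accuracy_invariant_to_channel_permutation_and_scale(self):
        rng = np.random.default_rng(5)
        x, _ = clouds(rng, 40, sep=2.0)
        image_id = np.repeat(np.arange(1, 13), 10)
        fs1 = toy_featureset(x, image_id)
        perm = rng.permutation(x.shape[1])
        fs2 = toy_featureset(5.0 * x[:, perm], image_id)
        lab = make_labels(StimulusSet.default())
        r1 = crossval_decode(fs1, lab, seed=2)
        r2 = crossval_decode(fs2, lab, seed=2)
        np.testing.assert_allclose(r1.accuracy, r2.accuracy, atol=1e-12)


class TestTemporalSpecificity:
    def test_pre_stimulus_windows_decode_at_chance(self):
        """Windows ending before +100 ms carry no category information:
        the evoked response starts at 120 ms and the causal high-pass does
        not smear it backwards."""
        from megbody.experiments import EFFECT_CONFIG, _seeds
        from megbody.preprocess import PreprocessConfig, preprocess
        from megbody.simulate import build_model, generate_subject

        model = build_model(EFFECT_CONFIG, seed=9)
        means = []
        for s in _seeds(10, 6):
            ep = generate_subject(EFFECT_CONFIG, seed=s, model=model)
            clean, _ = preprocess(ep, PreprocessConfig())
            fs = extract_features(clean)
            res = crossval_decode(fs, make_labels(StimulusSet.default()), seed=s)
            pre = res.window_centers < 90.0
            means.append(res.accuracy[pre].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - CHANCE) < 3 * se


class TestSignificance:
    def _result(self, acc, n_correct, n_trials, scheme="categorical"):
        nw = len(np.atleast_1d(acc))
        return SchemeResult(
            scheme=scheme,
            accuracy=np.full(nw, acc) if np.isscalar(acc) else np.asarray(acc),
            n_correct=np.asarray(n_correct),
            n_trials=n_trials,
            window_centers=np.arange(nw, dtype=float),
        )

    def test_all_correct_overwhelming_evidence(self):
        cat = [self._result(1.0, [50], 50), self._result(1.0, [50], 50)]
        rnd = [self._result(0.3, [15], 50, "random"),
               self._result(0.4, [20], 50, "random")]
        out = significance(cat, rnd)
        assert out.binom_p_categorical[0] < 1e-10

    def test_exact_chance_not_significant(self):
        cat = [self._result(CHANCE, [40], 120), self._result(CHANCE, [40], 120)]
        rnd = [self._result(CHANCE, [40], 120, "random"),
               self._result(CHANCE, [40], 120, "random")]
        out = significance(cat, rnd)
        assert out.binom_p_categorical[0] > 0.9

    def test_identical_schemes_paired_p_one(self):
        a = [self._result(0.5, [60], 120), self._result(0.6, [72], 120)]
        b = [self._result(0.5, [60], 120, "random"),
             self._result(0.6, [72], 120, "random")]
        out = significance(a, b)
        assert out.paired_p[0] == pytest.approx(1.0)

    def test_binomial_p_matches_reference_value(self):
        """scipy's two-sided binomial p on a known fixture: 60/120 at 1/3."""
        cat = [self._result(0.5, [30], 60), self._result(0.5, [30], 60)]
        rnd = [self._result(0.3, [18], 60, "random"),
               self._result(0.3, [18], 60, "random")]
        out = significance(cat, rnd)
        ref = stats.binomtest(60, 120, 1 / 3).pvalue
        assert out.binom_p_categorical[0] == pytest.approx(ref, abs=1e-12)
        assert ref < 3e-4  # strong evidence above chance

    def test_paired_t_matches_hand_computation(self):
        """Differences (0.1, 0.2, 0.3): t = mean/SE = 2/(1/sqrt(3)), df = 2."""
        cat = [self._result(0.4 + d, [0], 10) for d in (0.1, 0.2, 0.3)]
        rnd = [self._result(0.4, [0], 10, "random") for _ in range(3)]
        out = significance(cat, rnd)
        t_ref = 0.2 / (np.std([0.1, 0.2, 0.3], ddof=1) / np.sqrt(3))
        p_ref = 2 * stats.t.sf(t_ref, df=2)
        assert out.paired_p[0] == pytest.approx(p_ref, abs=1e-12)
        assert p_ref == pytest.approx(0.0742, abs=5e-4)
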