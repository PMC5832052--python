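import numpy as np
import pytest

from pqlung.injury_classifier import (
    AnnClassifier, AnnModel, evaluate, classify_volume, predict, predict_proba,
    split_dataset, train,
)
from pqlung.texture_features import FEATURE_NAMES, FeatureDataset
from pqlung.volume_io import BinaryMask, MaskRole


def brute_force_auc(labels, scores):
    """Pairwise concordance: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def gaussian_blobs(n=400, separation=6.0, seed=0):
    """Linearly separable 9-d two-class feature set."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.normal(0, 1, (n, 9))
    X[half:, 0] += separation
    y = np.array([0] * half + [1] * (n - half))
    perm = rng.permutation(n)
    return FeatureDataset(X[perm], y[perm])


def zero_model(hidden=18):
    return AnnModel(
        w_hidden=np.zeros((9, hidden)), b_hidden=np.zeros(hidden),
        w_out=np.zeros((hidden, 1)), b_out=np.zeros(1),
        scaler_mean=np.zeros(9), scaler_sd=np.ones(9),
    )


class TestSplit:
    def test_default_split_sizes(self):
        ds = gaussian_blobs(n=100)
        tr, va, te = split_dataset(ds, (0.70, 0.15, 0.15), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_partitions_disjoint_and_stratified(self):
        ds = gaussian_blobs(n=200, seed=3)
        tr, va, te = split_dataset(ds, seed=5)
        rows = np.vstack([tr.features, va.features, te.features])
        assert len(np.unique(rows, axis=0)) == 200
        for part in (tr, va, te):
            counts = part.class_counts
            assert min(counts.values()) > 0

    def test_all_training_fraction(self):
        ds = gaussian_blobs(n=60)
        tr, va, te = split_dataset(ds, (1.0, 0.0, 0.0), seed=0)
        assert (len(tr), len(va), len(te)) == (60, 0, 0)

    def test_same_seed_identical(self):
        ds = gaussian_blobs(n=120, seed=9)
        a = split_dataset(ds, seed=4)
        b = split_dataset(ds, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.features, y.features)


class TestTraining:
    def test_separable_data_learned(self):
        ds = gaussian_blobs(n=400, seed=1)
        tr, va, te = split_dataset(ds, seed=1)
        model = AnnClassifier(seed=1).fit(tr, va)
        acc = ((model.forward(tr.features) >= 0.5).astype(int) == tr.labels).mean()
        assert acc >= 0.99
        assert model.training_record.iterations_run <= 5000

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            ds = gaussian_blobs(n=300, seed=seed)
            shuffled = FeatureDataset(ds.features, rng.permutation(ds.labels))
            model, report = train(shuffled, seed=seed)
            aucs.append(report.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_capacity_matters_on_xor(self):
        rng = np.random.default_rng(7)
        n = 600
        X = np.zeros((n, 9))
        X[:, :2] = rng.uniform(-1, 1, (n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        ds = FeatureDataset(X, y)
        tr, va, te = split_dataset(ds, seed=2)
        accs = {}
        for hidden in (1, 18):
            model = AnnClassifier(hidden=hidden, seed=2).fit(tr, va)
            accs[hidden] = ((model.forward(te.features) >= 0.5).astype(int)
                            == te.labels).mean()
        assert accs[18] >= 0.9
        assert accs[18] > accs[1] + 0.1

    def test_determinism_same_seed_same_weights(self):
        ds = gaussian_blobs(n=200, seed=4)
        tr, va, _ = split_dataset(ds, seed=4)
        m1 = AnnClassifier(seed=8).fit(tr, va)
        m2 = AnnClassifier(seed=8).fit(tr, va)
        np.testing.assert_array_equal(m1.w_hidden, m2.w_hidden)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)

    def test_single_class_rejected(self):
        ds = gaussian_blobs(n=50)
        only = FeatureDataset(ds.features, np.zeros(len(ds), int))
        with pytest.raises(ValueError, match="both classes"):
            AnnClassifier().fit(only)


class TestPredict:
    def test_zero_weights_give_half(self):
        model = zero_model()
        assert predict(model, np.zeros(9)) == pytest.approx(0.5)

    def test_forward_matches_manual_sigmoid_math(self):
        rng = np.random.default_rng(6)
        model = AnnModel(
            w_hidden=rng.normal(size=(9, 18)), b_hidden=rng.normal(size=18),
            w_out=rng.normal(size=(18, 1)), b_out=rng.normal(size=1),
            scaler_mean=rng.normal(size=9), scaler_sd=rng.uniform(0.5, 2, 9),
        )
        x = rng.normal(size=9)
        z = (x - model.scaler_mean) / model.scaler_sd
        sig = lambda t: 1 / (1 + np.exp(-t))
        h = sig(z @ model.w_hidden + model.b_hidden)
        expected = sig(h @ model.w_out + model.b_out)[0]
        assert predict(model, x) == pytest.approx(expected, rel=1e-12)
        assert 0.0 < predict(model, x) < 1.0

    def test_batch_equals_elementwise(self):
        rng = np.random.default_rng(8)
        model = zero_model()
        model.w_hidden[:] = rng.normal(size=(9, 18))
        model.w_out[:] = rng.normal(size=(18, 1))
        X = rng.normal(size=(10, 9))
        batch = predict_proba(model, X)
        single = [predict(model, x) for x in X]
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_nan_features_rejected(self):
        model = zero_model()
        with pytest.raises(ValueError, match="NaN"):
            predict(model, np.full(9, np.nan))

    def test_save_load_round_trip(self, tmp_path):
        ds = gaussian_blobs(n=120, seed=2)
        tr, va, _ = split_dataset(ds, seed=2)
        model = AnnClassifier(seed=2).fit(tr, va)
        model.save(tmp_path / "m.json")
        back = AnnModel.load(tmp_path / "m.json")
        np.testing.assert_array_equal(back.w_hidden, model.w_hidden)
        x = ds.features[:5]
        np.testing.assert_allclose(back.forward(x), model.forward(x), rtol=1e-12)


class TestClassifyVolume:
    def test_threshold_extremes(self, training_phantom, trained_model):
        _, volume, truth = training_phantom
        model, _, _ = trained_model
        lung = truth["lung"]
        empty = classify_volume(model, volume, lung, threshold=1.0 + 1e-9)
        assert empty.count() == 0
        everything = classify_volume(model, volume, lung, threshold=0.0)
        np.testing.assert_array_equal(everything.bits, lung.bits)

    def test_candidate_subset_of_lung(self, training_phantom, trained_model):
        _, volume, truth = training_phantom
        model, _, _ = trained_model
        cand = classify_volume(model, volume, truth["lung"])
        assert cand.role == MaskRole.injured_candidate
        assert not np.any(cand.bits & ~truth["lung"].bits)

    def test_empty_lung_rejected(self, training_phantom, trained_model):
        _, volume, truth = training_phantom
        model, _, _ = trained_model
        empty = BinaryMask(np.zeros(volume.shape, bool), MaskRole.lung)
        with pytest.raises(ValueError, match="empty"):
            classify_volume(model, volume, empty)


class TestEvaluate:
    def test_perfect_scores(self):
        model = zero_model()
        labels = np.array([0] * 10 + [1] * 10)
        ds = FeatureDataset(np.zeros((20, 9)), labels)
        # bypass the net: evaluate on a model whose output is label-driven
        scores = np.where(labels == 1, 0.9, 0.1)
        from sklearn.metrics import roc_curve, auc
        fpr, tpr, _ = roc_curve(labels, scores)
        assert auc(fpr, tpr) == 1.0  # reference for the construction below
        report = evaluate(_const_model(scores), ds)
        assert report.auc == 1.0
        assert report.confusion[0, 1] == 0 and report.confusion[1, 0] == 0

    def test_auc_equals_brute_force_concordance(self, trained_model):
        model, _, dataset = trained_model
        rng = np.random.default_rng(0)
        sel = rng.choice(len(dataset), 200, replace=False)
        sub = FeatureDataset(dataset.features[sel], dataset.labels[sel])
        report = evaluate(model, sub)
        expected = brute_force_auc(sub.labels, model.forward(sub.features))
        assert report.auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_test_set_rejected(self):
        ds = FeatureDataset(np.zeros((5, 9)), np.ones(5, int))
        with pytest.raises(ValueError, match="single-class"):
            evaluate(zero_model(), ds)

    def test_confusion_sums_to_test_size(self, trained_model):
        model, _, dataset = trained_model
        _, _, te = split_dataset(dataset, seed=1)
        report = evaluate(model, te)
        assert report.confusion.sum() == len(te)


class _const_model(AnnModel):
    """Test double whose forward pass returns fixed scores."""

    def __init__(self, scores):
        super().__init__(np.zeros((9, 1)), np.zeros(1), np.zeros((1, 1)),
                         np.zeros(1), np.zeros(9), np.ones(9))
        self._scores = np.asarray(scores, float)

    def forward(self, features):
        return self._scores
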