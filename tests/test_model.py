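import numpy as np
import pytest

from fpddi.fingerprints import Drug
from fpddi.model import ClassifierConfig, InteractionModel, InteractionResults, train


def separable_toy(n=40, n_features=16, seed=0):
    """Labels follow a single-feature threshold rule; any consistent learner
    reaches 100% training accuracy."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, n_features)) < 0.5).astype(np.uint8)
    y = X[:, 0].astype(np.int8)
    if len(np.unique(y)) < 2:  # pragma: no cover
        raise AssertionError("degenerate draw")
    return X, y


class TestTraining:
    def test_separable_training_accuracy(self):
        X, y = separable_toy()
        results = train(X, y, feature_models="A")
        assert (results.predict(X) == y).all()
        proba = results.predict_proba(X)
        assert proba[y == 1].min() > 0.5
        assert proba[y == 0].max() < 0.5

    def test_single_tree_boundary_config(self):
        X, y = separable_toy()
        results = train(X, y, config=ClassifierConfig(n_trees=1))
        proba = results.predict_proba(X)
        assert ((0 <= proba) & (proba <= 1)).all()

    def test_same_seed_same_predictions(self):
        X, y = separable_toy(seed=1)
        probe = (np.random.default_rng(9).random((20, 16)) < 0.5).astype(np.uint8)
        p1 = train(X, y, config=ClassifierConfig(seed=5)).predict_proba(probe)
        p2 = train(X, y, config=ClassifierConfig(seed=5)).predict_proba(probe)
        assert np.array_equal(p1, p2)

    def test_single_class_labels_error(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError, match="single class"):
            InteractionModel(X, np.ones(10))

    def test_dimension_mismatch_error(self):
        with pytest.raises(ValueError):
            InteractionModel(np.zeros((10, 4)), np.array([0, 1]))

    def test_training_row_order_invariance_on_separable_data(self):
        """Shuffling training rows leaves predicted classes unchanged when the
        rule is cleanly learnable (trees grow to purity either way)."""
        X, y = separable_toy(seed=2)
        perm = np.random.default_rng(0).permutation(len(y))
        probe, probe_y = separable_toy(n=30, seed=3)
        a = train(X, y, config=ClassifierConfig(seed=0)).predict(probe)
        b = train(X[perm], y[perm], config=ClassifierConfig(seed=0)).predict(probe)
        assert np.array_equal(a, probe_y) and np.array_equal(b, probe_y)

    def test_feature_column_permutation_invariance_on_separable_data(self):
        """Permuting columns consistently in train and probe does not change
        predicted classes for the tree backend on cleanly separable data."""
        X, y = separable_toy(seed=4)
        probe, probe_y = separable_toy(n=30, seed=5)
        cols = np.random.default_rng(1).permutation(X.shape[1])
        a = train(X, y, config=ClassifierConfig(seed=0)).predict(probe)
        b = train(X[:, cols], y, config=ClassifierConfig(seed=0)).predict(
            probe[:, cols]
        )
        assert np.array_equal(a, probe_y) and np.array_equal(b, probe_y)


class TestPrediction:
    def test_empty_matrix(self):
        X, y = separable_toy()
        results = train(X, y)
        assert results.predict_proba(np.empty((0, 16))).shape == (0,)

    def test_probability_range(self):
        X, y = separable_toy(seed=6)
        proba = train(X, y).predict_proba(X)
        assert ((0 <= proba) & (proba <= 1)).all()

    def test_feature_length_mismatch(self):
        X, y = separable_toy()
        results = train(X, y)
        with pytest.raises(ValueError, match="feature length"):
            results.predict_proba(np.zeros((3, 5)))

    def test_predict_pair_symmetry(self):
        rng = np.random.default_rng(0)
        n_bits = 32
        fps = (rng.random((12, n_bits)) < 0.4).astype(np.uint8)
        drugs = [Drug(f"d{i}", f"s{i}", fp) for i, fp in enumerate(fps)]
        # labels from bit overlap of pairs
        from fpddi.fusion import encode_pairs

        pairs = [(f"d{i}", f"d{j}") for i in range(12) for j in range(i + 1, 12)]
        X = encode_pairs({d.drug_id: d for d in drugs}, pairs, "AS")
        overlap = np.array([(fps[int(a[1:])] & fps[int(b[1:])]).sum() for a, b in pairs])
        y = (overlap > np.median(overlap)).astype(int)
        results = train(X, y, feature_models="AS")
        p_ab = results.predict_pair(drugs[0], drugs[1])
        p_ba = results.predict_pair(drugs[1], drugs[0])
        assert p_ab == p_ba
        assert 0 <= p_ab <= 1


class TestSvmBackend:
    def test_svm_trains_and_predicts(self):
        X, y = separable_toy(seed=7)
        config = ClassifierConfig(backend="svm", seed=0)
        results = InteractionModel(X, y, config=config).fit()
        proba = results.predict_proba(X)
        assert ((0 <= proba) & (proba <= 1)).all()
        assert "svm" in results.summary()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(backend="mlp")
        with pytest.raises(ValueError):
            ClassifierConfig(n_trees=0)
        with pytest.raises(ValueError):
            ClassifierConfig(svm_C=0)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        X, y = separable_toy(seed=8)
        results = train(X, y, config=ClassifierConfig(seed=3), feature_models="A")
        path = tmp_path / "model.joblib"
        results.save(path)
        assert path.with_suffix(".joblib.json").exists()
        loaded = InteractionResults.load(path)
        assert np.array_equal(loaded.predict_proba(X), results.predict_proba(X))
        assert loaded.config == results.config
        assert loaded.feature_models == results.feature_models

    def test_missing_artifact_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            InteractionResults.load(tmp_path / "nope.joblib")


def test_summary_contents():
    X, y = separable_toy()
    results = train(X, y, config=ClassifierConfig(seed=11), feature_models="ASH")
    text = results.summary()
    assert "random_forest" in text
    assert "ASH" in text
    assert "40" in text  # training samples
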