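"""CNN architecture/training contracts, the numpy autodiff engine, and the SVM."""

import numpy as np
import pytest

from hsitissue import (
    CNNConfig,
    SVMConfig,
    build_cnn,
    build_dataset,
    classify,
    compute_class_weights,
    load_model,
    predict_image,
    save_model,
    train_cnn,
    train_svm,
)
from hsitissue import nn
from hsitissue.classifiers import (
    PreprocessingMismatch,
    predict_dataset,
    predict_scores_batch,
)
from hsitissue.core import TissueClassSet, WavelengthGrid
from hsitissue.preprocess import BandScaler, SubVolumeDataset

GRID = WavelengthGrid.default()


def _toy_dataset(rng, n=40, window=5, bands=100, normalization="none"):
    values = rng.normal(size=(n, window, window, bands)).astype(np.float32)
    labels = 1 + (np.arange(n) % 7)
    return SubVolumeDataset(
        values, labels.astype(np.int64),
        np.array(["s1", "s2"] * (n // 2), dtype=object),
        np.zeros((n, 2), dtype=int), TissueClassSet(), GRID, normalization,
    )


class TestArchitecture:
    def test_default_network_has_exactly_32628_parameters(self):
        assert build_cnn().n_params == 32_628

    def test_six_conv_plus_one_dense_hidden_layer(self):
        model = build_cnn()
        convs = [l for l in model.network.layers if isinstance(l, nn.Conv3d)]
        denses = [l for l in model.network.layers if isinstance(l, nn.Dense)]
        assert len(convs) == 6
        assert len(denses) == 2  # hidden + output
        assert denses[-1].out_features == 7

    def test_forward_pass_produces_finite_scores(self, rng):
        model = build_cnn()
        x = rng.normal(size=(3, 1, 100, 5, 5)).astype(np.float32)
        scores = model.network.forward(x)
        assert scores.shape == (3, 7)
        assert np.all(np.isfinite(scores))

    def test_collapsing_geometry_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            build_cnn(CNNConfig(window=1, n_bands=4))


class TestClassWeights:
    def test_equal_counts_give_unit_weights(self):
        w = compute_class_weights({c: 10 for c in range(1, 8)})
        np.testing.assert_allclose(w.weights, 1.0)

    def test_weights_inverse_to_counts(self):
        cs = TissueClassSet(("a", "b", "c"))
        w = compute_class_weights({1: 10, 2: 20, 3: 40}, cs).weights
        np.testing.assert_allclose(w / w[2], [4.0, 2.0, 1.0])
        assert abs(w.sum() - 3) < 1e-12

    def test_two_class_ratio(self):
        cs = TissueClassSet(("a", "b"))
        w = compute_class_weights({1: 100, 2: 300}, cs).weights
        np.testing.assert_allclose(w[0] / w[1], 3.0)

    def test_missing_class_is_an_error(self):
        with pytest.raises(ValueError, match="vein"):
            compute_class_weights({c: 10 for c in range(1, 7)})


class TestLossAndGradients:
    def test_weighted_loss_matches_hand_computation(self):
        """Four-sample batch: loss = sum w_y * (-log softmax) / sum w_y."""
        logits = np.array(
            [[2.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 3.0, -1.0], [0.5, 0.5, 2.0]]
        )
        labels = np.array([0, 1, 1, 2])
        weights = np.array([1.0, 2.0, 0.5])
        expected_terms = []
        for row, lab in zip(logits, labels):
            p = np.exp(row) / np.exp(row).sum()
            expected_terms.append(weights[lab] * -np.log(p[lab]))
        expected = sum(expected_terms) / weights[labels].sum()
        loss, _ = nn.weighted_cross_entropy(logits, labels, weights)
        assert abs(loss - expected) < 1e-12

    def test_backprop_matches_numerical_gradients(self, rng):
        """Finite-difference check of the whole conv/dense stack."""
        config = CNNConfig(
            window=5, n_bands=12, n_classes=3, channels=(2, 2, 3, 3, 3, 4), hidden=5, seed=3
        )
        model = build_cnn(config, TissueClassSet(("a", "b", "c")))
        net = model.network
        x = rng.normal(size=(2, 1, 12, 5, 5)).astype(np.float32)
        y = np.array([0, 2])
        w = np.array([1.0, 1.5, 0.7])

        def loss_value():
            return nn.weighted_cross_entropy(net.forward(x), y, w)[0]

        _, dlogits = nn.weighted_cross_entropy(net.forward(x, train=True), y, w)
        net.backward(dlogits)
        eps = 1e-3
        for layer in (net.trainable_layers()[0], net.trainable_layers()[-1]):
            grad = layer.grad_weight
            flat = layer.weight.ravel()
            for idx in rng.choice(flat.size, size=5, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert abs(numeric - grad.ravel()[idx]) < 5e-3 * max(1, abs(numeric))

    def test_zero_epochs_leave_parameters_unchanged(self, rng):
        config = CNNConfig(epochs=0)
        model = build_cnn(config)
        before = model.network.state()
        train_cnn(model, _toy_dataset(rng), config)
        after = model.network.state()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_training_is_deterministic_given_seed(self, rng):
        dataset = _toy_dataset(rng)
        config = CNNConfig(epochs=2, batch_size=16, seed=5)
        states = []
        for _ in range(2):
            model = train_cnn(build_cnn(config), dataset, config)
            states.append(model.network.state())
        for key in states[0]:
            np.testing.assert_array_equal(states[0][key], states[1][key])

    def test_training_reduces_loss_on_learnable_data(self, tiny_cohort):
        dataset = build_dataset(tiny_cohort[:1])
        config = CNNConfig(epochs=4, batch_size=32, seed=0)
        model = train_cnn(build_cnn(config), dataset, config)
        losses = [loss for _, loss in model.training_log]
        assert losses[-1] < losses[0]


class TestSVM:
    def _clusters(self, rng, n_classes=3, n=30, spread=0.01):
        centers = rng.normal(size=(n_classes, 100)) * 10
        feats = np.vstack(
            [centers[k] + spread * rng.normal(size=(n, 100)) for k in range(n_classes)]
        )
        labels = np.repeat(np.arange(1, n_classes + 1), n)
        return feats, labels, centers

    def test_separated_clusters_perfectly_fit(self, rng):
        feats, labels, _ = self._clusters(rng, n_classes=2)
        model = train_svm(feats, labels, SVMConfig(), BandScaler.fit(feats),
                          TissueClassSet(("a", "b")))
        scaled = model.scaler.transform(feats)
        assert (model.estimator.predict(scaled) == labels).all()

    def test_cluster_centers_recovered(self, rng):
        feats, labels, centers = self._clusters(rng)
        cs = TissueClassSet(("a", "b", "c"))
        model = train_svm(feats, labels, SVMConfig(), BandScaler.fit(feats), cs)
        pred = model.estimator.predict(model.scaler.transform(centers))
        assert list(pred) == [1, 2, 3]

    def test_single_class_training_rejected(self, rng):
        feats = rng.normal(size=(10, 100))
        with pytest.raises(ValueError, match="two classes"):
            train_svm(feats, np.ones(10, dtype=int))

    def test_scaler_is_part_of_the_model(self, rng):
        feats, labels, _ = self._clusters(rng, n_classes=2)
        model = train_svm(feats, labels, SVMConfig(), BandScaler.fit(feats),
                          TissueClassSet(("a", "b")))
        assert model.scaler is not None  # inference always routes through it


class TestPrediction:
    def test_classify_argmax_and_tie_break(self):
        assert classify(np.array([0.1, 0.9, 0.0])) == 2
        assert classify(np.array([0.2, 0.1, 0.5, 0.3, 0.5])) == 3  # tie -> lowest code
        with pytest.raises(ValueError):
            classify(np.array([0.1, np.nan]))

    def test_duplicate_input_gives_identical_scores(self, rng):
        dataset = _toy_dataset(rng)
        config = CNNConfig(epochs=1, batch_size=16)
        model = train_cnn(build_cnn(config), dataset, config)
        sub = dataset.values[0]
        a = predict_scores_batch(model, sub[None])
        b = predict_scores_batch(model, sub[None])
        np.testing.assert_array_equal(a, b)

    def test_cnn_scores_equal_output_layer_activations(self, rng):
        dataset = _toy_dataset(rng)
        config = CNNConfig(epochs=1, batch_size=16)
        model = train_cnn(build_cnn(config), dataset, config)
        batch = dataset.values[:3]
        scores = predict_scores_batch(model, batch)
        direct = model.network.forward(
            batch.transpose(0, 3, 1, 2)[:, None].astype(np.float32)
        )
        np.testing.assert_allclose(scores, direct, rtol=1e-6)

    def test_snv_model_rejects_raw_input(self, rng):
        dataset = _toy_dataset(rng, normalization="snv")
        config = CNNConfig(epochs=1, batch_size=16)
        model = train_cnn(build_cnn(config), dataset, config)
        with pytest.raises(PreprocessingMismatch):
            predict_scores_batch(model, dataset.values[:2], normalization="none")

    def test_predict_image_pixel_list_and_dense(self, separable_cohort, rng):
        dataset = build_dataset(separable_cohort[:2])
        config = CNNConfig(epochs=2, batch_size=32)
        model = train_cnn(build_cnn(config), dataset, config)
        cube = separable_cohort[2].cube
        pixels = [(5, 5), (10, 40), (30, 30)]
        label_map, score_maps = predict_image(model, cube, pixels=pixels)
        assert sum(label_map[r, c] > 0 for r, c in pixels) == 3
        assert np.isfinite(score_maps[5, 5]).all()
        with pytest.raises(ValueError, match="outside"):
            predict_image(model, cube, pixels=[(999, 0)])

    def test_checkpoint_roundtrip_preserves_predictions(self, rng, tmp_path):
        dataset = _toy_dataset(rng)
        config = CNNConfig(epochs=1, batch_size=16)
        model = train_cnn(build_cnn(config), dataset, config)
        pred_before, _ = predict_dataset(model, dataset)
        save_model(model, tmp_path / "m.joblib")
        restored = load_model(tmp_path / "m.joblib")
        pred_after, _ = predict_dataset(restored, dataset)
        np.testing.assert_array_equal(pred_before, pred_after)
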