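import numpy as np
import pytest

from submito.cnn_model import (
    CompartmentLabel,
    Model,
    ModelConfig,
    PredictionResult,
    TrainConfig,
    build_model,
    load_checkpoint,
    predict,
    predict_many,
    save_checkpoint,
    train,
)
from submito.encoding import EncodedProtein


def _random_input(length, seed=0, pid="p"):
    rng = np.random.default_rng(seed)
    return EncodedProtein(pid, rng.random((length, 30)))


SMALL = ModelConfig(n_filters=16, n_hidden=8, seed=0)


class TestArchitecture:
    def test_conv_feature_map_preserves_length(self):
        model = build_model(ModelConfig(seed=0))
        fmap = model.conv_feature_map(_random_input(100))
        assert fmap.shape == (100, 256)

    def test_pooled_vector_has_512_values(self):
        model = build_model(ModelConfig(seed=0))
        assert model.pooled_vector(_random_input(37)).shape == (512,)

    @pytest.mark.parametrize("length", [1, 19, 1000])
    def test_length_agnostic_output(self, length):
        model = build_model(SMALL)
        probs = model.predict_proba(_random_input(length))
        assert probs.shape == (4,)
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_even_kernel_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(kernel_width=18)

    def test_class_count_fixed_at_four(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=3)


class TestPredict:
    def test_probabilities_sum_to_one_over_random_models(self):
        for seed in range(100):
            model = build_model(ModelConfig(n_filters=4, n_hidden=4, seed=seed))
            probs = model.predict_proba(_random_input(30, seed=seed))
            assert probs.shape == (4,)
            assert np.all(probs >= 0)
            assert abs(probs.sum() - 1.0) < 1e-6

    def test_zeroed_output_layer_gives_uniform_probabilities(self):
        model = build_model(SMALL)
        model.W3 = np.zeros_like(model.W3)
        model.b3 = np.zeros_like(model.b3)
        probs = model.predict_proba(_random_input(25))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_repeated_inference_is_bit_identical(self):
        model = build_model(SMALL)
        x = _random_input(60, seed=3)
        p1, p2 = model.predict_proba(x), model.predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_label_is_argmax_with_lowest_index_tie_break(self):
        model = build_model(SMALL)
        model.W3 = np.zeros_like(model.W3)
        model.b3 = np.zeros_like(model.b3)
        result = predict(model, _random_input(10))
        assert result.label == CompartmentLabel.outer_membrane  # index 0 wins ties

    def test_wrong_channel_count_rejected(self):
        model = build_model(SMALL)
        with pytest.raises(ValueError, match="channels"):
            model.predict_proba(
                type("X", (), {"matrix": np.zeros((5, 29)), "protein_id": "p"})()
            )

    def test_prediction_result_validates_probabilities(self):
        with pytest.raises(ValueError):
            PredictionResult("p", np.array([0.5, 0.5, 0.5, 0.5]), CompartmentLabel(0))


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        """Central-difference check of the full backward pass."""
        cfg = ModelConfig(n_filters=3, n_hidden=3, kernel_width=3, seed=5)
        model = build_model(cfg)
        rng = np.random.default_rng(6)
        x = rng.random((7, 30))
        batch = [(x, 2)]
        w = np.ones(4)
        _, grads = model.loss_and_gradients(batch, w)
        eps = 1e-6
        for p_idx, param in enumerate(model.parameters()):
            flat = param.ravel()
            for j in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = model.loss_and_gradients(batch, w)
                flat[j] = orig - eps
                lm, _ = model.loss_and_gradients(batch, w)
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[p_idx].ravel()[j] == pytest.approx(numeric, abs=1e-4)


class TestTrain:
    def test_loss_decreases_on_separable_data(self, small_labelled_dataset):
        model = build_model(SMALL)
        _, history = train(
            model, small_labelled_dataset, TrainConfig(epochs=30, seed=0)
        )
        assert history[-1] < history[0]

    def test_same_seed_gives_identical_traces(self, small_labelled_dataset):
        traces = []
        for _ in range(2):
            model = build_model(ModelConfig(n_filters=8, n_hidden=8, seed=1))
            _, history = train(
                model, small_labelled_dataset[:12], TrainConfig(epochs=5, seed=9)
            )
            traces.append(history)
        assert traces[0] == traces[1]

    def test_full_training_accuracy_on_separable_data(self, small_labelled_dataset):
        model = build_model(ModelConfig(n_filters=32, n_hidden=16, seed=2))
        model, _ = train(model, small_labelled_dataset, TrainConfig(epochs=40, seed=2))
        preds = predict_many(model, [e for e, _ in small_labelled_dataset])
        correct = sum(
            p.label == label for p, (_, label) in zip(preds, small_labelled_dataset)
        )
        assert correct == len(small_labelled_dataset)

    def test_single_class_data_rejected(self, small_labelled_dataset):
        one_class = [d for d in small_labelled_dataset if d[1] == CompartmentLabel(0)]
        with pytest.raises(ValueError, match="2 classes"):
            train(build_model(SMALL), one_class, TrainConfig(epochs=1))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(SMALL), [], TrainConfig(epochs=1))

    def test_early_stopping_restores_best_weights(self, small_labelled_dataset):
        model = build_model(SMALL)
        val = small_labelled_dataset[::4]
        _, history = train(
            model,
            small_labelled_dataset,
            TrainConfig(epochs=50, seed=0, early_stopping_patience=3),
            validation=val,
        )
        assert len(history) <= 50


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_model(SMALL)
        x = _random_input(40, seed=11)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        restored = load_checkpoint(path)
        assert restored.config == model.config
        np.testing.assert_array_equal(
            restored.predict_proba(x), model.predict_proba(x)
        )
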