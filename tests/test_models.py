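"""Architecture contracts of the U-Net, FCN and LSTM window classifiers."""

import numpy as np
import pytest

from habitmine.models import (FCN1d, UNetConfig, build_fcn, build_lstm,
                              build_model, build_unet, predict_window)

N_INDICES = 20  # pad + 18 tokens + UNK


def rand_windows(n, w, rng=None, n_indices=N_INDICES):
    rng = rng or np.random.default_rng(0)
    return rng.integers(1, n_indices, size=(n, w))


class TestUNet:
    def test_printed_configuration_length_trace(self):
        """With the full filter stack and a length-64 window, feature lengths
        halve through the encoder: 64 -> 32 -> 16 -> 8 -> 4."""
        model = build_unet(UNetConfig(n_classes=5), 64, N_INDICES, seed=0)
        assert model.encoder_lengths == [64, 32, 16, 8, 4]
        assert model.cfg.encoder_filters == [64, 128, 256, 512, 1024]
        assert model.cfg.decoder_filters == [512, 256, 128, 64]

    @pytest.mark.parametrize("w", [16, 32, 64, 128])
    def test_output_length_equals_input_length(self, w):
        model = build_unet(UNetConfig(n_classes=4, depth_scale=0.0625), w,
                           N_INDICES, seed=0)
        probs = model.per_position_proba(rand_windows(3, w))
        assert probs.shape == (3, 4, w)

    @pytest.mark.parametrize("w", [16, 32, 64, 128])
    def test_per_position_softmax_normalisation(self, w):
        model = build_unet(UNetConfig(n_classes=4, depth_scale=0.0625), w,
                           N_INDICES, seed=1)
        probs = model.per_position_proba(rand_windows(2, w))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_window_is_padded_internally(self):
        model = build_unet(UNetConfig(n_classes=3, depth_scale=0.125), 25,
                           N_INDICES, seed=0)
        assert model.padded_size == 32
        assert model.per_position_proba(rand_windows(2, 25)).shape == (2, 3, 25)

    def test_too_deep_for_window_raises(self):
        with pytest.raises(ValueError):
            build_unet(UNetConfig(n_classes=3, depth_scale=0.125), 2, N_INDICES)

    def test_depth_scale_shrinks_parameter_count(self):
        """At depth_scale 0.125 and W=32 the filter stack is 8..128 and the
        model is more than 50x smaller than the printed configuration."""
        small = build_unet(UNetConfig(n_classes=5, depth_scale=0.125), 32,
                           N_INDICES, seed=0)
        assert small.cfg.scaled_encoder_filters() == [8, 16, 32, 64, 128]
        full = build_unet(UNetConfig(n_classes=5), 32, N_INDICES, seed=0)
        assert full.n_params > 50 * small.n_params

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UNetConfig(n_classes=5, kernel=4)
        with pytest.raises(ValueError):
            UNetConfig(n_classes=5, decoder_filters=[64])
        with pytest.raises(ValueError):
            UNetConfig(n_classes=5, pool=2, upsample=3)


class TestBaselines:
    def test_fcn_layer_spec_as_printed(self):
        model = build_fcn(5, 25, N_INDICES, seed=0)
        assert model.layer_spec == [(128, 8), (256, 5), (128, 3)]

    def test_fcn_window_logits_shape(self):
        model = build_fcn(5, 25, N_INDICES, width_scale=0.125, seed=0)
        assert model.predict_proba(rand_windows(4, 25)).shape == (4, 5)

    def test_degenerate_single_class_classifier_rejected(self):
        with pytest.raises(ValueError):
            build_fcn(1, 25, N_INDICES)
        with pytest.raises(ValueError):
            build_lstm(1, 25, N_INDICES)

    def test_lstm_units_default(self):
        model = build_lstm(5, 25, N_INDICES, seed=0)
        assert model.units == 64
        assert model.lstm.hidden == 64

    def test_lstm_all_padding_window_is_valid(self):
        model = build_lstm(3, 10, N_INDICES, seed=0)
        probs = model.predict_proba(np.zeros((2, 10), dtype=np.int64))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_loss_trajectory(self):
        X, y = rand_windows(32, 10), np.zeros(32, dtype=np.int64)
        losses = []
        for _ in range(2):
            model = build_lstm(3, 10, N_INDICES, seed=3)
            losses.append([model.loss_and_grad(X, y) for _ in range(3)])
        assert losses[0] == losses[1]

    def test_out_of_vocabulary_index_rejected(self):
        model = build_fcn(3, 10, N_INDICES, width_scale=0.125, seed=0)
        bad = np.full((1, 10), N_INDICES)  # == embedding table size
        with pytest.raises(ValueError):
            model.predict_proba(bad)


class TestPredictWindow:
    def test_uniform_probabilities_tie_breaks_to_lowest_class(self):
        class Stub:
            n_classes = 3

            def predict_proba(self, X, batch_size=256):
                return np.full((len(X), 3), 1 / 3)

        out = predict_window(Stub(), np.array([1, 2, 3]))
        assert out.window_label == 0

    def test_unet_mean_aggregation_over_positions(self):
        """Hand-set per-position distributions: mean favours the majority."""
        model = build_unet(UNetConfig(n_classes=2, depth_scale=0.0625), 16,
                           N_INDICES, seed=0)
        probs = model.per_position_proba(rand_windows(1, 16))
        window = model.predict_proba(rand_windows(1, 16))
        assert np.allclose(window.sum(), 1.0, atol=1e-5)
        assert np.allclose(window[0], probs.mean(axis=2)[0], atol=1e-6)

    def test_build_model_dispatch(self):
        for name in ("unet", "fcn", "lstm"):
            model = build_model(name, 4, 16, N_INDICES, depth_scale=0.125, seed=0)
            assert model.predict(rand_windows(2, 16)).shape == (2,)
        with pytest.raises(ValueError):
            build_model("transformer", 4, 16, N_INDICES)
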