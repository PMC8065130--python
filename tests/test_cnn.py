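"""CNN construction, parameter counting, training contract, prediction."""

import numpy as np
import pytest

from nonwear.cnn import (
    ARCHITECTURES,
    ChannelCenter,
    CnnConfig,
    Conv1D,
    Dense,
    Flatten,
    ModelConstructionError,
    Sequential,
    build_model,
    count_parameters,
    evaluate_on_split,
    load_model,
    predict,
    save_model,
    train_model,
)


def closed_form_v2_count(input_len: int) -> int:
    """Independent parameter count for V2 from the layer dimensions."""
    (f1, k1), (f2, k2) = ARCHITECTURES["V2"]["conv"]
    (d,) = ARCHITECTURES["V2"]["dense"]
    total = (k1 * 3 + 1) * f1
    l1 = input_len - k1 + 1
    total += (k2 * f1 + 1) * f2
    l2 = l1 - k2 + 1
    total += (l2 * f2) * d + d
    total += d + 1
    return total


class TestBuildAndCount:
    @pytest.mark.parametrize("window_s", [3, 7])
    def test_v2_matches_closed_form(self, window_s):
        cfg = CnnConfig(architecture="V2", window_s=window_s, rate_hz=100.0)
        model = build_model(cfg)
        assert count_parameters(model) == closed_form_v2_count(window_s * 100)

    def test_single_dense_layer_count(self):
        model = Sequential(
            [Flatten(), Dense(1, activation="linear", name="out")],
            input_shape=(10, 1), seed=0,
        )
        assert count_parameters(model) == 11

    def test_conv_layer_count_closed_form(self):
        # kernel 10, 3 input channels, 5 filters: (10*3 + 1) * 5 = 155
        layer = Conv1D(5, 10)
        layer.build((100, 3), np.random.default_rng(0))
        assert sum(p.size for p in layer.params) == 155

    def test_count_matches_introspection_on_all_architectures(self):
        for arch in ARCHITECTURES:
            cfg = CnnConfig(architecture=arch, window_s=4, rate_hz=100.0)
            model = build_model(cfg)
            total = 0
            for layer in model.layers:
                for p in layer.params:
                    total += int(np.prod(p.shape))
            assert count_parameters(model) == total

    def test_count_invariant_to_seed_and_batch(self):
        a = build_model(CnnConfig(architecture="V2", window_s=3, seed=1, batch_size=8))
        b = build_model(CnnConfig(architecture="V2", window_s=3, seed=2, batch_size=64))
        assert count_parameters(a) == count_parameters(b)

    def test_count_scales_linearly_with_input_length(self):
        # stride-1 valid convs + flatten: the count difference between a 7-s
        # and a 3-s input depends only on last-conv filters x dense units
        c3 = count_parameters(build_model(CnnConfig(architecture="V2", window_s=3)))
        c7 = count_parameters(build_model(CnnConfig(architecture="V2", window_s=7)))
        assert c7 - c3 == 400 * 50 * 10

    def test_incompatible_kernel_names_layer(self):
        cfg = CnnConfig(
            architecture="V2", window_s=2, rate_hz=10.0,
            conv_specs=[(10, 15), (50, 10)],  # 20-sample input, kernel 15 then 10
        )
        with pytest.raises(ModelConstructionError, match="conv2"):
            build_model(cfg)

    def test_v4_pools_after_each_conv(self):
        cfg = CnnConfig(architecture="V4", window_s=3, rate_hz=100.0)
        model = build_model(cfg)
        kinds = [type(l).__name__ for l in model.layers]
        assert kinds == [
            "ChannelCenter", "Conv1D", "MaxPool1D", "Conv1D", "MaxPool1D",
            "Flatten", "Dense", "Dense",
        ]


def _separable_data(rng, n=120, length=30):
    X = rng.normal(0, 0.05, size=(n, length, 3))
    y = np.zeros(n)
    y[: n // 2] = 1
    X[: n // 2] += np.sin(np.linspace(0, 20, length))[None, :, None]
    idx = rng.permutation(n)
    return X[idx], y[idx]


class TestTraining:
    def test_learns_separable_windows_quickly(self, rng):
        X, y = _separable_data(rng)
        cfg = CnnConfig(architecture="V2", window_s=3, rate_hz=10.0, seed=0,
                        max_epochs=50)
        model = build_model(cfg)
        model, hist = train_model(model, (X[:80], y[:80]), (X[80:], y[80:]), cfg)
        assert max(hist.train_accuracy) >= 0.99
        assert hist.stopped_epoch <= 50

    def test_worsening_val_loss_stops_at_patience_and_restores(self, rng):
        X, y = _separable_data(rng, n=60, length=20)
        cfg = CnnConfig(
            architecture="V1", window_s=2, rate_hz=10.0, seed=0,
            conv_specs=[(4, 3)], dense_units=[4], max_epochs=250, patience=25,
        )
        model = build_model(cfg)
        # validation labels inverted: every step that helps training hurts
        # validation, so the first epoch stays the best
        model, hist = train_model(model, (X, y), (X, 1 - y), cfg)
        assert hist.best_epoch == 1
        assert hist.stopped_epoch == 1 + cfg.patience == 26
        assert hist.stopped_epoch - hist.best_epoch <= cfg.patience
        # restored weights are the epoch-1 weights: retrain one epoch fresh
        one = build_model(cfg)
        one, _ = train_model(one, (X, y), (X, 1 - y),
                             CnnConfig(**{**cfg.__dict__, "max_epochs": 1}))
        for a, b in zip(model.get_weights(), one.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_improving_val_loss_runs_to_max_epochs(self, rng):
        X, y = _separable_data(rng, n=60, length=20)
        cfg = CnnConfig(
            architecture="V1", window_s=2, rate_hz=10.0, seed=0,
            conv_specs=[(4, 3)], dense_units=[4], max_epochs=30, patience=25,
        )
        model = build_model(cfg)
        model, hist = train_model(model, (X, y), (X, y), cfg)
        # a learnable problem with val == train: loss keeps improving
        assert hist.stopped_epoch == 30
        assert hist.best_epoch > 25

    def test_deterministic_under_seed(self, rng):
        X, y = _separable_data(rng, n=40, length=20)
        cfg = CnnConfig(architecture="V1", window_s=2, rate_hz=10.0, seed=5,
                        conv_specs=[(4, 3)], dense_units=[4], max_epochs=5)
        m1, h1 = train_model(build_model(cfg), (X, y), (X, y), cfg)
        m2, h2 = train_model(build_model(cfg), (X, y), (X, y), cfg)
        assert h1.train_loss == h2.train_loss
        for a, b in zip(m1.get_weights(), m2.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_empty_sets_rejected(self):
        cfg = CnnConfig(architecture="V1", window_s=2, rate_hz=10.0,
                        conv_specs=[(4, 3)], dense_units=[4])
        model = build_model(cfg)
        empty = (np.empty((0, 20, 3)), np.empty(0))
        X = np.zeros((4, 20, 3))
        with pytest.raises(ValueError):
            train_model(model, empty, (X, np.zeros(4)), cfg)


class TestPredict:
    @staticmethod
    def _zero_logit_model():
        model = Sequential(
            [ChannelCenter(), Flatten(), Dense(1, activation="linear", name="out")],
            input_shape=(10, 3), seed=0,
        )
        model.set_weights([np.zeros((30, 1)), np.zeros(1)])
        return model

    def test_probability_half_classifies_positive(self):
        model = self._zero_logit_model()
        (prob, cls), = predict(model, np.zeros((1, 10, 3)))
        assert prob == 0.5 and cls == 1

    def test_output_order_and_length(self, rng):
        model = self._zero_logit_model()
        out = predict(model, rng.normal(size=(7, 10, 3)))
        assert len(out) == 7

    def test_shape_mismatch_names_expected(self, rng):
        model = self._zero_logit_model()
        with pytest.raises(ValueError, match=r"\(10, 3\)"):
            predict(model, rng.normal(size=(2, 11, 3)))

    def test_evaluate_on_split_perfect_and_allwrong(self, rng):
        X, y = _separable_data(rng, n=40)
        cfg = CnnConfig(architecture="V1", window_s=3, rate_hz=10.0, seed=0,
                        conv_specs=[(4, 3)], dense_units=[4], max_epochs=60)
        model = build_model(cfg)
        model, _ = train_model(model, (X, y), (X, y), cfg)
        perfect = evaluate_on_split(model, (X, y))
        assert (perfect.accuracy, perfect.precision, perfect.recall, perfect.f1) == (
            1.0, 1.0, 1.0, 1.0,
        )
        wrong = evaluate_on_split(model, (X, 1 - y))
        assert wrong.accuracy == 0.0


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = CnnConfig(architecture="V2", window_s=3, rate_hz=10.0, seed=1)
        model = build_model(cfg)
        X = rng.normal(size=(5, 30, 3))
        save_model(model, cfg, tmp_path / "m.npz", tmp_path / "m.json")
        back, back_cfg = load_model(tmp_path / "m.npz", tmp_path / "m.json")
        assert back_cfg == cfg
        np.testing.assert_array_equal(
            model.predict_proba(X), back.predict_proba(X)
        )
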