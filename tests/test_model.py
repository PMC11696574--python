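"""U-Net architecture, gradient and training tests."""

import dataclasses

import numpy as np
import pytest

from mskseg import nn
from mskseg.model import ModelConfig, TrainConfig, TrainedModel, build_model, cross_validate, normalize_hu, train
from mskseg.phantom import PhantomSpec, generate_phantom, merge_sides


def tiny_config(**kw):
    base = dict(n_classes=3, n_encoder_layers=5, base_channels=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Independent hand formula for the layer-by-layer parameter count."""
    ch = [cfg.base_channels * cfg.channel_growth**i for i in range(cfg.n_encoder_layers)]
    total = 0
    c_prev = 1
    for c in ch:  # encoder: two (3x3 conv + BN) blocks per level
        total += (c * c_prev * 9 + c) + (c * c * 9 + c)
        if cfg.use_batch_norm:
            total += 2 * (2 * c)
        c_prev = c
    for c in reversed(ch[:-1]):  # decoder: 2x2 upconv + one (3x3 conv + BN)
        total += c_prev * c * 4 + c
        total += c * (2 * c) * 9 + c
        if cfg.use_batch_norm:
            total += 2 * c
        c_prev = c
    total += cfg.n_classes * c_prev + cfg.n_classes  # 1x1 head
    return total


class TestConfig:
    def test_layer_count_restricted(self):
        with pytest.raises(ValueError):
            tiny_config(n_encoder_layers=4)
        tiny_config(n_encoder_layers=6)

    def test_dropout_range(self):
        with pytest.raises(ValueError):
            tiny_config(dropout_rate=0.0)

    def test_window_order(self):
        with pytest.raises(ValueError):
            tiny_config(input_window_hu=(350.0, -150.0))

    def test_channels_double_per_level(self):
        cfg = tiny_config(base_channels=8)
        assert cfg.channels == [8, 16, 32, 64, 128]
        assert cfg.n_decoder_layers == 4


class TestArchitecture:
    @pytest.mark.parametrize("layers,base,k", [(5, 2, 3), (5, 8, 5), (6, 2, 3)])
    def test_parameter_count_matches_hand_formula(self, layers, base, k):
        cfg = tiny_config(n_encoder_layers=layers, base_channels=base, n_classes=k)
        assert build_model(cfg).n_parameters == expected_parameter_count(cfg)

    def test_deeper_model_has_more_parameters(self):
        p5 = build_model(tiny_config(n_encoder_layers=5)).n_parameters
        p6 = build_model(tiny_config(n_encoder_layers=6)).n_parameters
        assert p6 > p5

    def test_output_is_probability_field(self):
        model = build_model(tiny_config())
        probs = model.predict_slices(np.random.default_rng(0).random((2, 16, 16), dtype=np.float32))
        assert probs.shape == (2, 3, 16, 16)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_non_divisible_input_padded_and_cropped(self):
        """20x20 is not divisible by 2^(L-1)=16; output must still be 20x20."""
        model = build_model(tiny_config())
        probs = model.predict_slices(np.zeros((1, 20, 20), dtype=np.float32))
        assert probs.shape == (1, 3, 20, 20)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_2d_input_promoted(self):
        model = build_model(tiny_config())
        assert model.predict_slices(np.zeros((16, 16), dtype=np.float32)).shape == (1, 3, 16, 16)


class TestGradients:
    def test_directional_derivative_matches_backprop(self):
        """Finite-difference check of the full network's backward pass."""
        cfg = tiny_config()
        model = build_model(cfg)
        layers = [l for l in model.net.layers() if l.params]
        for layer in layers:  # float64 for a tight finite-difference bound
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1, 16, 16))
        y = rng.integers(0, cfg.n_classes, (2, 16, 16))

        def loss():
            logits = model.net.forward(x, training=True, rng=np.random.default_rng(123))
            p = nn.softmax(logits.astype(np.float64), axis=1)
            flat = p.transpose(0, 2, 3, 1).reshape(-1, cfg.n_classes)
            picked = flat[np.arange(y.size), y.reshape(-1)]
            return -np.log(picked).mean(), p

        l0, p = loss()
        onehot = np.zeros_like(p)
        idx = np.indices(y.shape)
        onehot[idx[0], y, idx[1], idx[2]] = 1.0
        model.net.backward((p - onehot) / y.size)

        direction = {id(l): {k: np.random.default_rng(7 + i).standard_normal(v.shape) for k, v in l.params.items()}
                     for i, l in enumerate(layers)}
        gdot = sum(float((l.grads[k] * direction[id(l)][k]).sum()) for l in layers for k in l.params)
        h = 1e-5
        for sgn in (+1, -1):
            for l in layers:
                for k in l.params:
                    l.params[k] += sgn * h * direction[id(l)][k]
            if sgn == +1:
                l_plus, _ = loss()
                for l in layers:
                    for k in l.params:
                        l.params[k] -= h * direction[id(l)][k]
        l_minus, _ = loss()
        fd = (l_plus - l_minus) / (2 * h)
        assert fd == pytest.approx(gdot, rel=1e-4, abs=1e-8)


def _tiny_dataset(n=2, seed=11):
    data = []
    for i in range(n):
        spec = PhantomSpec(grid_shape=(8, 32, 32), n_structures=1, hu_means=(60.0, 300.0), seed=seed + i)
        vol, lab = generate_phantom(spec)
        data.append((vol, merge_sides(lab)))
    return data


class TestTraining:
    def test_loss_decreases(self):
        data = _tiny_dataset()
        model = build_model(tiny_config(n_classes=3, base_channels=4))
        train(model, data, TrainConfig(n_iterations=120, batch_size=2, seed=0))
        log = np.array(model.training_log)
        assert log[-20:].mean() < 0.5 * log[:20].mean()

    def test_training_is_deterministic(self):
        data = _tiny_dataset()
        weights = []
        for _ in range(2):
            model = build_model(tiny_config(n_classes=3))
            train(model, data, TrainConfig(n_iterations=5, batch_size=2, seed=4))
            weights.append(model.net.head.params["W"].copy())
        assert np.array_equal(weights[0], weights[1])

    def test_rejects_out_of_range_labels(self):
        data = _tiny_dataset()
        model = build_model(tiny_config(n_classes=2))  # labels go up to 2
        with pytest.raises(ValueError):
            train(model, data, TrainConfig(n_iterations=1))

    def test_rejects_empty_dataset(self):
        with pytest.raises(ValueError):
            train(build_model(tiny_config()), [], TrainConfig())

    @pytest.mark.parametrize("loss", ["dice", "combined"])
    def test_alternative_losses_run(self, loss):
        data = _tiny_dataset(n=1)
        model = build_model(tiny_config(n_classes=3))
        train(model, data, TrainConfig(n_iterations=3, batch_size=1, loss=loss, seed=0))
        assert len(model.training_log) == 3
        assert np.all(np.isfinite(model.training_log))

    def test_checkpoint_roundtrip(self, tmp_path):
        data = _tiny_dataset(n=1)
        model = build_model(tiny_config(n_classes=3))
        train(model, data, TrainConfig(n_iterations=5, batch_size=1, seed=0))
        model.save(tmp_path / "ckpt")
        loaded = TrainedModel.load(tmp_path / "ckpt")
        assert loaded.config == model.config
        x = normalize_hu(data[0][0].voxels, model.config.input_window_hu)
        assert np.array_equal(model.predict_slices(x), loaded.predict_slices(x))


class TestCrossValidation:
    def test_each_subject_held_out_once(self):
        data = _tiny_dataset(n=4)
        cfg = TrainConfig(n_iterations=2, batch_size=1, seed=0)
        res = cross_validate(data, 2, cfg, tiny_config(n_classes=3))
        held = sorted(i for r in res for i in r["held_out"])
        assert held == [0, 1, 2, 3]
        for r in res:
            assert set(r["predictions"]) == set(r["held_out"])
            for pred in r["predictions"].values():
                assert pred.shape == data[0][0].voxels.shape

    def test_fold_count_validation(self):
        data = _tiny_dataset(n=2)
        cfg = TrainConfig(n_iterations=1)
        with pytest.raises(ValueError):
            cross_validate(data, 1, cfg, tiny_config())
        with pytest.raises(ValueError):
            cross_validate(data, 3, cfg, tiny_config())


def test_normalize_hu_window():
    v = np.array([-500.0, -150.0, 100.0, 350.0, 1000.0])
    out = normalize_hu(v, (-150.0, 350.0))
    assert np.allclose(out, [0.0, 0.0, 0.5, 1.0, 1.0])
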