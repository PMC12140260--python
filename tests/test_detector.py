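"""Heatmap codec, network contracts, autodiff gradients, short training."""

import numpy as np
import pytest

from fishmorph.detector import (
    Adam,
    ConfigError,
    DetectorConfig,
    EncodeError,
    TrainingError,
    build_model,
    decode_heatmaps,
    detect,
    encode_heatmaps,
    load_checkpoint,
    save_checkpoint,
    train,
)
from fishmorph.detector.autodiff import Tensor, add, conv2d, maxpool2, mse, relu, upsample2
from fishmorph.detector.heatmaps import letterbox, unletterbox
from fishmorph.detector.train import make_detection_dataset


def small_config(**kw):
    defaults = dict(num_keypoints=3, input_size=32, heatmap_size=16,
                    num_stacks=2, hourglass_order=2, num_features=8)
    defaults.update(kw)
    return DetectorConfig(**defaults)


class TestConfig:
    def test_upscale_factor(self):
        assert DetectorConfig().upscale_factor == 4
        assert small_config().upscale_factor == 2

    def test_indivisible_sizes_rejected(self):
        with pytest.raises(ConfigError):
            DetectorConfig(input_size=60, heatmap_size=16)

    def test_order_too_deep_for_heatmap_rejected(self):
        with pytest.raises(ConfigError):
            DetectorConfig(heatmap_size=8, hourglass_order=4, input_size=32)


class TestHeatmapCodec:
    def test_peak_at_center(self):
        cfg = small_config(num_keypoints=1)
        maps = encode_heatmaps(np.array([[16.0, 16.0]]), cfg)
        assert maps.shape == (1, 16, 16)
        assert maps[0, 8, 8] == pytest.approx(1.0)

    def test_distant_keypoints_disjoint(self):
        cfg = small_config(num_keypoints=2, gaussian_sigma=1.0)
        maps = encode_heatmaps(np.array([[4.0, 4.0], [28.0, 28.0]]), cfg)
        overlap = (maps[0] > 0.5) & (maps[1] > 0.5)
        assert not overlap.any()

    def test_interior_map_mass(self):
        # The discrete sum of an interior Gaussian bump approximates the
        # continuous integral 2*pi*sigma^2.
        cfg = DetectorConfig(num_keypoints=1, input_size=128, heatmap_size=32,
                             gaussian_sigma=2.0)
        maps = encode_heatmaps(np.array([[64.0, 64.0]]), cfg)
        assert maps[0].sum() == pytest.approx(2 * np.pi * 2.0**2, rel=0.01)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(EncodeError):
            encode_heatmaps(np.array([[-1.0, 5.0]]), small_config(num_keypoints=1))

    def test_decode_upscales_argmax(self):
        cfg = DetectorConfig(num_keypoints=1, input_size=2048, heatmap_size=128)
        assert cfg.upscale_factor == 16
        maps = np.zeros((1, 128, 128))
        maps[0, 20, 10] = 1.0  # row 20, col 10
        assert decode_heatmaps(maps, cfg)[0] == pytest.approx((160, 320))

    def test_decode_encode_quantization_bound(self, rng):
        cfg = small_config(num_keypoints=1)
        f = cfg.upscale_factor
        for _ in range(100):
            kp = rng.uniform(0, cfg.input_size - 1e-6, size=(1, 2))
            decoded = decode_heatmaps(encode_heatmaps(kp, cfg), cfg)
            assert np.all(np.abs(decoded - kp) <= f)

    def test_subpixel_refinement_tightens_round_trip(self, rng):
        cfg = small_config(num_keypoints=1, gaussian_sigma=1.5)
        f = cfg.upscale_factor
        for _ in range(50):
            kp = rng.uniform(4, cfg.input_size - 4, size=(1, 2))
            maps = encode_heatmaps(kp, cfg)
            plain = decode_heatmaps(maps, cfg)
            refined = decode_heatmaps(maps, cfg, refine=True)
            assert np.all(np.abs(refined - kp) <= np.abs(plain - kp) + 1e-9)
            assert np.all(np.abs(refined - kp) <= f)

    def test_tie_breaks_to_lowest_row_major_index(self):
        cfg = small_config(num_keypoints=1)
        maps = np.zeros((1, 16, 16))
        maps[0, 3, 7] = maps[0, 9, 2] = 2.0
        assert tuple(decode_heatmaps(maps, cfg)[0]) == (7 * 2, 3 * 2)

    def test_all_zero_map_decodes_to_center(self, caplog):
        cfg = small_config(num_keypoints=1)
        with caplog.at_level("WARNING"):
            out = decode_heatmaps(np.zeros((1, 16, 16)), cfg)
        assert tuple(out[0]) == (16, 16)
        assert "all-zero" in caplog.text

    def test_letterbox_round_trip(self, rng):
        img = rng.uniform(size=(48, 96))
        square, tf = letterbox(img, 64)
        assert square.shape == (64, 64)
        kps = np.array([[10.0, 20.0], [90.0, 40.0]])
        boxed = kps * tf["scale"] + np.array([tf["pad_x"], tf["pad_y"]])
        np.testing.assert_allclose(unletterbox(boxed, tf), kps, atol=1e-9)


class TestAutodiff:
    def test_numerical_gradients(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 2, 8, 8))
        w = Tensor(rng.normal(size=(3, 2, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(rng.normal(size=3) * 0.1, requires_grad=True)
        target = rng.normal(size=(2, 3, 8, 8))

        def forward():
            h = relu(conv2d(Tensor(x), w, b))
            h = upsample2(maxpool2(h))
            return mse(h, target)

        loss = forward()
        loss.backward()
        eps = 1e-6
        for p in (w, b):
            analytic = p.grad.copy()
            flat = p.data.ravel()
            idx = np.random.default_rng(1).choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = float(forward().data)
                flat[i] = orig - eps
                down = float(forward().data)
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                assert analytic.ravel()[i] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_add_accumulates_both_branches(self):
        # loss = mean((a + a)^2) so dloss/da_i = 8 a_i / n = 2 at a_i = 1.
        a = Tensor(np.ones((1, 1, 2, 2)), requires_grad=True)
        out = mse(add(a, a), np.zeros((1, 1, 2, 2)))
        out.backward()
        np.testing.assert_allclose(a.grad, 2.0 * np.ones((1, 1, 2, 2)))


class TestModel:
    def test_output_shape_contract(self):
        cfg = small_config()
        model = build_model(cfg, seed=0)
        outs = model(np.random.default_rng(0).normal(size=(3, 1, 32, 32)).astype(np.float32))
        assert len(outs) == cfg.num_stacks
        for o in outs:
            assert o.data.shape == (3, cfg.num_keypoints, 16, 16)

    def test_smallest_legal_config_runs(self):
        cfg = DetectorConfig(num_keypoints=1, input_size=8, heatmap_size=8,
                             num_stacks=1, hourglass_order=1, num_features=4)
        model = build_model(cfg, seed=0)
        outs = model(np.zeros((1, 1, 8, 8), dtype=np.float32))
        assert outs[0].data.shape == (1, 1, 8, 8)

    def test_parameter_count_grows_with_order(self):
        counts = [
            build_model(small_config(hourglass_order=o), seed=0).num_parameters()
            for o in (1, 2, 3)
        ]
        assert counts == sorted(counts) and counts[0] < counts[-1]

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = small_config()
        model = build_model(cfg, seed=1)
        imgs = np.random.default_rng(2).normal(size=(2, 1, 32, 32)).astype(np.float32)
        before = model.predict(imgs)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        np.testing.assert_allclose(restored.predict(imgs), before, atol=1e-6)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_detection_dataset(4, "side", seed=500)


class TestTraining:
    def test_zero_steps_leaves_model_unchanged(self, tiny_dataset):
        cfg = DetectorConfig()
        model = build_model(cfg, seed=0)
        before = [p.data.copy() for p in model.params()]
        trace = train(model, tiny_dataset, steps=0)
        assert trace == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_same_seed_identical_traces(self, tiny_dataset):
        cfg = DetectorConfig()
        t1 = train(build_model(cfg, seed=3), tiny_dataset, steps=5)
        t2 = train(build_model(cfg, seed=3), tiny_dataset, steps=5)
        assert t1 == t2

    def test_loss_decreases_on_tiny_set(self, tiny_dataset):
        cfg = DetectorConfig()
        model = build_model(cfg, seed=0)
        trace = train(model, tiny_dataset, steps=60)
        assert trace[-1] < 0.5 * trace[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(TrainingError):
            train(build_model(DetectorConfig(), seed=0), [], steps=1)

    def test_detect_output_contract(self, tiny_dataset):
        cfg = DetectorConfig()
        model = build_model(cfg, seed=0)
        img, _ = tiny_dataset[0]
        kps = detect(model, img)
        assert kps.shape == (cfg.num_keypoints, 2)
        np.testing.assert_array_equal(kps, detect(model, img))
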