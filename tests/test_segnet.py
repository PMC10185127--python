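import numpy as np
import pytest

from onquant.grid import BinaryMask, VolumeGrid
from onquant.metrics import dsc
from onquant.segnet import (TrainConfig, UNetConfig, augment, build_unet,
                            dice_loss, dice_loss_grad, largest_component,
                            load_checkpoint, predict_mask, save_checkpoint,
                            train)

from conftest import make_mask

TOY = UNetConfig(depth=2, base_features=2, input_shape=(8, 8, 8))


class TestUNetConfig:
    def test_default_features_reach_512(self):
        cfg = UNetConfig(depth=5, base_features=32, input_shape=(144, 240, 112))
        assert cfg.features == [32, 64, 128, 256, 512]

    def test_indivisible_axis_rejected_naming_axis(self):
        with pytest.raises(ValueError, match="axis x"):
            UNetConfig(depth=5, base_features=32, input_shape=(60, 64, 32))

    def test_json_roundtrip(self):
        cfg = UNetConfig(depth=3, base_features=4, input_shape=(16, 16, 8))
        assert UNetConfig.from_json(cfg.to_json()) == cfg


class TestForward:
    def test_output_shape_and_range(self):
        model = build_unet(UNetConfig(depth=3, base_features=2,
                                      input_shape=(16, 16, 8)), seed=0)
        x = np.random.default_rng(0).normal(size=(16, 16, 8)).astype(np.float32)
        y = model.forward(x, train=False)
        assert y.shape == (16, 16, 8)
        assert np.all((y >= 0) & (y <= 1))

    def test_wrong_shape_rejected(self):
        model = build_unet(TOY, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((9, 8, 8), dtype=np.float32))

    def test_state_dict_roundtrip(self):
        m1 = build_unet(TOY, seed=0)
        m2 = build_unet(TOY, seed=1)
        x = np.random.default_rng(2).normal(size=(8, 8, 8)).astype(np.float32)
        assert not np.allclose(m1.forward(x, train=False), m2.forward(x, train=False))
        m2.load_state_dict(m1.state_dict())
        assert np.allclose(m1.forward(x, train=False), m2.forward(x, train=False))


class TestDiceLoss:
    def test_perfect_binary(self):
        t = (np.random.default_rng(0).random((6, 6, 6)) < 0.3).astype(float)
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-2)  # eps-limited

    def test_disjoint(self):
        p = np.zeros((6, 6, 6))
        p[0, 0, 0] = 1
        t = np.zeros((6, 6, 6))
        t[5, 5, 5] = 1
        assert dice_loss(p, t) == pytest.approx(1.0, abs=0.35)  # eps-limited at n=1
        big_p = np.zeros((10, 10, 10))
        big_p[:5] = 1
        big_t = np.zeros((10, 10, 10))
        big_t[5:] = 1
        assert dice_loss(big_p, big_t) == pytest.approx(1.0, abs=1e-2)

    def test_half_overlap_value(self):
        n = 100
        p = np.zeros(300)
        t = np.zeros(300)
        p[:n] = 1
        t[n // 2:n + n // 2] = 1
        expected = 1.0 - (2 * (n / 2) + 1.0) / (2 * n + 1.0)
        assert dice_loss(p, t) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_consistent_with_dsc(self):
        rng = np.random.default_rng(1)
        a = (rng.random((8, 8, 8)) < 0.4).astype(np.uint8)
        b = (rng.random((8, 8, 8)) < 0.4).astype(np.uint8)
        ma = BinaryMask(a, np.ones(3), np.zeros(3))
        mb = BinaryMask(b, np.ones(3), np.zeros(3))
        assert dice_loss(a.astype(float), b.astype(float), eps=0.0) == pytest.approx(
            1.0 - dsc(ma, mb), abs=1e-12)

    def test_gradient_matches_fd(self):
        rng = np.random.default_rng(2)
        p = rng.random((4, 4, 4))
        t = (rng.random((4, 4, 4)) < 0.4).astype(float)
        _, g = dice_loss_grad(p, t)
        eps = 1e-6
        for k in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            old = p[k]
            p[k] = old + eps
            lp = dice_loss(p, t)
            p[k] = old - eps
            lm = dice_loss(p, t)
            p[k] = old
            assert g[k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestAugment:
    def _sample(self, seed=0):
        rng = np.random.default_rng(seed)
        vol = rng.normal(size=(16, 16, 16)).astype(np.float32)
        mask = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)
        return vol, mask

    def test_zero_probabilities_identity(self):
        vol, mask = self._sample()
        cfg = TrainConfig(p_scale=0, p_flip=0, p_intensity=0, p_noise=0, p_blur=0)
        v2, m2 = augment(vol, mask, cfg, np.random.default_rng(0))
        assert np.array_equal(v2, vol)
        assert np.array_equal(m2, mask)

    def test_forced_flip_is_involution(self):
        vol, mask = self._sample()
        cfg = TrainConfig(p_scale=0, p_flip=1.0, p_intensity=0, p_noise=0, p_blur=0)
        v1, m1 = augment(vol, mask, cfg, np.random.default_rng(0))
        v2, m2 = augment(v1, m1, cfg, np.random.default_rng(1))
        assert np.array_equal(v2, vol)
        assert np.array_equal(m2, mask)

    def test_seeded_determinism(self):
        vol, mask = self._sample()
        cfg = TrainConfig()
        v1, m1 = augment(vol, mask, cfg, np.random.default_rng(42))
        v2, m2 = augment(vol, mask, cfg, np.random.default_rng(42))
        assert np.array_equal(v1, v2)
        assert np.array_equal(m1, m2)

    def test_mask_stays_binary(self):
        vol, mask = self._sample()
        cfg = TrainConfig(p_scale=1.0, p_flip=1.0, p_intensity=1.0, p_noise=1.0,
                          p_blur=1.0)
        for seed in range(5):
            _, m2 = augment(vol, mask, cfg, np.random.default_rng(seed))
            assert set(np.unique(m2)) <= {0, 1}

    def test_geometry_applied_to_both(self):
        vol, mask = self._sample()
        cfg = TrainConfig(p_scale=0, p_flip=1.0, p_intensity=0, p_noise=0, p_blur=0)
        v2, m2 = augment(vol, mask, cfg, np.random.default_rng(0))
        assert np.array_equal(v2, vol[::-1])
        assert np.array_equal(m2, mask[::-1])


class _ConstantModel:
    """Stub with the training interface and an unchanging output."""

    def __init__(self, value=0.5, shape=(4, 4, 4)):
        self.value = value
        self.cfg = type("C", (), {"input_shape": shape})()
        self._p = np.zeros(1, dtype=np.float32)
        self._g = np.zeros(1, dtype=np.float32)

    def forward(self, x, train=True):
        return np.full(x.shape[-3:], self.value, dtype=np.float32)

    def backward(self, g):
        pass

    def param_grad_pairs(self):
        return [(self._p, self._g)]

    def state_dict(self):
        return {"p": self._p.copy()}

    def load_state_dict(self, s):
        self._p[...] = s["p"]


class TestTrain:
    def _set(self, n, seed=0, shape=(4, 4, 4)):
        rng = np.random.default_rng(seed)
        return [(rng.normal(size=shape).astype(np.float32),
                 (rng.random(shape) < 0.3).astype(np.float32))
                for _ in range(n)]

    def test_early_stop_bookkeeping(self):
        # constant loss: epoch 1 improves over inf, then patience-2 epochs
        model = _ConstantModel()
        cfg = TrainConfig(max_epochs=50, early_stop_patience=2, p_scale=0,
                          p_flip=0, p_intensity=0, p_noise=0, p_blur=0)
        _, hist = train(model, self._set(3), self._set(2, 1), cfg)
        assert len(hist["val_loss"]) == 3

    def test_history_length_equals_epochs(self):
        model = _ConstantModel()
        cfg = TrainConfig(max_epochs=4, early_stop_patience=4, p_scale=0,
                          p_flip=0, p_intensity=0, p_noise=0, p_blur=0)
        _, hist = train(model, self._set(2), self._set(2, 1), cfg)
        assert len(hist["train_loss"]) == len(hist["val_loss"]) <= 4

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            train(_ConstantModel(), [], self._set(1), TrainConfig())

    def test_seeded_reproducibility(self):
        sets = self._set(3, 2, (8, 8, 8)), self._set(2, 3, (8, 8, 8))
        cfg = TrainConfig(max_epochs=2, early_stop_patience=2, seed=7)
        m1 = build_unet(TOY, seed=0)
        _, h1 = train(m1, *sets, cfg)
        m2 = build_unet(TOY, seed=0)
        _, h2 = train(m2, *sets, cfg)
        assert h1["val_loss"] == h2["val_loss"]


class TestPredictMask:
    def _grid(self, shape=(8, 8, 8)):
        return VolumeGrid(np.random.default_rng(0).normal(size=shape),
                          np.full(3, 0.3))

    def test_zero_output_gives_empty_mask(self):
        model = _ConstantModel(value=0.0, shape=(8, 8, 8))
        mask = predict_mask(model, self._grid())
        assert mask.voxels.sum() == 0

    def test_threshold_zero_gives_full_mask(self):
        model = build_unet(TOY, seed=0)
        mask = predict_mask(model, self._grid(), threshold=0.0)
        assert mask.voxels.all()  # sigmoid output is strictly positive

    def test_grid_mismatch_errors(self):
        model = build_unet(TOY, seed=0)
        with pytest.raises(ValueError):
            predict_mask(model, self._grid((16, 8, 8)))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_unet(TOY, seed=0)
        path = tmp_path / "m.ckpt.npz"
        save_checkpoint(path, model)
        model2 = load_checkpoint(path)
        g = self._grid()
        assert np.array_equal(predict_mask(model, g).voxels,
                              predict_mask(model2, g).voxels)


class TestLargestComponent:
    def test_keeps_largest(self):
        vox = np.zeros((20, 20, 20), dtype=np.uint8)
        vox[1:6, 1:6, 1:5] = 1  # 100 voxels
        vox[15:16, 15:20, 15:16] = 1  # 5 voxels
        mask = BinaryMask(vox, np.ones(3), np.zeros(3))
        out = largest_component(mask)
        assert out.voxels.sum() == 100
        assert out.voxels[2, 2, 2] == 1

    def test_single_blob_unchanged(self):
        mask = make_mask((6, 6, 6), [(1, 1, 1), (1, 1, 2), (2, 1, 1)])
        out = largest_component(mask)
        assert np.array_equal(out.voxels, mask.voxels)

    def test_empty_in_empty_out(self):
        mask = make_mask((4, 4, 4), [])
        assert largest_component(mask).voxels.sum() == 0

    def test_tie_break_lexicographic(self):
        vox = np.zeros((10, 10, 10), dtype=np.uint8)
        vox[1:3, 1, 1] = 1  # first in raster order
        vox[7:9, 7, 7] = 1  # same size
        mask = BinaryMask(vox, np.ones(3), np.zeros(3))
        out = largest_component(mask)
        assert out.voxels[1, 1, 1] == 1
        assert out.voxels[7, 7, 7] == 0

    def test_26_connectivity(self):
        vox = np.zeros((6, 6, 6), dtype=np.uint8)
        vox[1, 1, 1] = 1
        vox[2, 2, 2] = 1  # diagonal neighbour: one component
        vox[5, 5, 5] = 1
        mask = BinaryMask(vox, np.ones(3), np.zeros(3))
        assert largest_component(mask).voxels.sum() == 2
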