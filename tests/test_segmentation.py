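"""Network construction, losses, autodiff, and prediction post-processing."""

import math

import numpy as np
import pytest

from craniometry import _nn
from craniometry import segmentation as seg
from craniometry._nn import Tensor


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
        w = Tensor(rng.normal(size=(27, 5)), requires_grad=True)

        def forward():
            cols, (oh, ow) = _nn.im2col(x, 3, 1)
            y = cols.matmul(w).reshape(2, 8, 8, 5).transpose((0, 3, 1, 2))
            y = _nn.maxpool2(y.relu())
            p = _nn.softmax_channels(_nn.upsample2(y))
            return (p * p).mean()

        out = forward()
        out.backward()
        eps = 1e-3
        for tensor, idx in ((x, (1, 2, 5, 3)), (w, (13, 2))):
            analytic = tensor.grad[idx]
            orig = tensor.data[idx]
            tensor.data[idx] = orig + eps
            hi = float(forward().data)
            tensor.data[idx] = orig - eps
            lo = float(forward().data)
            tensor.data[idx] = orig
            assert analytic == pytest.approx((hi - lo) / (2 * eps), rel=0.05, abs=1e-5)

    def test_groupnorm_normalizes(self):
        gn = _nn.GroupNorm(8, groups=4)
        x = Tensor(np.random.default_rng(1).normal(3.0, 2.0, size=(2, 8, 6, 6)))
        y = gn(x).data
        flat = y.reshape(2, 4, -1)
        assert np.allclose(flat.mean(axis=2), 0.0, atol=1e-4)
        assert np.allclose(flat.std(axis=2), 1.0, atol=1e-3)


class TestLosses:
    def test_both_losses_vanish_at_perfect_prediction(self):
        truth = np.eye(3)[np.random.default_rng(0).integers(0, 3, size=(6, 6))]
        assert seg.dice_loss(truth, truth) == pytest.approx(0.0, abs=1e-5)
        assert seg.focal_loss(truth, truth) == pytest.approx(0.0, abs=1e-6)

    def test_losses_positive_for_imperfect_prediction(self):
        truth = np.eye(3)[np.zeros((4, 4), dtype=int)]
        pred = np.full((4, 4, 3), 1 / 3)
        assert seg.dice_loss(pred, truth) > 0
        assert seg.focal_loss(pred, truth) > 0

    def test_binary_toy_dice(self):
        # two classes, |pred| = |truth| = 8 px each, intersection 4
        pred = np.zeros((16, 2))
        truth = np.zeros((16, 2))
        pred[:8, 1] = 1
        pred[8:, 0] = 1
        truth[4:12, 1] = 1
        truth[:4, 0] = 1
        truth[12:, 0] = 1
        assert seg.dice_loss(pred, truth, class_weights=(1.0, 1.0)) == pytest.approx(
            0.5, abs=1e-6
        )

    def test_dice_invariant_under_weight_scaling(self):
        rng = np.random.default_rng(2)
        pred = rng.dirichlet([1, 1, 1], size=(5, 5))
        truth = np.eye(3)[rng.integers(0, 3, size=(5, 5))]
        a = seg.dice_loss(pred, truth, (0.2, 1.0, 3.0))
        b = seg.dice_loss(pred, truth, (0.4, 2.0, 6.0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_dice_rejects_nonpositive_weights(self):
        truth = np.eye(3)[np.zeros((2, 2), dtype=int)]
        with pytest.raises(ValueError, match="positive"):
            seg.dice_loss(truth, truth, class_weights=(0.0, 1.0, 1.0))

    def test_focal_single_pixel_value(self):
        pred = np.array([[0.05, 0.9, 0.05]])
        truth = np.array([[0.0, 1.0, 0.0]])
        assert seg.focal_loss(pred, truth, gamma=2.0) == pytest.approx(
            -(0.1**2) * math.log(0.9), rel=1e-9
        )

    def test_focal_gamma_zero_is_cross_entropy(self):
        rng = np.random.default_rng(3)
        pred = rng.dirichlet([1, 1, 1], size=50)
        truth = np.eye(3)[rng.integers(0, 3, size=50)]
        ce = -np.mean(np.log(np.clip((pred * truth).sum(1), 1e-7, 1.0)))
        assert seg.focal_loss(pred, truth, gamma=0.0) == pytest.approx(ce, abs=1e-9)

    def test_focal_rejects_negative_gamma(self):
        truth = np.eye(3)[np.zeros(4, dtype=int)]
        with pytest.raises(ValueError, match="gamma"):
            seg.focal_loss(truth, truth, gamma=-1.0)

    def test_dice_bounded_by_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pred = rng.dirichlet([1, 1, 1], size=(4, 4))
            truth = np.eye(3)[rng.integers(0, 3, size=(4, 4))]
            assert 0.0 <= seg.dice_loss(pred, truth) <= 1.0

    def test_autodiff_losses_agree_with_numpy_forms(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        truth = np.eye(3, dtype=np.float32)[rng.integers(0, 3, size=(2, 8, 8))]
        truth_nchw = truth.transpose(0, 3, 1, 2)
        p = _nn.softmax_channels(Tensor(logits))
        d_t = float(seg._dice_loss_t(p, truth_nchw, (0.2, 1.0, 3.0)).data)
        f_t = float(seg._focal_loss_t(p, truth_nchw, 2.0).data)
        probs = p.data.transpose(0, 2, 3, 1)
        assert d_t == pytest.approx(seg.dice_loss(probs, truth, (0.2, 1.0, 3.0)), abs=1e-5)
        assert f_t == pytest.approx(seg.focal_loss(probs, truth, 2.0), abs=1e-5)


class TestModel:
    def test_forward_shape_contract(self):
        model = seg.build_segmenter(depth=4, base_channels=4, input_hw=(96, 128), seed=0)
        x = np.random.default_rng(0).random((1, 96, 128, 3)).astype(np.float32)
        probs = model.predict_probs(x)
        assert probs.shape == (1, 96, 128, 3)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_bottleneck_downsampling_arithmetic(self):
        # four pooling stages divide each spatial dim by 16
        assert (736 // 2**4, 960 // 2**4) == (46, 60)
        model = seg.build_segmenter(depth=4, base_channels=4, input_hw=(96, 128), seed=0)
        x = Tensor(np.zeros((1, 3, 96, 128), dtype=np.float32))
        y = model.stem(x)
        for enc, down in zip(model.enc_blocks, model.down_blocks):
            y = down(_nn.maxpool2(enc(y)))
        y = model.bottleneck(y)
        assert y.shape[2:] == (96 // 16, 128 // 16)

    def test_indivisible_input_rejected(self):
        with pytest.raises(seg.SegmentationError, match="divisible"):
            seg.build_segmenter(depth=4, input_hw=(100, 128))
        model = seg.build_segmenter(depth=4, base_channels=4, input_hw=(96, 128))
        with pytest.raises(seg.SegmentationError, match="divisible"):
            model.forward(Tensor(np.zeros((1, 3, 50, 64), dtype=np.float32)))

    def test_checkpoint_round_trip(self, tmp_path):
        model = seg.build_segmenter(depth=2, base_channels=4, input_hw=(32, 32), seed=3)
        x = np.random.default_rng(1).random((1, 32, 32, 3)).astype(np.float32)
        before = model.predict_probs(x)
        seg.save_checkpoint(model, tmp_path / "ckpt.npz",
                            seg.TrainConfig(), {"val_f1": 0.5})
        loaded, meta = seg.load_checkpoint(tmp_path / "ckpt.npz")
        assert meta["metrics"]["val_f1"] == 0.5
        assert np.allclose(loaded.predict_probs(x), before)


class TestPostProcessing:
    def test_keep_largest_component_reassigns_fragments(self):
        mask = np.zeros((20, 40), dtype=np.uint8)
        mask[5:15, 2:12] = 1          # 100 px component
        mask[2:3, 30:37] = 1          # 7 px stray
        out = seg._keep_largest(mask, 1)
        assert (out[2:3, 30:37] == 0).all()
        assert (out[5:15, 2:12] == 1).all()

    def test_predict_mask_argmax_identity_and_flags(self):
        class FakeModel:
            def __init__(self, probs):
                self._p = probs

            def predict_probs(self, images):
                return self._p[None]

        h = w = 32
        probs = np.zeros((h, w, 3))
        probs[..., 0] = 1.0
        probs[10:20, 10:20] = [0.0, 1.0, 0.0]
        probs[14:16, 14:16] = [0.0, 0.0, 1.0]
        pred = seg.predict_mask(FakeModel(probs), np.zeros((h, w, 3), dtype=np.float32))
        assert set(np.unique(pred.mask)) == {0, 1, 2}
        assert pred.flags == []
        # disjoint coin gets flagged
        probs2 = probs.copy()
        probs2[14:16, 14:16] = [0.0, 1.0, 0.0]
        probs2[25:27, 25:27] = [0.0, 0.0, 1.0]
        pred2 = seg.predict_mask(FakeModel(probs2), np.zeros((h, w, 3), dtype=np.float32))
        assert "coin_outside_head_bbox" in pred2.flags

    def test_missing_class_is_an_error_naming_it(self):
        class FakeModel:
            def predict_probs(self, images):
                p = np.zeros((1, 16, 16, 3))
                p[..., 0] = 1.0
                p[0, 4:12, 4:12] = [0, 1, 0]
                return p

        with pytest.raises(seg.SegmentationError, match="coin"):
            seg.predict_mask(FakeModel(), np.zeros((16, 16, 3), dtype=np.float32))


@pytest.fixture(scope="module")
def tiny_sets():
    from craniometry.preprocess import Sample

    rng = np.random.default_rng(0)
    samples = []
    for i in range(4):
        img = rng.random((32, 32, 3)).astype(np.float32)
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        mask[14:18, 14:18] = 2
        img[mask == 1] = 0.3
        img[mask == 2] = 0.9
        samples.append(Sample(img, mask, i))
    return samples[:3], samples[3:]


class TestTrainingLoop:

    def test_history_recorded_and_deterministic(self, tiny_sets):
        train, val = tiny_sets
        cfg = seg.TrainConfig(epochs=3, batch_size=2, seed=11)

        def run():
            model = seg.build_segmenter(depth=2, base_channels=4,
                                        input_hw=(32, 32), seed=11)
            _, history = seg.train_segmenter(model, train, val, cfg)
            return history

        h1, h2 = run(), run()
        assert len(h1) == 3
        assert h1 == h2  # bit-identical on CPU for a fixed seed
        assert all({"train_loss", "val_f1", "val_iou"} <= set(h.keys()) for h in h1)

    def test_best_checkpoint_at_least_first_epoch(self, tiny_sets):
        train, val = tiny_sets
        cfg = seg.TrainConfig(epochs=4, batch_size=2, seed=1)
        model = seg.build_segmenter(depth=2, base_channels=4, input_hw=(32, 32), seed=1)
        model, history = seg.train_segmenter(model, train, val, cfg)
        best = max(h["val_f1"] for h in history)
        assert best >= history[0]["val_f1"]
        final = seg._evaluate(model, val, cfg)
        assert final["val_f1"] == pytest.approx(best, abs=1e-6)

    def test_empty_sets_rejected(self, tiny_sets):
        train, val = tiny_sets
        model = seg.build_segmenter(depth=2, base_channels=4, input_hw=(32, 32))
        with pytest.raises(ValueError, match="nonempty"):
            seg.train_segmenter(model, [], val, seg.TrainConfig(epochs=1))
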