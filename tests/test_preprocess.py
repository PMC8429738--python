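"""Standardization geometry and the augmentation schedule."""

import numpy as np
import pytest

from craniometry import phantom as ph
from craniometry.preprocess import (
    AugmentationOp,
    AugmentationSpec,
    augment_sample,
    build_training_set,
    standardize_input,
    standardize_mask,
)


class TestStandardize:
    def test_smartphone_frame_geometry(self):
        img = np.zeros((2448, 3264, 3), dtype=np.uint8)
        out, info = standardize_input(img, factor=3.4)
        assert out.shape == (736, 960, 3)  # 720x960 after downscale, padded
        assert info.pad == (8, 8, 0, 0)

    def test_identity_when_already_conformant(self):
        img = np.arange(736 * 960 * 3, dtype=np.uint8).reshape(736, 960, 3)
        out, info = standardize_input(img, factor=1.0)
        assert np.array_equal(out, img)
        assert info.scale == 1.0

    def test_small_image_rounds_up_to_32(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="smaller"):
            out, _ = standardize_input(img, factor=3.4)
        assert out.shape == (32, 32, 3)  # floor(100/3.4) = 29 -> 32

    @pytest.mark.parametrize("shape", [(97, 211), (640, 480), (31, 33)])
    def test_output_always_multiple_of_32(self, shape):
        out, _ = standardize_input(np.zeros((*shape, 3)), factor=1.7)
        assert out.shape[0] % 32 == 0 and out.shape[1] % 32 == 0

    def test_mask_classes_preserved(self):
        mask = np.zeros((200, 300), dtype=np.uint8)
        mask[50:150, 80:220] = 1
        mask[90:110, 140:160] = 2
        out, _ = standardize_mask(mask, factor=2.0)
        assert set(np.unique(out)) <= {0, 1, 2}
        assert out.shape == (128, 160)  # 100x150 padded up to multiples of 32


@pytest.fixture()
def sample_pair():
    rng = np.random.default_rng(3)
    img = rng.random((64, 96, 3)).astype(np.float32)
    mask = np.zeros((64, 96), dtype=np.uint8)
    mask[20:50, 10:40] = 1
    mask[30:36, 20:26] = 2
    return img, mask


class TestAugmentSample:
    def test_flip_is_an_involution(self, sample_pair):
        img, mask = sample_pair
        spec = AugmentationSpec([AugmentationOp("horizontal_flip", {}, 1.0)])
        once_img, once_mask = augment_sample(img, mask, spec, seed=0)
        twice_img, twice_mask = augment_sample(once_img, once_mask, spec, seed=0)
        assert np.allclose(twice_img, img, atol=1e-6)
        assert np.array_equal(twice_mask, mask)

    def test_zero_likelihood_is_identity(self, sample_pair):
        img, mask = sample_pair
        spec = AugmentationSpec(
            [AugmentationOp(op.name, op.params, 0.0) for op in AugmentationSpec.default().ops]
        )
        out_img, out_mask = augment_sample(img, mask, spec, seed=1)
        assert np.allclose(out_img, img, atol=1e-6)
        assert np.array_equal(out_mask, mask)

    def test_quarter_rotation_moves_left_content_to_bottom(self):
        mask = np.zeros((80, 80), dtype=np.uint8)
        mask[:, :20] = 1  # head pixels only in the left half
        img = np.zeros((80, 80, 3), dtype=np.float32)
        spec = AugmentationSpec([AugmentationOp("rotate", {"limit_deg": [90.0, 90.0]}, 1.0)])
        _, out_mask = augment_sample(img, mask, spec, seed=0)
        rows = np.nonzero(out_mask == 1)[0]
        assert rows.min() >= 40  # counterclockwise display rotation: left -> bottom

    def test_flip_and_quarter_turn_conserve_class_counts(self, sample_pair):
        img, mask = sample_pair
        for name, params in (
            ("horizontal_flip", {}),
            ("rotate", {"limit_deg": [90.0, 90.0]}),
        ):
            # square canvas so the 90-degree rotation loses no corners
            sq_img = img[:64, :64]
            sq_mask = mask[:64, :64]
            spec = AugmentationSpec([AugmentationOp(name, params, 1.0)])
            _, out = augment_sample(sq_img, sq_mask, spec, seed=2)
            for cls in (0, 1, 2):
                assert (out == cls).sum() == (sq_mask == cls).sum()

    def test_labels_stay_in_range_under_full_schedule(self, sample_pair):
        img, mask = sample_pair
        spec = AugmentationSpec.default()
        for seed in range(5):
            _, out = augment_sample(img, mask, spec, seed=seed)
            assert set(np.unique(out)) <= {0, 1, 2}

    def test_photometric_ops_never_touch_mask(self, sample_pair):
        img, mask = sample_pair
        spec = AugmentationSpec(
            [
                AugmentationOp("gaussian_noise", {"std_choices": [0.05]}, 1.0),
                AugmentationOp("photometric_oneof", {}, 1.0),
                AugmentationOp("hsv_shift", {}, 1.0),
            ]
        )
        out_img, out_mask = augment_sample(img, mask, spec, seed=4)
        assert np.array_equal(out_mask, mask)
        assert not np.allclose(out_img, img)

    def test_unknown_operation_lists_supported(self, sample_pair):
        img, mask = sample_pair
        spec = AugmentationSpec([AugmentationOp("elastic_warp", {}, 1.0)])
        with pytest.raises(ValueError, match="horizontal_flip"):
            augment_sample(img, mask, spec, seed=0)

    def test_deterministic_per_seed(self, sample_pair):
        img, mask = sample_pair
        spec = AugmentationSpec.default()
        a_img, a_mask = augment_sample(img, mask, spec, seed=7)
        b_img, b_mask = augment_sample(img, mask, spec, seed=7)
        assert np.array_equal(a_img, b_img) and np.array_equal(a_mask, b_mask)


class TestSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = AugmentationSpec.default()
        path = tmp_path / "aug.yaml"
        spec.to_yaml(path)
        loaded = AugmentationSpec.from_yaml(path)
        assert loaded == spec

    def test_default_schedule_contents(self):
        spec = AugmentationSpec.default()
        by_name = {op.name: op for op in spec.ops}
        assert by_name["horizontal_flip"].likelihood == 0.5
        assert by_name["rotate"].likelihood == 1.0
        assert by_name["rotate"].params["limit_deg"] == [-90.0, 90.0]
        assert by_name["gaussian_noise"].likelihood == 0.2
        assert by_name["gaussian_noise"].params["std_choices"] == [0.01, 0.05]
        assert by_name["photometric_oneof"].likelihood == 0.9
        assert by_name["hsv_shift"].likelihood == 0.9


@pytest.fixture(scope="module")
def mini_phantoms():
    rng = np.random.default_rng(10)
    phantoms = []
    for _ in range(6):
        _, contour = ph.sample_params(rng)
        phantoms.append(
            ph.render_phantom(contour, 0.45, seed=int(rng.integers(2**31 - 1)),
                              canvas_px=(96, 128))
        )
    return phantoms


class TestBuildTrainingSet:
    def test_split_counts_and_no_leakage(self, mini_phantoms):
        spec = AugmentationSpec.default()
        train, val = build_training_set(mini_phantoms, spec, copies=3, seed=1)
        assert len(val) == 2  # 6 phantoms at 2:1
        assert len(train) == 4 * (3 + 1)  # originals + 3 augmented copies each
        train_ids = {s.phantom_index for s in train}
        val_ids = {s.phantom_index for s in val}
        assert train_ids.isdisjoint(val_ids)

    def test_deterministic_per_seed(self, mini_phantoms):
        spec = AugmentationSpec.default()
        t1, v1 = build_training_set(mini_phantoms, spec, copies=1, seed=5)
        t2, v2 = build_training_set(mini_phantoms, spec, copies=1, seed=5)
        assert all(np.array_equal(a.image, b.image) for a, b in zip(t1, t2))
        assert all(np.array_equal(a.mask, b.mask) for a, b in zip(v1, v2))

    def test_too_few_phantoms_rejected(self, mini_phantoms):
        with pytest.raises(ValueError, match="at least 3"):
            build_training_set(mini_phantoms[:2], AugmentationSpec.default(), seed=0)
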