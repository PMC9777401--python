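"""Letterboxing, FOV recovery, one-hot encoding and augmentation lockstep."""

import dataclasses

import numpy as np
import pytest

from mslfnet import (FundusSample, PreprocessConfig, augment, encode_one_hot,
                     letterbox_resize, make_fov_mask, unletterbox_mask)
from mslfnet.preprocessing import AugmentParams, draw_augment_params


def _make_sample(h, w, rng):
    image = rng.random((h, w, 3)).astype(np.float32)
    masks = np.zeros((4, h, w), bool)
    masks[0, h // 3, w // 3] = True
    masks[2, 2 * h // 3, 2 * w // 3] = True
    fov = np.ones((h, w), bool)
    return FundusSample(image=image, lesion_masks=masks, fov_mask=fov)


class TestLetterbox:
    def test_identity_geometry(self, rng):
        cfg = PreprocessConfig(target_width=96, target_height=64)
        s = _make_sample(64, 96, rng)
        out = letterbox_resize(s, cfg)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.lesion_masks, s.lesion_masks)

    def test_exact_double_no_padding(self, rng):
        cfg = PreprocessConfig(target_width=96, target_height=64)
        s = _make_sample(128, 192, rng)
        out = letterbox_resize(s, cfg)
        assert out.image.shape == (64, 96, 3)
        # content fills the whole canvas: no zero bands at the borders
        assert out.fov_mask.all()

    def test_padding_split_and_content_region(self, rng):
        # 100x100 -> 96x64: scale 0.64, content 64x64, 16px bands left/right
        cfg = PreprocessConfig(target_width=96, target_height=64)
        s = _make_sample(100, 100, rng)
        s.image += 0.1  # strictly positive so content is detectable
        s.image /= s.image.max()
        out = letterbox_resize(s, cfg)
        assert out.image.shape == (64, 96, 3)
        occupied = out.image.sum(axis=2) > 0
        cols = np.where(occupied.any(axis=0))[0]
        assert cols.min() == 16 and cols.max() == 96 - 16 - 1
        assert occupied.any(axis=1).all()

    def test_masks_move_with_image(self, rng):
        cfg = PreprocessConfig(target_width=96, target_height=64)
        s = _make_sample(100, 100, rng)
        out = letterbox_resize(s, cfg)
        # lesion pixels survive and stay within the content region
        assert out.lesion_masks[0].sum() >= 1
        assert not (out.lesion_masks.any(axis=0) & ~out.fov_mask).any()

    def test_unletterbox_recovers_mask(self, rng):
        cfg = PreprocessConfig(target_width=96, target_height=64)
        h, w = 100, 120
        mask = np.zeros((h, w), bool)
        mask[20:40, 30:70] = True
        s = _make_sample(h, w, rng)
        s = FundusSample(image=s.image,
                         lesion_masks=np.stack([mask] + [np.zeros((h, w), bool)] * 3),
                         fov_mask=np.ones((h, w), bool))
        out = letterbox_resize(s, cfg)
        back = unletterbox_mask(out.lesion_masks[0], (h, w), cfg)
        # agreement up to nearest-neighbour rounding at the boundary
        disagreement = np.logical_xor(back, mask).sum()
        assert disagreement <= 0.1 * mask.sum()

    def test_zero_sized_raster_rejected(self):
        cfg = PreprocessConfig(target_width=96, target_height=64)
        s = FundusSample(image=np.zeros((0, 5, 3), np.float32),
                         lesion_masks=np.zeros((4, 0, 5), bool),
                         fov_mask=np.zeros((0, 5), bool))
        with pytest.raises(ValueError):
            letterbox_resize(s, cfg)


class TestFovMask:
    def test_recovers_synthetic_disc(self, default_sample):
        mask = make_fov_mask(default_sample.image)
        inter = (mask & default_sample.fov_mask).sum()
        union = (mask | default_sample.fov_mask).sum()
        assert inter / union >= 0.99

    def test_constant_images_warn(self):
        with pytest.warns(UserWarning):
            assert not make_fov_mask(np.zeros((32, 32, 3))).any()
        with pytest.warns(UserWarning):
            assert make_fov_mask(np.ones((32, 32, 3))).all()


class TestOneHot:
    def test_all_zero_masks_give_background(self):
        label = encode_one_hot(np.zeros((4, 8, 8), bool))
        assert label.y[4].all()
        assert not label.y[:4].any()

    def test_single_ma_pixel(self):
        masks = np.zeros((4, 8, 8), bool)
        masks[0, 2, 3] = True
        y = encode_one_hot(masks).y
        assert y[0, 2, 3] == 1 and y[0].sum() == 1
        assert y[4, 2, 3] == 0 and y[4].sum() == 63

    def test_argmax_matches_brute_force_index_map(self, rng):
        idx = rng.integers(0, 5, (16, 16))
        masks = np.stack([idx == c for c in range(4)])
        y = encode_one_hot(masks).y
        expected = np.where(idx < 4, idx, 4)
        assert np.array_equal(np.argmax(y, axis=0), expected)
        assert np.array_equal(y.sum(axis=0), np.ones((16, 16)))

    def test_overlap_rejected_with_pixel_count(self):
        masks = np.zeros((4, 8, 8), bool)
        masks[0, :2, :2] = True
        masks[1, :2, :2] = True
        with pytest.raises(ValueError, match="4 pixel"):
            encode_one_hot(masks)


def _forced(**kwargs):
    base = dict(vflip=False, hflip=False, do_affine=False,
                translate=(0.0, 0.0), shear_deg=0.0, do_rotate=False,
                angle_deg=0.0, do_jitter=False, brightness=1.0, contrast=1.0,
                saturation=1.0, hue_shift=0.0)
    base.update(kwargs)
    return AugmentParams(**base)


class TestAugment:
    def test_augment_disabled_is_identity(self, tiny_samples):
        cfg = PreprocessConfig(augment=False)
        s = tiny_samples[0]
        label = encode_one_hot(s.lesion_masks)
        out_s, out_l = augment(s, label, cfg, seed=0)
        assert out_s is s and out_l is label

    def test_forced_horizontal_flip_is_lockstep_involution(self, tiny_samples):
        cfg = PreprocessConfig(augment=True)
        s = tiny_samples[0]
        label = encode_one_hot(s.lesion_masks)
        params = _forced(hflip=True)
        s1, l1 = augment(s, label, cfg, seed=0, params=params)
        assert np.array_equal(s1.image, s.image[:, ::-1])
        assert np.array_equal(s1.lesion_masks, s.lesion_masks[:, :, ::-1])
        assert np.array_equal(s1.fov_mask, s.fov_mask[:, ::-1])
        s2, l2 = augment(s1, l1, cfg, seed=0, params=params)
        assert np.array_equal(s2.image, s.image)
        assert np.array_equal(l2.y, label.y)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 17])
    def test_one_hot_preserved_for_any_seed(self, tiny_samples, seed):
        cfg = PreprocessConfig(augment=True)
        s = tiny_samples[1]
        label = encode_one_hot(s.lesion_masks)
        out_s, out_l = augment(s, label, cfg, seed=seed)
        assert np.allclose(out_l.y.sum(axis=0), 1.0)
        assert np.array_equal(out_l.y[:4] > 0, out_s.lesion_masks)

    def test_rotation_moves_masks_with_geometry(self, tiny_samples):
        cfg = PreprocessConfig(augment=True)
        s = tiny_samples[0]
        label = encode_one_hot(s.lesion_masks)
        params = _forced(do_rotate=True, angle_deg=90.0)
        out_s, _ = augment(s, label, cfg, seed=0, params=params)
        # a 90-degree rotation permutes pixels: lesion mass is conserved
        # away from the canvas boundary (FOV disc is interior)
        assert out_s.lesion_masks.sum() == s.lesion_masks.sum()

    def test_jitter_touches_image_only(self, tiny_samples):
        cfg = PreprocessConfig(augment=True)
        s = tiny_samples[0]
        label = encode_one_hot(s.lesion_masks)
        params = _forced(do_jitter=True, brightness=1.07, contrast=0.95,
                         saturation=1.05, hue_shift=0.03)
        out_s, out_l = augment(s, label, cfg, seed=0, params=params)
        assert not np.array_equal(out_s.image, s.image)
        assert np.array_equal(out_s.lesion_masks, s.lesion_masks)
        assert np.array_equal(out_l.y, label.y)

    def test_draw_is_seed_deterministic(self):
        cfg = PreprocessConfig()
        a = draw_augment_params(cfg, 9, (32, 32))
        b = draw_augment_params(cfg, 9, (32, 32))
        assert a == b


def test_invalid_preprocess_configs():
    with pytest.raises(ValueError):
        PreprocessConfig(target_width=0)
    with pytest.raises(ValueError):
        PreprocessConfig(flip_prob=1.5)
    with pytest.raises(ValueError):
        PreprocessConfig(jitter_range=-0.1)


def test_config_roundtrips_through_dict():
    cfg = PreprocessConfig(jitter_range=0.05)
    assert PreprocessConfig(**dataclasses.asdict(cfg)) == cfg
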