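"""Architecture contracts: shapes, rearrangement permutation, group isolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mslfnet import (FeaturePyramid, ModelConfig, MSLFNet, build_encoder,
                     mlff_rearrange, mlff_split_blocks)
from mslfnet.nn import softmax


@pytest.fixture(scope="module")
def toy_net():
    return MSLFNet(ModelConfig(input_size=(32, 32), seed=0))


@pytest.fixture(scope="module")
def toy_x():
    return np.random.default_rng(0).normal(
        0, 0.5, (1, 3, 32, 32)).astype(np.float32)


class TestConfig:
    def test_input_size_must_divide_by_16(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            ModelConfig(input_size=(100, 96))

    def test_at_least_two_classes(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=1)

    def test_pretrained_without_weights_file_raises(self):
        with pytest.raises(ValueError, match="npz"):
            MSLFNet(ModelConfig(input_size=(32, 32), pretrained_encoder=True))


class TestEncoder:
    def test_toy_stage_shapes(self):
        cfg = ModelConfig(input_size=(64, 96), seed=0)
        enc = build_encoder(cfg)
        x = np.zeros((1, 3, 64, 96), np.float32)
        _, stage_outs = enc.forward(x, train=False)
        shapes = [o.shape for o in stage_outs]
        assert shapes == [(1, 64, 32, 48), (1, 128, 16, 24), (1, 256, 8, 12),
                          (1, 512, 4, 6), (1, 512, 4, 6)]

    def test_deterministic_init(self):
        cfg = ModelConfig(input_size=(32, 32), seed=3)
        a, b = build_encoder(cfg), build_encoder(cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)


class TestDecoderAndPyramid:
    def test_head_and_pyramid_shapes(self, toy_net, toy_x):
        skips, _ = toy_net.encoder.forward(toy_x, train=False)
        pyr, aux = toy_net.decoder.forward(list(skips), train=False)
        assert aux.shape == (1, 5, 32, 32)
        assert [m.shape for m in pyr.maps] == [
            (1, 64, 32, 32), (1, 64, 16, 16), (1, 128, 8, 8),
            (1, 256, 4, 4), (1, 512, 2, 2)]

    def test_n_classes_parameterizes_head(self):
        net = MSLFNet(ModelConfig(n_classes=3, input_size=(32, 32), seed=0))
        x = np.zeros((1, 3, 32, 32), np.float32)
        main, aux = net.forward(x, train=False)
        assert main.shape == (1, 3, 32, 32) and aux.shape == (1, 3, 32, 32)

    def test_pyramid_validation(self):
        with pytest.raises(ValueError, match="5 levels"):
            FeaturePyramid(maps=[np.zeros((1, 1, 4, 4))] * 3).validate()


class TestMSFE:
    def test_output_shapes_full_resolution(self, toy_net, toy_x):
        skips, _ = toy_net.encoder.forward(toy_x, train=False)
        pyr, _ = toy_net.decoder.forward(list(skips), train=False)
        maps = toy_net.msfe.forward(pyr, train=False)
        assert len(maps) == 5
        assert all(m.shape == (1, 5, 32, 32) for m in maps)

    def test_zero_residual_weights_reduce_to_projection(self, toy_net, toy_x):
        skips, _ = toy_net.encoder.forward(toy_x, train=False)
        pyr, _ = toy_net.decoder.forward(list(skips), train=False)
        msfe = toy_net.msfe
        saved = [(c.w.value.copy(), c.b.value.copy()) for c in msfe.res]
        try:
            for conv in msfe.res:
                conv.w.value[...] = 0
                conv.b.value[...] = 0
            maps = msfe.forward(pyr, train=False)
            direct = msfe.proj[0].forward(pyr.maps[0], train=False)
            np.testing.assert_allclose(maps[0], direct, atol=1e-6)
        finally:
            for conv, (w, b) in zip(msfe.res, saved):
                conv.w.value[...] = w
                conv.b.value[...] = b

    def test_wrong_tap_channels_rejected(self, toy_net):
        bad = [np.zeros((1, 7, 2 ** (5 - i), 2 ** (5 - i)), np.float32)
               for i in range(5)]
        with pytest.raises(ValueError, match="channels"):
            toy_net.msfe.forward(bad, train=False)


class TestMLFFRearrange:
    def test_enumerated_category_major_permutation(self):
        # block b, category k filled with 10*b + k (1-based)
        blocks = []
        for b in range(1, 6):
            m = np.zeros((1, 5, 2, 2), np.float32)
            for k in range(1, 6):
                m[:, k - 1] = 10 * b + k
            blocks.append(m)
        out = mlff_rearrange(blocks)
        assert out.shape == (1, 25, 2, 2)
        flat = out[0, :, 0, 0]
        expected = [10 * b + k for k in range(1, 6) for b in range(1, 6)]
        assert flat.tolist() == expected  # (11,21,31,41,51, 12,22, ...)

    def test_single_category_is_plain_concatenation(self):
        blocks = [np.full((1, 1, 3, 3), float(b)) for b in range(5)]
        out = mlff_rearrange(blocks)
        np.testing.assert_array_equal(out, np.concatenate(blocks, axis=1))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 6))
    def test_permutation_is_invertible_and_value_preserving(self, seed, m):
        prng = np.random.default_rng(seed)
        blocks = [prng.normal(0, 1, (1, m, 3, 4)).astype(np.float32)
                  for _ in range(5)]
        out = mlff_rearrange(blocks)
        assert np.array_equal(np.sort(out.ravel()),
                              np.sort(np.concatenate(blocks, axis=1).ravel()))
        back = mlff_split_blocks(out, m)
        for a, b in zip(back, blocks):
            assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        blocks = [np.zeros((1, 5, 4, 4))] * 4 + [np.zeros((1, 5, 2, 2))]
        with pytest.raises(ValueError, match="share shape"):
            mlff_rearrange(blocks)


class TestMLFFFusion:
    def test_group_isolation_under_perturbation(self, toy_net, rng):
        fuse = toy_net.mlff
        x = rng.normal(0, 1, (1, 25, 4, 4)).astype(np.float32)
        y0 = fuse.forward(x, train=False)
        for j in range(5):  # perturb one channel of category j
            x2 = x.copy()
            x2[:, j * 5 + 2] += 10.0
            y2 = fuse.forward(x2, train=False)
            others = [i for i in range(5) if i != j]
            assert np.array_equal(y0[:, others], y2[:, others])
            assert not np.array_equal(y0[:, j], y2[:, j])

    def test_identity_weights_select_block_one(self, toy_net, rng):
        fuse = toy_net.mlff
        saved = (fuse.w.value.copy(), fuse.b.value.copy())
        try:
            fuse.w.value[...] = 0
            fuse.w.value[:, 0] = 1.0
            fuse.b.value[...] = 0
            x = rng.normal(0, 1, (1, 25, 4, 4)).astype(np.float32)
            y = fuse.forward(x, train=False)
            for k in range(5):
                np.testing.assert_allclose(y[:, k], x[:, k * 5], atol=1e-6)
        finally:
            fuse.w.value[...], fuse.b.value[...] = saved

    def test_wrong_channel_count_rejected(self, toy_net):
        with pytest.raises(ValueError, match="channels"):
            toy_net.mlff.forward(np.zeros((1, 24, 4, 4), np.float32),
                                 train=False)


class TestForward:
    def test_baseline_main_equals_aux(self, toy_x):
        net = MSLFNet(ModelConfig(input_size=(32, 32), use_msfe=False,
                                  use_mlff=False, seed=0))
        main, aux = net.forward(toy_x, train=False)
        assert main is aux

    def test_msfe_only_main_is_mean_of_maps(self, toy_x):
        net = MSLFNet(ModelConfig(input_size=(32, 32), use_msfe=True,
                                  use_mlff=False, seed=0))
        main, _ = net.forward(toy_x, train=False)
        skips, _ = net.encoder.forward(toy_x, train=False)
        pyr, _ = net.decoder.forward(list(skips), train=False)
        maps = net.msfe.forward(pyr, train=False)
        np.testing.assert_allclose(main, sum(maps) / 5.0, atol=1e-5)

    def test_full_model_toy_shapes(self, toy_net, toy_x):
        main, aux = toy_net.forward(toy_x, train=False)
        assert main.shape == (1, 5, 32, 32) and aux.shape == (1, 5, 32, 32)

    def test_probabilities_normalized(self, toy_net, toy_x):
        p = toy_net.predict_proba(toy_x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert (p >= 0).all() and (p <= 1).all()
        pred = toy_net.predict(toy_x)
        assert np.array_equal(pred, np.argmax(p, axis=1))

    def test_forward_rejects_bad_geometry(self, toy_net):
        with pytest.raises(ValueError):
            toy_net.forward(np.zeros((1, 3, 30, 32), np.float32), train=False)
        with pytest.raises(ValueError):
            toy_net.forward(np.zeros((1, 1, 32, 32), np.float32), train=False)

    def test_forward_deterministic(self, toy_net, toy_x):
        a, _ = toy_net.forward(toy_x, train=False)
        b, _ = toy_net.forward(toy_x, train=False)
        assert np.array_equal(a, b)


class TestSerialization:
    def test_state_dict_roundtrip(self, toy_x):
        cfg = ModelConfig(input_size=(32, 32), seed=1)
        a, b = MSLFNet(cfg), MSLFNet(ModelConfig(input_size=(32, 32), seed=2))
        ref, _ = a.forward(toy_x, train=False)
        b.load_state_dict(a.state_dict())
        out, _ = b.forward(toy_x, train=False)
        assert np.array_equal(ref, out)

    def test_mismatched_state_rejected(self, toy_net):
        with pytest.raises(ValueError):
            toy_net.load_state_dict({"0000:x": np.zeros(3)})
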