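"""Architecture assembly, shape chain, functional forward passes, checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import conv_block_oracle, model_oracle
from specattn.network import (ArchitectureSpec, ConvBlockSpec, Model,
                              build_architecture, conv_block_forward,
                              fully_connected_forward, init_params,
                              load_checkpoint, model_forward, save_checkpoint,
                              shape_chain, softmax)

SWIR_CHAIN = [(16, 144), (16, 72), (32, 36), (64, 18), (64, 9), (32, 4)]


class TestBuildArchitecture:
    def test_swir_shape_chain(self):
        spec = build_architecture(288, 8, "csam")
        assert shape_chain(spec) == SWIR_CHAIN
        assert shape_chain(spec)[-1][1] == 4

    def test_vnir_floor_halving_chain(self):
        spec = build_architecture(108, 8, "csam")
        # 108 -> 54 -> 27 -> 13 -> 6 -> 3 -> 1, halving with floor
        lengths = [length for _, length in shape_chain(spec)]
        assert lengths == [54, 27, 13, 6, 3, 1]

    def test_no_attention_mode(self):
        spec = build_architecture(288, 8, "none")
        assert all(b.attention_after == "none" for b in spec.blocks)
        assert shape_chain(spec) == SWIR_CHAIN     # attention never changes shapes

    def test_default_placements_first_four(self):
        spec = build_architecture(288, 8, "csam")
        assert [b.attention_after for b in spec.blocks] == \
            ["csam", "csam", "csam", "csam", "none", "none"]

    def test_five_placement_variant(self):
        spec = build_architecture(288, 8, "csam", attention_placements=(0, 1, 2, 3, 4))
        assert [b.attention_after for b in spec.blocks] == \
            ["csam", "csam", "csam", "csam", "csam", "none"]

    def test_too_few_bands(self):
        with pytest.raises(ValueError, match="too few bands|>= 16"):
            build_architecture(32, 8, "none")

    def test_fc_head_sizes(self):
        spec = build_architecture(288, 8, "none")
        assert spec.fc_sizes == [64, 32, 16, 8]
        spec2 = build_architecture(288, 2, "none")
        assert spec2.fc_sizes == [64, 32, 16, 2]


def bypass_bn(c):
    return {"bn.gamma": np.ones(c), "bn.beta": np.zeros(c),
            "bn.running_mean": np.zeros(c), "bn.running_var": np.ones(c)}


class TestConvBlockForward:
    def test_identity_kernel_no_pool(self):
        blk = ConvBlockSpec(kernel_size=1, in_channels=1, out_channels=1, pool="none")
        params = {**bypass_bn(1), "conv.w": np.ones((1, 1, 1)), "conv.b": np.zeros(1)}
        x = np.array([[-1.0, 2.0, -3.0, 4.0]])
        out = conv_block_forward(blk, params, x)
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-4)

    def test_hand_convolution_and_pool(self):
        blk = ConvBlockSpec(kernel_size=3, in_channels=1, out_channels=1,
                            batch_norm_before=False)
        params = {"conv.w": np.ones((1, 1, 3)), "conv.b": np.zeros(1)}
        out = conv_block_forward(blk, params, np.array([[1.0, 0.0, 2.0, 0.0]]))
        # pre-pool [1, 3, 2, 2]; pool(2, 2) -> [3, 2]
        np.testing.assert_allclose(out, [[3.0, 2.0]])

    def test_length_nine_pools_to_four(self, rng):
        blk = ConvBlockSpec(kernel_size=3, in_channels=64, out_channels=32,
                            batch_norm_before=False)
        params = {"conv.w": rng.normal(size=(32, 64, 3)),
                  "conv.b": rng.normal(size=32)}
        out = conv_block_forward(blk, params, rng.normal(size=(64, 9)))
        assert out.shape == (32, 4)

    def test_channel_mismatch(self, rng):
        blk = ConvBlockSpec(kernel_size=3, in_channels=4, out_channels=2,
                            batch_norm_before=False)
        params = {"conv.w": rng.normal(size=(2, 4, 3)), "conv.b": np.zeros(2)}
        with pytest.raises(ValueError, match="channels"):
            conv_block_forward(blk, params, rng.normal(size=(3, 8)))

    @pytest.mark.parametrize("mode", ["none", "cam", "sam", "csam"])
    def test_matches_loop_oracle(self, rng, mode):
        blk = ConvBlockSpec(kernel_size=3, in_channels=2, out_channels=4,
                            attention_after=mode)
        params = {**bypass_bn(2),
                  "conv.w": rng.normal(size=(4, 2, 3)),
                  "conv.b": rng.normal(size=4)}
        params["bn.running_mean"] = rng.normal(size=2)
        params["bn.running_var"] = rng.uniform(0.5, 2.0, size=2)
        if mode in ("cam", "csam"):
            params.update({"cam.w1": rng.normal(size=(2, 4)),
                           "cam.b1": rng.normal(size=2),
                           "cam.w2": rng.normal(size=(4, 2)),
                           "cam.b2": rng.normal(size=4)})
        if mode in ("sam", "csam"):
            params.update({"sam.w": rng.normal(size=4),
                           "sam.b": rng.normal(size=())})
        x = rng.normal(size=(2, 12))
        got = conv_block_forward(blk, params, x, cam_reduction=2)
        want = conv_block_oracle(blk, params, x, cam_reduction=2)
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestFullyConnected:
    def test_zero_params_zero_logits(self):
        params = {"fc0.w": np.zeros((4, 3)), "fc0.b": np.zeros(3)}
        np.testing.assert_allclose(fully_connected_forward([3], params,
                                                           np.ones(4)), 0.0)

    def test_single_identity_layer_is_affine(self, rng):
        # final layer: affine only, no ReLU
        params = {"fc0.w": np.eye(4), "fc0.b": np.zeros(4)}
        v = rng.normal(size=4)
        np.testing.assert_allclose(fully_connected_forward([4], params, v), v)

    def test_hand_affine_hidden_vs_final(self):
        w = np.array([[1.0, 0.0], [0.0, -1.0]])
        b = np.array([0.0, 1.0])
        v = np.array([2.0, 3.0])
        # as hidden layer (ReLU applied): [2, -2] -> [2, 0]
        params2 = {"fc0.w": w, "fc0.b": b,
                   "fc1.w": np.eye(2), "fc1.b": np.zeros(2)}
        np.testing.assert_allclose(fully_connected_forward([2, 2], params2, v),
                                   [2.0, 0.0])
        # as final layer (affine only): [2, -2]
        params1 = {"fc0.w": w, "fc0.b": b}
        np.testing.assert_allclose(fully_connected_forward([2], params1, v),
                                   [2.0, -2.0])

    def test_dimension_mismatch(self):
        params = {"fc0.w": np.zeros((4, 3)), "fc0.b": np.zeros(3)}
        with pytest.raises(ValueError, match="size"):
            fully_connected_forward([3], params, np.ones(5))

    def test_inference_deterministic_despite_dropout_rate(self, rng):
        params = {"fc0.w": rng.normal(size=(4, 4)), "fc0.b": np.zeros(4),
                  "fc1.w": rng.normal(size=(4, 2)), "fc1.b": np.zeros(2)}
        v = rng.normal(size=4)
        a = fully_connected_forward([4, 2], params, v, dropout_rate=0.5, training=False)
        b = fully_connected_forward([4, 2], params, v, dropout_rate=0.5, training=False)
        np.testing.assert_array_equal(a, b)


class TestSoftmax:
    def test_uniform_for_equal_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(8)), np.full(8, 1 / 8))

    def test_closed_form(self):
        np.testing.assert_allclose(softmax(np.array([0.0, np.log(2.0)])),
                                   [1 / 3, 2 / 3])

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-100, 100))
    def test_shift_invariance(self, shift):
        logits = np.array([0.5, -1.0, 2.0])
        np.testing.assert_allclose(softmax(logits + shift), softmax(logits),
                                   atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            softmax(np.array([1.0, np.inf]))

    def test_sums_to_one_extreme(self):
        out = softmax(np.array([1000.0, -1000.0, 0.0]))
        assert out.sum() == pytest.approx(1.0)


class TestModelForward:
    def test_zero_params_uniform(self):
        spec = build_architecture(288, 8, "none")
        params = {k: np.zeros_like(v) for k, v in init_params(spec).items()}
        for k in params:
            if k.endswith("running_var"):
                params[k][:] = 1.0
        probs = model_forward(spec, params, np.random.default_rng(0).normal(size=(3, 288)))
        np.testing.assert_allclose(probs, 1 / 8, atol=1e-9)

    def test_batch_permutation_equivariance(self, rng):
        spec = build_architecture(108, 8, "csam")
        params = init_params(spec, rng)
        X = rng.normal(size=(6, 108))
        perm = rng.permutation(6)
        probs = model_forward(spec, params, X)
        probs_perm = model_forward(spec, params, X[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-10)

    def test_band_mismatch_names_lens(self, rng):
        spec = build_architecture(288, 8, "none")
        with pytest.raises(ValueError, match="SWIR"):
            model_forward(spec, init_params(spec, rng), rng.normal(size=(2, 108)))

    def test_probabilities_normalized(self, rng):
        spec = build_architecture(108, 8, "csam")
        probs = model_forward(spec, init_params(spec, rng),
                              rng.normal(size=(5, 108)))
        assert np.all(np.isfinite(probs))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_layer_by_layer_oracle(self, rng):
        spec = build_architecture(108, 8, "csam", cam_reduction=2)
        params = init_params(spec, rng)
        x = rng.normal(size=108)
        got = model_forward(spec, params, x[None])[0]
        want = model_oracle(spec, params, x)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_model_class_agrees_with_functional(self, rng):
        spec = build_architecture(108, 8, "sam")
        params = init_params(spec, rng)
        X = rng.normal(size=(4, 108))
        m = Model(spec, params=params)
        np.testing.assert_allclose(m.predict_proba(X),
                                   model_forward(spec, params, X), atol=1e-10)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        spec = build_architecture(108, 8, "csam")
        params = init_params(spec, rng)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, spec, params)
        spec2, params2 = load_checkpoint(path)
        assert spec2 == spec
        assert set(params2) == set(params)
        for k in params:
            np.testing.assert_array_equal(params2[k], params[k])
        X = rng.normal(size=(2, 108))
        np.testing.assert_allclose(model_forward(spec2, params2, X),
                                   model_forward(spec, params, X), atol=1e-12)


class TestSpecValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ConvBlockSpec(kernel_size=4, in_channels=1, out_channels=8)

    def test_fc_head_must_end_in_n_classes(self):
        blk = ConvBlockSpec(kernel_size=3, in_channels=1, out_channels=8)
        with pytest.raises(ValueError, match="n_classes"):
            ArchitectureSpec(input_bands=64, blocks=[blk], fc_sizes=[16, 4],
                             n_classes=8)
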