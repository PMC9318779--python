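"""Backbone/classifier shape contracts, fusion operators, model assembly."""

import numpy as np
import pytest

import eegfuse as ef
from eegfuse import nn
from eegfuse.model import AttentionFusion, fuse_add, fuse_mult


def _stage_shapes(stack, x):
    shapes = []
    for layer in stack.layers:
        x = layer.forward(x, training=False)
        shapes.append(x.shape[1:])
    return shapes, x


class TestBackbone:
    def test_table_cascade_2000(self):
        """2000 samples -> (1000,32) -> (498,64) -> pooled (249,64)."""
        model = ef.ECNAF(("gamma",), 6, fusion="none", seed=0)
        x = np.random.default_rng(0).standard_normal((2, 2000, 6)).astype(np.float32)
        shapes, out = _stage_shapes(model.backbones["gamma"], x)
        assert shapes[0] == (1000, 32)  # conv1
        assert shapes[2] == (498, 64)  # conv2
        assert shapes[4] == (249, 64)  # pool
        assert out.shape == (2, 249, 64)

    def test_length_1280_maps_to_159(self):
        assert ef.backbone_stage_lengths(1280) == [640, 318, 159]
        model = ef.ECNAF(("gamma",), 6, fusion="none", seed=0)
        x = np.zeros((1, 1280, 6), dtype=np.float32)
        out = model.backbones["gamma"].forward(x)
        assert out.shape == (1, 159, 64)

    def test_eval_mode_deterministic(self):
        model = ef.ECNAF(("beta", "gamma"), 4, fusion="attention", seed=3)
        rng = np.random.default_rng(1)
        xs = {b: rng.standard_normal((3, 256, 4)).astype(np.float32) for b in model.bands}
        p1 = model.forward(xs, training=False)
        p2 = model.forward(xs, training=False)
        assert np.array_equal(p1, p2)

    def test_input_below_receptive_field_errors(self):
        model = ef.ECNAF(("gamma",), 2, fusion="none", seed=0)
        with pytest.raises(ValueError, match="minimum valid length"):
            model.backbones["gamma"].forward(np.zeros((1, 8, 2), dtype=np.float32))


class TestFusionOperators:
    def test_add_identity_and_values(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((2, 5, 3))
        assert np.array_equal(fuse_add([f, np.zeros_like(f)]), f)
        out = fuse_add([np.array([[[1.0], [2.0]]]), np.array([[[3.0], [4.0]]])])
        assert out.ravel().tolist() == [4.0, 6.0]

    def test_mult_identity_and_values(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((2, 5, 3))
        assert np.array_equal(fuse_mult([f, np.ones_like(f)]), f)
        out = fuse_mult([np.array([[[2.0], [3.0]]]), np.array([[[4.0], [5.0]]])])
        assert out.ravel().tolist() == [8.0, 15.0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        fs = [rng.standard_normal((2, 4, 3)) for _ in range(3)]
        assert np.allclose(fuse_add(fs), fuse_add(fs[::-1]))
        assert np.allclose(fuse_mult(fs), fuse_mult(fs[::-1]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_add([np.zeros((1, 4, 2)), np.zeros((1, 5, 2))])


class TestAttentionUnit:
    def test_zero_queries_give_half_gates(self):
        fusion = AttentionFusion(("beta", "gamma"), 4)
        rng = np.random.default_rng(0)
        feats = {b: rng.standard_normal((3, 6, 4)) for b in ("beta", "gamma")}
        out, gates = fusion.forward_bands(feats)
        for w in gates.values():
            assert np.allclose(w, 0.5)
        assert np.allclose(out, 0.5 * (feats["beta"] + feats["gamma"]))

    def test_log3_logit_gives_three_quarter_gate(self):
        fusion = AttentionFusion(("gamma",), 2)
        # arrange q . v = ln 3 -> sigmoid = 0.75
        fusion.params["q_gamma"] = np.array([np.log(3.0), 0.0])
        feats = {"gamma": np.ones((1, 4, 2))}
        _, gates = fusion.forward_bands(feats)
        assert gates["gamma"][0] == pytest.approx(0.75, abs=1e-12)

    def test_gates_open_interval_and_per_band(self):
        fusion = AttentionFusion(("beta", "gamma"), 4)
        rng = np.random.default_rng(1)
        fusion.params["q_beta"] = rng.standard_normal(4)
        fusion.params["q_gamma"] = rng.standard_normal(4)
        feats = {b: rng.standard_normal((16, 6, 4)) for b in ("beta", "gamma")}
        _, gates = fusion.forward_bands(feats)
        for w in gates.values():
            assert np.all((w > 0) & (w < 1))
        assert not np.allclose(gates["beta"], gates["gamma"])

    def test_permutation_equivariance(self):
        """Permuting bands together with their queries leaves F' unchanged."""
        rng = np.random.default_rng(2)
        feats = {b: rng.standard_normal((2, 5, 3)) for b in ("delta", "beta", "gamma")}
        qs = {b: rng.standard_normal(3) for b in feats}
        fwd = AttentionFusion(("delta", "beta", "gamma"), 3)
        rev = AttentionFusion(("gamma", "beta", "delta"), 3)
        for b in feats:
            fwd.params[f"q_{b}"] = qs[b]
            rev.params[f"q_{b}"] = qs[b]
        out_f, _ = fwd.forward_bands(feats)
        out_r, _ = rev.forward_bands(feats)
        assert np.allclose(out_f, out_r)

    def test_gate_gradient_nonzero_at_init(self):
        """No dead gating: dWeight/dq != 0 for nonzero pooled features."""
        fusion = AttentionFusion(("gamma",), 3, dtype=np.float64)
        feats = {"gamma": np.full((2, 4, 3), 2.0)}
        fusion.forward_bands(feats)
        fusion.backward(np.ones((2, 4, 3)))
        assert np.any(fusion.grads["q_gamma"] != 0)

    def test_wrong_query_length(self):
        fusion = AttentionFusion(("gamma",), 8)
        with pytest.raises(ValueError, match="feature maps"):
            fusion.forward_bands({"gamma": np.zeros((1, 4, 3))})


class TestClassifier:
    def test_table_cascade_249(self):
        """(249,64) -> 245 -> 245 -> 122 -> 118 -> 118 -> 256 -> 3."""
        assert ef.classifier_stage_lengths(249) == [245, 245, 122, 118, 118]
        model = ef.ECNAF(("gamma",), 6, fusion="none", seed=0)
        x = np.random.default_rng(0).standard_normal((2, 249, 64)).astype(np.float32)
        shapes, out = _stage_shapes(model.classifier, x)
        assert shapes[0] == (245, 128)
        assert shapes[4] == (122, 128)
        assert shapes[9] == (118, 256)
        assert shapes[11] == (256,)  # global average pool
        assert out.shape == (2, 3)

    def test_probabilities_sum_to_one(self):
        model = ef.ECNAF(("beta", "gamma"), 4, seed=0)
        rng = np.random.default_rng(0)
        xs = {b: rng.standard_normal((5, 256, 4)).astype(np.float32) for b in model.bands}
        probs = model.forward(xs)
        assert probs.shape == (5, 3)
        assert np.all(probs > 0) and np.all(probs < 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_global_pool_of_constant_map(self):
        pool = nn.GlobalAvgPool1D()
        out = pool.forward(np.full((2, 10, 4), 3.5))
        assert np.allclose(out, 3.5)


class TestAssembly:
    def test_branch_count_matches_bands(self):
        model = ef.build_ecnaf(("delta", "beta", "gamma"), 6, "attention", seed=0)
        assert len(model.backbones) == 3
        assert set(model.backbones) == {"delta", "beta", "gamma"}
        assert len([k for k in model.named_params() if k.startswith("fusion.")]) == 3

    def test_seeded_init_reproducible(self):
        a = ef.ECNAF(("beta", "gamma"), 4, seed=11)
        b = ef.ECNAF(("beta", "gamma"), 4, seed=11)
        for (ka, (la, na)), (kb, (lb, nb)) in zip(
            a.named_params().items(), b.named_params().items()
        ):
            assert ka == kb
            assert np.array_equal(la.params[na], lb.params[nb])
        c = ef.ECNAF(("beta", "gamma"), 4, seed=12)
        assert any(
            not np.array_equal(a.named_params()[k][0].params[a.named_params()[k][1]],
                               c.named_params()[k][0].params[c.named_params()[k][1]])
            for k in a.named_params()
        )

    def test_single_band_with_fusion_rejected(self):
        with pytest.raises(ValueError, match="single band"):
            ef.ECNAF(("gamma",), 4, fusion="attention")
        with pytest.raises(ValueError, match="none"):
            ef.ECNAF(("beta", "gamma"), 4, fusion="none")

    def test_no_weight_sharing_across_bands(self):
        model = ef.ECNAF(("beta", "gamma"), 4, seed=0)
        wb = model.backbones["beta"].layers[0].params["W"]
        wg = model.backbones["gamma"].layers[0].params["W"]
        assert not np.array_equal(wb, wg)

    def test_parameter_count_positive_and_reported(self):
        model = ef.ECNAF(("beta", "gamma"), 6, seed=0)
        n = model.parameter_count()
        assert n == sum(
            layer.params[name].size for layer, name in model.named_params().values()
        )
        assert n > 100_000

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path):
        model = ef.ECNAF(("beta", "gamma"), 4, fusion="attention", seed=5)
        rng = np.random.default_rng(0)
        xs = {b: rng.standard_normal((3, 256, 4)).astype(np.float32) for b in model.bands}
        # perturb away from init so the test is not trivially passing
        for layer, name in model.named_params().values():
            layer.params[name] = layer.params[name] + 0.01
        before = model.forward(xs)
        model.save(tmp_path / "ckpt")
        reloaded = ef.ECNAF.load(tmp_path / "ckpt")
        assert np.array_equal(before, reloaded.forward(xs))
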