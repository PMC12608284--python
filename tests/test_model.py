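"""Architecture contracts: attention vs a scalar-loop oracle, multiscale
shape arithmetic, transformer shape preservation, TCN causality and
receptive field, demographic fusion semantics, and variant assembly."""

import numpy as np
import pytest

from difnet.model import (
    DIFNet,
    DifnetConfig,
    FusionConfig,
    FusionHead,
    MultiscaleBlock,
    MultiscaleConfig,
    TCN,
    TCNConfig,
    TransformerConfig,
    TransformerEncoder,
    build_difnet,
    multi_head_attention,
    normalize_demographics,
    receptive_field,
    scaled_dot_attention,
)
from difnet.nn import Tensor

from conftest import tiny_config

RNG = np.random.default_rng(42)


def attention_oracle(q, k, v):
    """Scalar-loop reference: every dot product, exponential and
    normalization computed elementwise."""
    n_q, d_k = q.shape
    n_kv, d_v = v.shape
    out = np.zeros((n_q, d_v))
    for i in range(n_q):
        scores = np.empty(n_kv)
        for j in range(n_kv):
            s = 0.0
            for a in range(d_k):
                s += q[i, a] * k[j, a]
            scores[j] = s / np.sqrt(d_k)
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n_kv):
            for b in range(d_v):
                out[i, b] += w[j] * v[j, b]
    return out


class TestScaledDotAttention:
    def test_single_key_value_returns_value(self):
        q = RNG.normal(size=(4, 3))
        k = RNG.normal(size=(1, 3))
        v = RNG.normal(size=(1, 5))
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out, np.tile(v, (4, 1)), atol=1e-12)

    def test_zero_query_gives_value_mean(self):
        k = RNG.normal(size=(6, 3))
        v = RNG.normal(size=(6, 2))
        out = scaled_dot_attention(np.zeros((2, 3)), k, v)
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (2, 1)),
                                   atol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            n, m, dk, dv = rng.integers(1, 6, size=4)
            q = rng.normal(size=(n, dk))
            k = rng.normal(size=(m, dk))
            v = rng.normal(size=(m, dv))
            np.testing.assert_allclose(scaled_dot_attention(q, k, v),
                                       attention_oracle(q, k, v), atol=1e-10)

    def test_weight_rows_sum_to_one(self):
        from difnet.model import attention_weights

        w = attention_weights(RNG.normal(size=(5, 4)), RNG.normal(size=(7, 4)))
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-9)

    def test_empty_matrices_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((0, 3)), np.zeros((2, 3)),
                                 np.zeros((2, 3)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_attention(self):
        x = RNG.normal(size=(5, 4))
        eye = np.eye(4)
        out = multi_head_attention(x, eye, eye, eye, eye, n_heads=1)
        np.testing.assert_allclose(out, scaled_dot_attention(x, x, x),
                                   atol=1e-12)

    def test_shape_preserved_at_study_dimensions(self):
        x = RNG.normal(size=(2, 31, 96))
        w = [RNG.normal(size=(96, 96)) * 0.1 for _ in range(4)]
        out = multi_head_attention(x, *w, n_heads=6)
        assert out.shape == (2, 31, 96)

    def test_permutation_equivariance_without_positional_encoding(self):
        x = RNG.normal(size=(7, 12))
        w = [RNG.normal(size=(12, 12)) * 0.3 for _ in range(4)]
        perm = np.random.default_rng(1).permutation(7)
        out = multi_head_attention(x, *w, n_heads=3)
        out_perm = multi_head_attention(x[perm], *w, n_heads=3)
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_indivisible_heads_rejected(self):
        x = RNG.normal(size=(5, 10))
        w = [np.eye(10)] * 4
        with pytest.raises(ValueError, match="divisible"):
            multi_head_attention(x, *w, n_heads=3)


class TestMultiscale:
    def test_study_shape_chain(self):
        block = MultiscaleBlock(MultiscaleConfig(), np.random.default_rng(0))
        block.eval()
        out = block(Tensor(RNG.normal(size=(1, 1, 16, 1000))))
        assert out.shape == (1, 96, 31)

    def test_electrode_axis_collapsed(self):
        """The depthwise spatial stage removes the electrode axis entirely:
        channel count depends only on filters x multiplier x branches."""
        for n_ch in (4, 16, 19):
            cfg = MultiscaleConfig(kernel_sizes=(31,), temporal_filters=2,
                                   n_channels=n_ch)
            block = MultiscaleBlock(cfg, np.random.default_rng(0))
            block.eval()
            out = block(Tensor(RNG.normal(size=(1, 1, n_ch, 256))))
            assert out.shape == (1, 4, 8)

    def test_minimal_configuration_channel_count(self):
        cfg = MultiscaleConfig(kernel_sizes=(7,), temporal_filters=1,
                               n_channels=2)
        block = MultiscaleBlock(cfg, np.random.default_rng(0))
        block.eval()
        out = block(Tensor(RNG.normal(size=(1, 1, 2, 64))))
        assert out.shape[1] == 2  # 1 branch x 1 filter x multiplier 2

    def test_kernel_longer_than_epoch_rejected(self):
        block = MultiscaleBlock(MultiscaleConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="kernel"):
            block(Tensor(RNG.normal(size=(1, 1, 16, 100))))


class TestTransformerEncoder:
    def test_shape_preserving(self):
        enc = TransformerEncoder(TransformerConfig(), 96,
                                 np.random.default_rng(0))
        enc.eval()
        out = enc(Tensor(RNG.normal(size=(2, 31, 96))))
        assert out.shape == (2, 31, 96)

    def test_two_layers_six_heads(self):
        enc = TransformerEncoder(TransformerConfig(), 96,
                                 np.random.default_rng(0))
        assert len(enc.layers) == 2
        assert all(layer.attn.n_heads == 6 for layer in enc.layers)

    def test_zero_output_projections_give_residual_identity(self):
        """With attention and FFN output projections zeroed, each layer is
        residual + normalization; row-normalized input passes unchanged."""
        enc = TransformerEncoder(TransformerConfig(n_layers=2), 96,
                                 np.random.default_rng(0))
        enc.eval()
        for layer in enc.layers:
            layer.attn.wo.data[...] = 0.0
            layer.ff2.weight.data[...] = 0.0
            layer.ff2.bias.data[...] = 0.0
        x = RNG.normal(size=(1, 31, 96))
        x = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)
        out = enc(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-2)

    def test_width_mismatch_rejected_without_adaptation(self):
        cfg = TransformerConfig(adapt_width=False)
        with pytest.raises(ValueError, match="boundary"):
            TransformerEncoder(cfg, 48, np.random.default_rng(0))

    def test_width_adaptation_picks_largest_dividing_head_count(self):
        enc = TransformerEncoder(TransformerConfig(), 32,
                                 np.random.default_rng(0))
        assert enc.n_heads == 4  # largest h <= 6 dividing 32


class TestTCN:
    def test_receptive_field_formula(self):
        assert receptive_field(2, 4) == 19
        assert receptive_field(1, 1) == 1
        assert receptive_field(3, 1) == 1  # pointwise kernels see one sample
        assert receptive_field(3, 2) == 15
        with pytest.raises(ValueError):
            receptive_field(0, 4)

    @staticmethod
    def probe(tcn, c_in, length):
        """Empirical influence map: which input times affect the last output."""
        tcn.eval()
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, c_in, length))
        ref = tcn(Tensor(base)).data[0, :, -1]
        reach = []
        for t in range(length):
            x = base.copy()
            x[0, :, t] += 10.0
            delta = np.abs(tcn(Tensor(x)).data[0, :, -1] - ref).max()
            reach.append(delta > 1e-9)
        return np.array(reach)

    @pytest.mark.parametrize("n_blocks,kernel", [(1, 2), (1, 4), (2, 3), (3, 2)])
    def test_empirical_receptive_field_matches_formula(self, n_blocks, kernel):
        rfs = receptive_field(n_blocks, kernel)
        length = rfs + 5
        tcn = TCN(TCNConfig(n_blocks=n_blocks, kernel=kernel, filters=4),
                  c_in=3, rng=np.random.default_rng(1))
        reach = self.probe(tcn, 3, length)
        # the last output sees exactly the trailing RFS samples
        assert reach[-rfs:].all()
        assert not reach[: length - rfs].any()

    def test_causality_at_every_index(self):
        length = 31
        tcn = TCN(TCNConfig(filters=8), c_in=8, rng=np.random.default_rng(2))
        tcn.eval()
        base = np.random.default_rng(3).normal(size=(1, 8, length))
        ref = tcn(Tensor(base)).data[0]
        for t in range(length):
            x = base.copy()
            x[0, :, t] += 5.0
            out = tcn(Tensor(x)).data[0]
            delta = np.abs(out - ref).max(axis=0)
            assert delta[:t].max() < 1e-9 if t else True  # strictly causal
            assert delta[t] > 1e-9  # perturbation is visible at its own time

    def test_projection_only_when_widths_differ(self):
        same = TCN(TCNConfig(filters=32), c_in=32, rng=np.random.default_rng(0))
        assert same.blocks[0].projection is None
        diff = TCN(TCNConfig(filters=32), c_in=96, rng=np.random.default_rng(0))
        assert diff.blocks[0].projection is not None
        assert diff.blocks[1].projection is None


class TestNormalizeDemographics:
    def test_affine_endpoints_and_midpoint(self):
        import pandas as pd

        demo = pd.DataFrame({"age": [20, 35, 50]})
        vals, stats = normalize_demographics(demo, ["age"])
        np.testing.assert_allclose(vals[:, 0], [0.0, 0.5, 1.0])
        assert stats["age"] == (20.0, 50.0)

    def test_frozen_stats_clip_out_of_range_with_warning(self):
        import pandas as pd

        train = pd.DataFrame({"age": [20, 40]})
        _, stats = normalize_demographics(train, ["age"])
        test = pd.DataFrame({"age": [55]})
        with pytest.warns(UserWarning, match="clipping"):
            vals, _ = normalize_demographics(test, ["age"], stats)
        assert vals[0, 0] == 1.0

    def test_degenerate_indicator_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="degenerate"):
            normalize_demographics(pd.DataFrame({"age": [30, 30]}), ["age"])


class TestFusion:
    def test_code_n_skips_fusion_and_matches_no_fusion_network(self):
        cfg = tiny_config(indicators="N")
        model = build_difnet(cfg, seed=0)
        assert model.fusion is None
        assert "fusion" not in model.block_sequence

    def test_frozen_scalar_doubles_features(self):
        head = FusionHead(FusionConfig(indicators="AY"),
                          np.random.default_rng(0))
        head.eval()
        head.dense.weight.data[...] = 0.0
        head.dense.bias.data[...] = 40.0  # sigmoid saturates -> F == 2.0
        feats = Tensor(RNG.normal(size=(3, 8, 10)))
        demo = Tensor(RNG.random(size=(3, 2)))
        out = head(feats, demo)
        np.testing.assert_array_equal(out.data, 2.0 * feats.data)

    def test_fusion_scalar_starts_bounded_and_centered(self):
        """At initialization F lies in (0, 2) and is centered near 1, so
        fusion begins identity-like but with enough spread to receive
        gradient through the demographic pathway."""
        fs = []
        for seed in range(20):
            head = FusionHead(FusionConfig(indicators="ASY"),
                              np.random.default_rng(seed))
            head.eval()
            f = head.scalar(Tensor(RNG.random(size=(8, 3))), n=10).data
            assert ((f > 0) & (f < 2)).all()
            fs.append(f.mean())
        assert abs(np.mean(fs) - 1.0) < 0.2

    def test_demographics_influence_loss_end_to_end(self):
        """Finite-difference gradient of the loss w.r.t. a demographic input
        is non-zero once the fusion head is non-degenerate."""
        from difnet.nn import cross_entropy

        cfg = tiny_config(indicators="AY")
        model = build_difnet(cfg, seed=1)
        model.eval()
        model.fusion.dense.weight.data[...] = \
            np.random.default_rng(2).normal(size=model.fusion.dense.weight.shape)
        x = RNG.normal(size=(2, 1, 4, 500))
        y = np.array([0, 1])
        demo = RNG.random(size=(2, 2))

        def loss_at(d):
            return float(cross_entropy(model.forward(x, d), y).data)

        eps = 1e-5
        d_hi = demo.copy(); d_hi[0, 0] += eps
        d_lo = demo.copy(); d_lo[0, 0] -= eps
        grad = (loss_at(d_hi) - loss_at(d_lo)) / (2 * eps)
        assert abs(grad) > 1e-8

    def test_empty_indicator_set_rejected(self):
        with pytest.raises(ValueError):
            FusionHead(FusionConfig(indicators="N"), np.random.default_rng(0))


class TestBuildDifnet:
    def test_softmax_probabilities(self):
        model = build_difnet(tiny_config(indicators="AY"), seed=0)
        x = RNG.normal(size=(3, 1, 4, 500))
        demo = RNG.random(size=(3, 2))
        p = model.predict_proba(x, demo)
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_all_five_ablation_variants_assemble_distinctly(self):
        sequences = {}
        for order in ("baseline", "T1", "T2", "T2T1", "T1T2"):
            model = build_difnet(tiny_config(module_order=order), seed=0)
            sequences[order] = tuple(model.block_sequence)
        assert sequences["baseline"] == ("multiscale", "dense_softmax")
        assert sequences["T1"] == ("multiscale", "transformer", "dense_softmax")
        assert sequences["T2"] == ("multiscale", "tcn", "dense_softmax")
        assert sequences["T2T1"] == ("multiscale", "tcn", "transformer",
                                     "dense_softmax")
        assert sequences["T1T2"] == ("multiscale", "transformer", "tcn",
                                     "dense_softmax")

    def test_order_swap_changes_computation(self):
        x = RNG.normal(size=(2, 1, 4, 500))
        a = build_difnet(tiny_config(module_order="T1T2"), seed=5)
        b = build_difnet(tiny_config(module_order="T2T1"), seed=5)
        a.eval(); b.eval()
        assert not np.allclose(a.forward(x).data, b.forward(x).data)

    def test_seeded_build_is_reproducible(self):
        x = RNG.normal(size=(1, 1, 4, 500))
        a = build_difnet(tiny_config(), seed=7)
        b = build_difnet(tiny_config(), seed=7)
        a.eval(); b.eval()
        np.testing.assert_array_equal(a.forward(x).data, b.forward(x).data)

    def test_missing_demographics_rejected(self):
        model = build_difnet(tiny_config(indicators="A"), seed=0)
        model.eval()
        with pytest.raises(ValueError, match="requires demographics"):
            model.forward(RNG.normal(size=(1, 1, 4, 500)))

    def test_config_yaml_and_checkpoint_round_trip(self, tmp_path):
        from difnet.model import (config_from_yaml, config_to_yaml,
                                  load_checkpoint, save_checkpoint)

        cfg = tiny_config(indicators="AY")
        config_to_yaml(cfg, tmp_path / "model.yaml")
        cfg2 = config_from_yaml(tmp_path / "model.yaml")
        assert cfg2 == cfg

        model = build_difnet(cfg, seed=4).eval()
        x = RNG.normal(size=(2, 1, 4, 500))
        demo = RNG.random(size=(2, 2))
        before = model.forward(x, demo).data
        save_checkpoint(model, tmp_path / "weights.npz")
        other = build_difnet(cfg, seed=99).eval()
        assert not np.allclose(other.forward(x, demo).data, before)
        load_checkpoint(other, tmp_path / "weights.npz")
        np.testing.assert_array_equal(other.forward(x, demo).data, before)

    def test_fingerprint_reports_architecture(self):
        model = build_difnet(tiny_config(indicators="AY"), seed=0)
        fp = model.fingerprint()
        assert fp["variant"] == "DIFNet-AY"
        assert fp["n_parameters"] == model.n_parameters()
        assert "fusion" in fp["blocks"]
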