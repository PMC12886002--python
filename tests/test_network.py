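"""Architecture contracts: shapes, dual-branch routing, biased transformer."""

import numpy as np
import pytest

from hemaseg import gpsa
from hemaseg.autodiff import Tensor, no_grad
from hemaseg.errors import ConfigurationError, ShapeMismatchError
from hemaseg.network import CrossPhaseNet, ModelConfig


def _layernorm_np(x, gamma, beta, eps=1e-6):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def _softmax_np(x):
    z = x - x.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


def plain_transformer_oracle(model, tokens):
    """Independent numpy re-implementation of the pre-norm stack (no bias)."""
    x = tokens.copy()
    for blk in model.blocks:
        xn = _layernorm_np(x, blk.ln1.gamma.data, blk.ln1.beta.data)
        B, N, D = x.shape
        h, dh = blk.heads, D // blk.heads

        def proj(lin, t):
            return (t @ lin.weight.data + lin.bias.data)

        def split(t):
            return t.reshape(B, N, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(proj(blk.wq, xn)), split(proj(blk.wk, xn)), split(proj(blk.wv, xn))
        logits = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
        att = _softmax_np(logits) @ v
        att = att.transpose(0, 2, 1, 3).reshape(B, N, D)
        x = x + proj(blk.wo, att)
        xn2 = _layernorm_np(x, blk.ln2.gamma.data, blk.ln2.beta.data)
        mlp = np.maximum(proj(blk.fc1, xn2), 0.0)
        x = x + proj(blk.fc2, mlp)
    return _layernorm_np(x, model.ln_f.gamma.data, model.ln_f.beta.data)


@pytest.fixture(scope="module")
def tiny_model():
    return CrossPhaseNet(ModelConfig.tiny(), seed=0)


class TestConfig:
    def test_grid_side_is_pure_function_of_config(self):
        for side in (32, 64, 128, 512):
            cfg = ModelConfig.tiny(input_size=side)
            assert cfg.grid_side == side // 16
            assert cfg.n_tokens == (side // 16) ** 2
        assert ModelConfig().grid_side == 32  # 512-input default

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig.tiny(input_size=65)


class TestEncoder:
    @pytest.mark.parametrize("side", [32, 64])
    def test_four_stride2_stages(self, tiny_model, side, rng):
        x = Tensor(rng.normal(size=(1, 1, side, side)))
        final, skips = tiny_model.enc_nc(x)
        assert final.shape == (1, 64, side // 16, side // 16)
        assert [s.shape[-1] for s in skips] == [side // 2, side // 4, side // 8, side // 16]

    def test_zero_input_gives_zero_features(self, tiny_model):
        final, skips = tiny_model.enc_nc(Tensor(np.zeros((1, 1, 64, 64))))
        for s in skips:
            np.testing.assert_array_equal(s.data, 0.0)

    def test_indivisible_side_rejected(self, tiny_model):
        with pytest.raises(ShapeMismatchError):
            tiny_model.enc_nc(Tensor(np.zeros((1, 1, 60, 60))))


class TestTokens:
    def test_token_counts(self, tiny_model, rng):
        t = tiny_model.tokenize(Tensor(rng.normal(size=(1, 64, 4, 4))))
        assert t.shape == (1, 16, 32)

    def test_constant_map_identity_projection(self):
        model = CrossPhaseNet(ModelConfig.tiny(token_dim=64), seed=0)
        model.proj.weight.data = np.eye(64)
        model.proj.bias.data[:] = 0.0
        model.pos.data[:] = 0.0
        t = model.tokenize(Tensor(np.full((1, 64, 4, 4), 1.5)))
        np.testing.assert_allclose(t.data, 1.5)

    def test_full_scale_token_count(self):
        cfg = ModelConfig()
        assert cfg.n_tokens == 1024  # 32 x 32 feature grid of the 512 input


class TestTransformer:
    def test_zero_bias_matches_plain_oracle(self, tiny_model, rng):
        tokens = rng.normal(size=(2, 16, 32))
        with no_grad():
            out, _ = tiny_model.transform(Tensor(tokens), None)
        np.testing.assert_allclose(out.data, plain_transformer_oracle(tiny_model, tokens),
                                   atol=1e-5)

    def test_shape_contract(self, tiny_model, rng):
        tokens = rng.normal(size=(1, 16, 32))
        with no_grad():
            out, probs = tiny_model.transform(Tensor(tokens), None)
        assert out.shape == (1, 16, 32)
        assert probs.shape == (1, 16, 16)
        np.testing.assert_allclose(probs.data.sum(-1), 1.0, atol=1e-6)

    def test_bias_size_mismatch_rejected(self, tiny_model, rng):
        bias = Tensor(np.ones((1, 1, 9, 9)))
        with pytest.raises(ShapeMismatchError):
            tiny_model.transform(Tensor(rng.normal(size=(1, 16, 32))), bias)

    def test_stronger_bias_concentrates_attention_on_tumor_tokens(self, tiny_model, rng):
        tokens = rng.normal(size=(1, 16, 32))
        g = np.full(16, 0.05)
        tumor = [5, 6, 9, 10]
        g[tumor] = 1.0
        Bmat = np.outer(g, g)[None, None]
        masses = []
        for lam in (0.5, 1.0, 2.0, 4.0):
            with no_grad():
                _, probs = tiny_model.transform(Tensor(tokens), Tensor(lam * Bmat))
            masses.append(probs.data[0][:, tumor].sum(-1).mean())
        assert all(a < b for a, b in zip(masses, masses[1:]))


class TestForward:
    def test_end_to_end_shapes_and_determinism(self, rng):
        x = rng.normal(size=(1, 1, 64, 64))
        v = rng.normal(size=(1, 1, 64, 64))
        m1 = CrossPhaseNet(ModelConfig.tiny(), seed=3)
        m2 = CrossPhaseNet(ModelConfig.tiny(), seed=3)
        with no_grad():
            out1, _ = m1.forward(Tensor(x), Tensor(v))
            out2, _ = m2.forward(Tensor(x), Tensor(v))
        assert out1.shape == (1, 2, 64, 64)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_paired_requires_venous(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward(Tensor(rng.normal(size=(1, 1, 64, 64))), None,
                               mode="paired")

    def test_single_equals_paired_on_identical_inputs(self, tiny_model, rng):
        x = rng.normal(size=(1, 1, 64, 64))
        with no_grad():
            p, _ = tiny_model.forward(Tensor(x), Tensor(x.copy()), mode="paired")
            s, _ = tiny_model.forward(Tensor(x), mode="single")
        np.testing.assert_array_equal(p.data, s.data)

    def test_gpsa_bias_changes_output_and_uniform_fallback_does_not(
            self, tiny_model, rng, tiny_case):
        x = rng.normal(size=(1, 1, 64, 64))
        v = rng.normal(size=(1, 1, 64, 64))
        with no_grad():
            base, _ = tiny_model.forward(Tensor(x), Tensor(v), use_gpsa=False)
            biased, aux = tiny_model.forward(Tensor(x), Tensor(v), use_gpsa=True,
                                             masks=tiny_case.mask[None])
            empty, aux_empty = tiny_model.forward(
                Tensor(x), Tensor(v), use_gpsa=True,
                masks=np.zeros((1, 64, 64)))
        assert aux["gpsa_valid"][0]
        assert not np.array_equal(base.data, biased.data)
        # empty mask -> uniform g -> rank-1 bias is row-constant -> no effect
        assert not aux_empty["gpsa_valid"][0]
        np.testing.assert_allclose(empty.data, base.data, atol=1e-10)

    def test_population_stats_inference_path(self, tiny_model, rng):
        x = rng.normal(size=(1, 1, 64, 64))
        stats = gpsa.GaussianStats(0.1, 0.2)
        with no_grad():
            out, aux = tiny_model.forward(Tensor(x), Tensor(x), use_gpsa=True,
                                          stats=stats)
        assert aux["gpsa_valid"][0]
        assert out.shape == (1, 2, 64, 64)

    def test_parameter_count_reported(self, tiny_model):
        n = tiny_model.parameter_count()
        assert n == sum(p.size for p in tiny_model.parameters()) > 0
        assert f"parameters: {n}" in tiny_model.describe()

    def test_predict_mask_binary(self, tiny_model, rng):
        x = rng.normal(size=(2, 1, 64, 64))
        pred = tiny_model.predict_mask(x, x)
        assert pred.shape == (2, 64, 64)
        assert set(np.unique(pred)) <= {0, 1}


class TestDecoder:
    def test_skip_length_mismatch_rejected(self, tiny_model, rng):
        with pytest.raises(ShapeMismatchError):
            tiny_model.decode(Tensor(rng.normal(size=(1, 64, 4, 4))), [])

    def test_head_channels_equal_num_classes(self, tiny_model):
        assert tiny_model.head.weight.data.shape[0] == 2

    def test_full_scale_forward_shape(self):
        """A narrow full-geometry instance: 512 input -> 32x32 tokens ->
        512x512 logits."""
        cfg = ModelConfig(input_size=512, base_channels=2, token_dim=8,
                          transformer_layers=1, attention_heads=2)
        model = CrossPhaseNet(cfg, seed=0)
        x = np.zeros((1, 1, 512, 512))
        with no_grad():
            out, _ = model.forward(Tensor(x), Tensor(x))
        assert out.shape == (1, 2, 512, 512)
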