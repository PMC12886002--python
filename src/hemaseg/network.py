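"""The cross-phase segmentation network.

Dual-branch 4-layer CNN encoders (3x3 kernels, stride 2) reduce each
512 x 512 input to a 32 x 32 feature map (64 -> 4 x 4 in the desk-scale
configuration). The venous-branch map is linearly projected into tokens
(plus learned positional embeddings) and refined by a pre-norm transformer
encoder (default 12 layers, 8 heads) whose attention logits carry the
additive rank-1 Gaussian bias lambda * g g^T from the GPSA module. The
token map is reshaped back to the feature grid and decoded by four stages
of 2x bilinear upsampling, each concatenated with the corresponding
non-contrast-branch skip (the innermost three encoder stages, then the
input image itself at full resolution) and mixed by a 3x3 stride-1 ReLU
convolution; a 1x1 head emits per-pixel class logits.

In paired mode the venous branch feeds the tokens and the non-contrast
branch feeds the Gaussian weights and the skips; in single mode one image
is routed through both branches, so paired and single outputs coincide
when the two phase inputs are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gpsa
from .autodiff import Tensor, concat, no_grad, softmax, upsample2x
from .errors import ConfigurationError, ShapeMismatchError
from .nn import Conv2d, Linear, LayerNorm, Module, parameter


@dataclass
class ModelConfig:
    input_size: int = 512
    encoder_layers: int = 4
    encoder_kernel: int = 3
    encoder_stride: int = 2
    base_channels: int = 16
    token_dim: int = 64
    transformer_layers: int = 12
    attention_heads: int = 8
    decoder_stages: int = 4
    num_classes: int = 2

    def __post_init__(self):
        if self.input_size % (2 ** self.encoder_layers):
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{self.encoder_layers}")
        if self.token_dim % self.attention_heads:
            raise ConfigurationError("token_dim must be divisible by attention_heads")

    @property
    def grid_side(self) -> int:
        return self.input_size // 2 ** self.encoder_layers

    @property
    def n_tokens(self) -> int:
        return self.grid_side ** 2

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale configuration that trains in minutes on one CPU."""
        kwargs = dict(input_size=64, base_channels=8, token_dim=32,
                      transformer_layers=2, attention_heads=2)
        kwargs.update(overrides)
        return cls(**kwargs)


class Encoder(Module):
    """Four stride-2 conv+ReLU stages, channels base * {1, 2, 4, 8}."""

    def __init__(self, config: ModelConfig, rng):
        chans = [1] + [config.base_channels * 2 ** i for i in range(config.encoder_layers)]
        self.convs = [
            Conv2d(chans[i], chans[i + 1], kernel=config.encoder_kernel,
                   stride=config.encoder_stride, padding=config.encoder_kernel // 2,
                   rng=rng)
            for i in range(config.encoder_layers)
        ]

    def __call__(self, x: Tensor):
        side = x.shape[-1]
        if side % (2 ** len(self.convs)):
            raise ShapeMismatchError(
                f"input side {side} not divisible by 2^{len(self.convs)}")
        skips = []
        for conv in self.convs:
            x = conv(x).relu()
            skips.append(x)
        return x, skips


class TransformerBlock(Module):
    """Pre-norm block: LN -> biased MHSA -> residual; LN -> 4x MLP -> residual."""

    def __init__(self, dim: int, heads: int, rng):
        self.ln1 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng=rng)
        self.wk = Linear(dim, dim, rng=rng)
        self.wv = Linear(dim, dim, rng=rng)
        self.wo = Linear(dim, dim, rng=rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 4 * dim, rng=rng)
        self.fc2 = Linear(4 * dim, dim, rng=rng)
        self.heads = heads
        self.dim = dim

    def attention(self, x: Tensor, bias_term):
        B, N, D = x.shape
        h, dh = self.heads, D // self.heads

        def split(t):
            return t.reshape(B, N, h, dh).transpose(0, 2, 1, 3)  # (B,h,N,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        if bias_term is not None:
            logits = logits + bias_term  # (B,1,N,N) broadcast over heads
        probs = softmax(logits, axis=-1)
        out = (probs @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.wo(out), probs

    def __call__(self, x: Tensor, bias_term):
        att, probs = self.attention(self.ln1(x), bias_term)
        x = x + att
        x = x + self.fc2(self.fc1(self.ln2(x)).relu())
        return x, probs


class CrossPhaseNet(Module):
    """Dual-branch encoder + biased transformer + skip-connected decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng([int(seed), 7])
        self.config = config
        bc = config.base_channels
        c4 = bc * 2 ** (config.encoder_layers - 1)
        self.enc_v = Encoder(config, rng)
        self.enc_nc = Encoder(config, rng)
        self.proj = Linear(c4, config.token_dim, rng=rng)
        self.pos = parameter(rng.normal(0.0, 0.02,
                                        size=(1, config.n_tokens, config.token_dim)))
        self.blocks = [TransformerBlock(config.token_dim, config.attention_heads, rng)
                       for _ in range(config.transformer_layers)]
        self.ln_f = LayerNorm(config.token_dim)
        self.unproj = Linear(config.token_dim, c4, rng=rng)
        # decoder stage input channels: upsampled features + skip
        skip_ch = [bc * 2 ** (config.encoder_layers - 2 - i)
                   for i in range(config.encoder_layers - 1)] + [1]
        out_ch = [max(ch, bc) for ch in skip_ch[:-1]] + [bc]
        in_ch = [c4] + out_ch[:-1]
        self.dec_convs = [
            Conv2d(in_ch[i] + skip_ch[i], out_ch[i], kernel=3, stride=1, padding=1, rng=rng)
            for i in range(config.decoder_stages)
        ]
        self.head = Conv2d(out_ch[-1], config.num_classes, kernel=1, stride=1,
                           padding=0, rng=rng)
        self.lambda_bias = parameter(np.asarray(gpsa.LAMBDA_BIAS_INIT))

    # -- stages ---------------------------------------------------------
    def tokenize(self, feature_map: Tensor, gate: np.ndarray | None = None) -> Tensor:
        """Row-major flatten + linear projection + positional embedding.

        ``gate`` optionally applies the multiplicative GPSA path
        (features * (1 + G)) before projection.
        """
        B, C, h, w = feature_map.shape
        if gate is not None:
            feature_map = feature_map * (1.0 + gate[:, None, :, :])
        tokens = feature_map.transpose(0, 2, 3, 1).reshape(B, h * w, C)
        return self.proj(tokens) + self.pos

    def transform(self, tokens: Tensor, bias_term):
        """Run the transformer stack; returns tokens and the last layer's
        head-mean attention probabilities (B, N, N)."""
        if bias_term is not None and bias_term.shape[-1] != tokens.shape[1]:
            raise ShapeMismatchError(
                f"bias size {bias_term.shape[-1]} != token count {tokens.shape[1]}")
        probs = None
        for block in self.blocks:
            tokens, probs = block(tokens, bias_term)
        return self.ln_f(tokens), probs.mean(axis=1)

    def untokenize(self, tokens: Tensor) -> Tensor:
        B, N, _ = tokens.shape
        side = int(np.sqrt(N))
        x = self.unproj(tokens)
        return x.reshape(B, side, side, x.shape[-1]).transpose(0, 3, 1, 2)

    def decode(self, x: Tensor, skips) -> Tensor:
        """Four rounds of 2x bilinear upsampling + skip concat + 3x3 ReLU conv,
        then the 1x1 segmentation head."""
        if len(skips) != len(self.dec_convs):
            raise ShapeMismatchError(
                f"need {len(self.dec_convs)} skip maps, got {len(skips)}")
        for conv, skip in zip(self.dec_convs, skips):
            x = upsample2x(x)
            if x.shape[-2:] != skip.shape[-2:]:
                raise ShapeMismatchError(
                    f"skip shape {skip.shape} does not match decoder {x.shape}")
            x = conv(concat([x, skip], axis=1)).relu()
        return self.head(x)

    def gaussian_weights(self, feature_mean: np.ndarray, masks=None, stats=None):
        """Per-sample multi-scale Gaussian maps from the channel-mean
        non-contrast feature map.

        ``masks`` (training) yields per-case statistics; ``stats``
        (inference) applies pooled population statistics. Samples whose
        mask vanishes at the token grid fall back to uniform weights (a
        constant g makes the rank-1 bias a per-row constant, which softmax
        ignores). Returns (G, per_case_stats, valid_flags).
        """
        B, h, w = feature_mean.shape
        G = np.ones((B, h, w))
        collected, valid = [], np.zeros(B, dtype=bool)
        for b in range(B):
            st = None
            if masks is not None:
                try:
                    st = gpsa.tumor_stats(feature_mean[b], masks[b])
                except gpsa.EmptyMaskError:
                    st = None
            elif stats is not None:
                st = stats
            if st is not None:
                G[b] = gpsa.multiscale_gaussian(feature_mean[b], st)
                valid[b] = True
                if masks is not None:
                    collected.append(st)
        return G, collected, valid

    # -- full forward ----------------------------------------------------
    def forward(self, xnc, xv=None, mode: str = "paired", use_gpsa: bool = False,
                masks=None, stats=None, gate: bool = False):
        """Full forward pass.

        Returns (logits, aux) where aux carries the last-layer head-mean
        attention probabilities, the Gaussian maps, per-case statistics and
        validity flags. ``use_gpsa`` enables the additive bias path;
        ``gate`` additionally enables the multiplicative feature gate.
        """
        xnc = xnc if isinstance(xnc, Tensor) else Tensor(xnc)
        if mode == "paired":
            if xv is None:
                raise ValueError("paired mode requires a venous-phase input")
            xv = xv if isinstance(xv, Tensor) else Tensor(xv)
        elif mode == "single":
            xv = xnc
        else:
            raise ValueError(f"unknown mode {mode!r}")

        fv, _ = self.enc_v(xv)
        fnc, skips_nc = self.enc_nc(xnc)

        aux = {"attention": None, "gaussian": None, "case_stats": [],
               "gpsa_valid": None}
        bias_term, gate_map = None, None
        if use_gpsa:
            feature_mean = fnc.data.mean(axis=1)  # detached guidance signal
            G, case_stats, valid = self.gaussian_weights(feature_mean,
                                                         masks=masks, stats=stats)
            aux.update(gaussian=G, case_stats=case_stats, gpsa_valid=valid)
            B = G.shape[0]
            g = G.reshape(B, -1)
            Bmat = g[:, :, None] * g[:, None, :]
            bias_term = self.lambda_bias * Tensor(Bmat[:, None, :, :])
            if gate:
                gate_map = G

        tokens = self.tokenize(fv, gate=gate_map)
        tokens, attn = self.transform(tokens, bias_term)
        aux["attention"] = attn
        x = self.untokenize(tokens)
        skips = list(reversed(skips_nc[:-1])) + [xnc]
        logits = self.decode(x, skips)
        return logits, aux

    __call__ = forward

    def predict_mask(self, xnc, xv=None, mode: str = "paired",
                     use_gpsa: bool = False, stats=None) -> np.ndarray:
        """Inference: argmax over class logits -> binary mask (B,H,W)."""
        with no_grad():
            logits, _ = self.forward(xnc, xv, mode=mode, use_gpsa=use_gpsa,
                                     stats=stats)
        return (logits.data[:, 1] > logits.data[:, 0]).astype(np.uint8)

    # -- bookkeeping -----------------------------------------------------
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def describe(self) -> str:
        c = self.config
        lines = [f"input: {c.input_size}x{c.input_size}x1 (per phase)"]
        side = c.input_size
        for i in range(c.encoder_layers):
            side //= 2
            lines.append(f"encoder stage {i + 1}: {side}x{side}x{c.base_channels * 2 ** i}")
        lines.append(f"tokens: {c.n_tokens} x {c.token_dim} "
                     f"({c.transformer_layers} layers, {c.attention_heads} heads)")
        for i in range(c.decoder_stages):
            side *= 2
            lines.append(f"decoder stage {i + 1}: {side}x{side}")
        lines.append(f"head: {c.input_size}x{c.input_size}x{c.num_classes} logits")
        lines.append(f"parameters: {self.parameter_count()}")
        return "\n".join(lines)
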