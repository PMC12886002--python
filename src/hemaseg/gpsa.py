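"""Gaussian position-sensitive attention (GPSA).

Tumor-region intensity statistics (mu, sigma with a 1e-5 stabilizer) are
taken from a feature map under the ground-truth mask; a multi-scale
Gaussian weighting G = mean_k exp(-(I - mu)^2 / (2 (k sigma)^2 + eps)),
k in {0.5, 1.0, 2.0}, scores how tumor-like each location's intensity is.
Flattened into g, the weights enter self-attention as a rank-1 bias
matrix B = g g^T added to the scaled dot-product logits with a learnable
scale (init 0.5). A supervision loss ties attention rows to the binary
token-level tumor target. At inference, when no mask exists, per-case
statistics are replaced by population averages accumulated in training.

All functions here are plain-numpy reference operations; the network
re-creates the biased-attention arithmetic inside its autodiff graph and
is cross-checked against these in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import instrumentation
from .errors import EmptyMaskError, ShapeMismatchError

EPSILON = 1e-5
DEFAULT_SCALES = (0.5, 1.0, 2.0)
LAMBDA_BIAS_INIT = 0.5
_PROB_CLAMP = 1e-7


@dataclass
class GaussianStats:
    """Tumor-region intensity mean/spread, per case or pooled."""

    mu: float
    sigma: float
    epsilon: float = EPSILON
    scales: tuple = DEFAULT_SCALES

    def __post_init__(self):
        if self.sigma < np.sqrt(self.epsilon):
            raise ValueError(f"sigma {self.sigma} below stabilizer floor")
        if any(k <= 0 for k in self.scales):
            raise ValueError("scales must be strictly positive")


@dataclass
class AttentionBias:
    """Flattened Gaussian weights g and the rank-1 bias matrix B = g g^T."""

    g: np.ndarray
    B: np.ndarray
    lambda_bias: float = LAMBDA_BIAS_INIT


def mask_to_grid_fraction(mask: np.ndarray, grid_shape: tuple) -> np.ndarray:
    """Area fraction of tumor per token cell (mask downsampled by block mean).

    Requires the mask shape to be an integer multiple of the token grid.
    """
    mask = np.asarray(mask)
    gh, gw = grid_shape
    H, W = mask.shape
    if gh > H or gw > W:
        raise ShapeMismatchError(f"token grid {grid_shape} larger than mask {mask.shape}")
    if H % gh or W % gw:
        raise ShapeMismatchError(f"mask {mask.shape} not divisible by grid {grid_shape}")
    return mask.astype(float).reshape(gh, H // gh, gw, W // gw).mean(axis=(1, 3))


def mask_to_grid(mask: np.ndarray, grid_shape: tuple) -> np.ndarray:
    """Binary token-level mask: area fraction thresholded at 0.5."""
    return mask_to_grid_fraction(mask, grid_shape) >= 0.5


def tumor_stats(feature_map: np.ndarray, mask: np.ndarray,
                epsilon: float = EPSILON, scales=DEFAULT_SCALES) -> GaussianStats:
    """Mean and stabilized spread of feature intensities inside the mask.

    ``mask`` may be given at the feature-map resolution or at full image
    resolution (it is then pooled to the feature grid, threshold 0.5).
    Raises :class:`EmptyMaskError` when no tumor cell survives -- callers
    should then fall back to population statistics.
    """
    feature_map = np.asarray(feature_map, dtype=float)
    mask = np.asarray(mask)
    if mask.shape != feature_map.shape:
        mask = mask_to_grid(mask, feature_map.shape)
    m = mask.astype(bool)
    if not m.any():
        raise EmptyMaskError(
            "tumor mask empty at the feature grid; use population_stats for inference")
    vals = feature_map[m]
    mu = float(vals.mean())
    sigma = float(np.sqrt(((vals - mu) ** 2).mean() + epsilon))
    return GaussianStats(mu, sigma, epsilon=epsilon, scales=tuple(scales))


def gaussian_map(feature_map: np.ndarray, stats: GaussianStats, k: float) -> np.ndarray:
    """Single-scale Gaussian weight map, values in (0, 1]."""
    if k <= 0:
        raise ValueError("scale k must be positive")
    I = np.asarray(feature_map, dtype=float)
    return np.exp(-((I - stats.mu) ** 2) / (2.0 * (k * stats.sigma) ** 2 + stats.epsilon))


def multiscale_gaussian(feature_map: np.ndarray, stats: GaussianStats) -> np.ndarray:
    """Unweighted mean of the per-scale Gaussian maps."""
    if not stats.scales:
        raise ValueError("empty scale set")
    maps = [gaussian_map(feature_map, stats, k) for k in stats.scales]
    return np.mean(maps, axis=0)


def build_bias(G: np.ndarray, lambda_bias: float = LAMBDA_BIAS_INIT) -> AttentionBias:
    """Row-major flatten of G and the rank-1 outer-product bias matrix."""
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite Gaussian weights")
    instrumentation.record("gpsa.build_bias")
    g = G.reshape(-1)
    return AttentionBias(g=g, B=np.outer(g, g), lambda_bias=lambda_bias)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def biased_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                     bias: AttentionBias | None = None) -> np.ndarray:
    """Scaled dot-product attention with the additive rank-1 Gaussian bias.

    logits = Q K^T / sqrt(d_k) + lambda * B; output = softmax(logits) V.
    Reference (single-head, unbatched) implementation.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[0] != K.shape[0] or K.shape[0] != V.shape[0]:
        raise ShapeMismatchError("Q, K, V must agree in token count")
    if Q.shape[1] != K.shape[1]:
        raise ShapeMismatchError("Q and K must agree in key dimension")
    d_k = Q.shape[1]
    A = Q @ K.T / np.sqrt(d_k)
    if bias is not None:
        if bias.B.shape != A.shape:
            raise ShapeMismatchError(
                f"bias matrix {bias.B.shape} does not match logits {A.shape}")
        A = A + bias.lambda_bias * bias.B
    return _softmax(A, axis=-1) @ V


def attention_supervision_target(mask: np.ndarray, token_grid_shape: tuple) -> np.ndarray:
    """Binary per-token label vector (length N, row-major)."""
    return mask_to_grid(np.asarray(mask), token_grid_shape).astype(float).reshape(-1)


def attention_supervision_loss(A: np.ndarray, target: np.ndarray) -> float:
    """Binary cross-entropy between attention rows and the token target.

    Each query row of ``A`` (N x N logits) is softmaxed into an attended
    mass over tokens, clamped away from {0, 1}, and scored against the
    binary target; the result is the mean over queries and tokens.
    """
    A = np.asarray(A, dtype=float)
    target = np.asarray(target, dtype=float).reshape(-1)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] != target.size:
        raise ShapeMismatchError(f"logits {A.shape} vs target length {target.size}")
    P = np.clip(_softmax(A, axis=-1), _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    bce = -(target * np.log(P) + (1.0 - target) * np.log(1.0 - P))
    return float(bce.mean())


def population_stats(per_case_stats) -> GaussianStats:
    """Plain averages of per-case mu and sigma, stored with the model for
    annotation-free inference."""
    per_case_stats = list(per_case_stats)
    if not per_case_stats:
        raise ValueError("no per-case statistics to pool")
    eps = per_case_stats[0].epsilon
    scales = per_case_stats[0].scales
    return GaussianStats(
        mu=float(np.mean([s.mu for s in per_case_stats])),
        sigma=float(np.mean([s.sigma for s in per_case_stats])),
        epsilon=eps, scales=scales)
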