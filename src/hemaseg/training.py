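"""Losses and the two-phase cross-domain training protocol.

Phase 1 pre-trains the full model on venous-phase images (where lesions
are conspicuous) with the soft Dice loss; the venous-branch encoder
weights are then frozen and transferred, and phase 2 adapts the remaining
modules on paired data with the total loss

    L_total = L_Dice + alpha * L_attention,   alpha = 0.3,

where L_attention is a binary cross-entropy that ties attention rows to
the token-level tumor target. Optimization uses AdamW (lr 3e-4, weight
decay 1e-2) with a cosine-annealed learning rate. During phase 2,
per-case Gaussian statistics are accumulated and pooled into population
statistics stored in the checkpoint sidecar for annotation-free inference.

All randomness (weight init, shuffling, augmentation) is keyed to a
single seed, and every kernel is deterministic, so loss trajectories are
exactly reproducible and the freeze contract can be asserted bitwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gpsa, instrumentation, weem
from .autodiff import Tensor, no_grad
from .errors import ConfigurationError
from .network import CrossPhaseNet, ModelConfig
from .nn import AdamW
from .preprocess import AugmentConfig, apply_affine, hu_clip_normalize

_SMOOTH = 1e-6


@dataclass
class TrainConfig:
    lr_init: float = 3e-4
    epochs: int = 200
    batch_size: int = 8
    weight_decay: float = 1e-2
    supervision_alpha: float = 0.3
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.lr_init <= 0 or self.epochs < 1 or self.supervision_alpha < 0:
            raise ConfigurationError("invalid training configuration")

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """Desk-scale schedule: 20 epochs, batch 4, augmentation off so the
        loss trajectory is a pure function of the seed."""
        kwargs = dict(epochs=20, batch_size=4, augment=None)
        kwargs.update(overrides)
        return cls(**kwargs)


# -- losses --------------------------------------------------------------

def dice_loss(truth_mask, predicted_soft_mask):
    """Soft Dice loss 1 - 2|Y cap Yhat| / (|Y| + |Yhat|), sums over pixels.

    A smoothing constant of 1e-6 in numerator and denominator defines the
    empty-vs-empty case as loss 0. Works on numpy arrays or on autodiff
    tensors (for the training graph); result is in [0, 1].
    """
    t = np.asarray(truth_mask, dtype=float)
    if isinstance(predicted_soft_mask, Tensor):
        p = predicted_soft_mask
        inter = (p * t).sum()
        return 1.0 - (2.0 * inter + _SMOOTH) / (p.sum() + float(t.sum()) + _SMOOTH)
    p = np.asarray(predicted_soft_mask, dtype=float)
    inter = float((p * t).sum())
    return 1.0 - (2.0 * inter + _SMOOTH) / (float(p.sum()) + float(t.sum()) + _SMOOTH)


def total_loss(dice, attention_loss, alpha: float):
    """L_total = L_Dice + alpha * L_attention."""
    if alpha < 0:
        raise ConfigurationError("alpha must be >= 0")
    return dice + alpha * attention_loss


def attention_supervision_loss_t(probs: Tensor, targets: np.ndarray,
                                 sample_mask: np.ndarray) -> Tensor | None:
    """Autodiff version of the attention supervision BCE.

    ``probs``: (B, N, N) attention rows (already softmaxed, head-mean);
    ``targets``: (B, N) binary token labels; ``sample_mask`` selects the
    samples that carry a usable (non-empty) token target.
    """
    idx = np.flatnonzero(sample_mask)
    if idx.size == 0:
        return None
    p = probs[idx].clip(gpsa._PROB_CLAMP, 1.0 - gpsa._PROB_CLAMP)
    y = targets[idx][:, None, :]  # broadcast over queries
    bce = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return bce.mean()


def cosine_lr(step: int, total_steps: int, lr_init: float) -> float:
    """lr_init * (1 + cos(pi * step / total_steps)) / 2."""
    if total_steps <= 0:
        raise ConfigurationError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr_init * (1.0 + np.cos(np.pi * step / total_steps)) / 2.0


# -- data plumbing -------------------------------------------------------

def prepare_case(case, enhancement: weem.EnhancementConfig | None):
    """Normalize both phases to [0, 1] and optionally edge-enhance them."""
    xnc = hu_clip_normalize(case.noncontrast).data
    xv = hu_clip_normalize(case.venous).data
    if enhancement is not None:
        xnc = weem.enhance(xnc, enhancement)
        xv = weem.enhance(xv, enhancement)
    return xnc, xv, case.mask.astype(float)


def _prepare_dataset(cases, enhancement):
    return [prepare_case(c, enhancement) for c in cases]


def _soft_tumor_prob(logits: Tensor) -> Tensor:
    """Softmax over the two class channels; probability of the tumor class."""
    from .autodiff import softmax as _softmax

    p = _softmax(logits.transpose(0, 2, 3, 1), axis=-1)
    return p[:, :, :, 1]


def _epoch_batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _maybe_augment(triplet, aug_cfg, rng):
    xnc, xv, mask = triplet
    if aug_cfg is None or not aug_cfg.enabled:
        return triplet
    angle = rng.uniform(-aug_cfg.rotation_deg, aug_cfg.rotation_deg)
    scale = rng.uniform(*aug_cfg.scale_range)
    flip = bool(rng.random() < aug_cfg.hflip_prob)
    xnc, mask_t = apply_affine(xnc, mask, angle_deg=angle, scale=scale, flip=flip)
    xv, _ = apply_affine(xv, None, angle_deg=angle, scale=scale, flip=flip)
    return xnc, xv, mask_t


# -- training phases -----------------------------------------------------

def _train_loop(model, data, train_config, *, paired: bool, use_gpsa: bool,
                use_attention_loss: bool, rng) -> list:
    params = model.parameters()
    opt = AdamW(params, lr=train_config.lr_init,
                weight_decay=train_config.weight_decay)
    n = len(data)
    steps_per_epoch = int(np.ceil(n / train_config.batch_size))
    total_steps = train_config.epochs * steps_per_epoch
    grid = (model.config.grid_side, model.config.grid_side)
    history, step = [], 0
    for epoch in range(train_config.epochs):
        losses = []
        for idx in _epoch_batches(n, train_config.batch_size, rng):
            batch = [_maybe_augment(data[i], train_config.augment, rng) for i in idx]
            xnc = np.stack([b[0] for b in batch])[:, None]
            xv = np.stack([b[1] for b in batch])[:, None]
            masks = np.stack([b[2] for b in batch])
            lr = cosine_lr(step, total_steps, train_config.lr_init)
            logits, aux = model.forward(
                Tensor(xnc), Tensor(xv) if paired else None,
                mode="paired" if paired else "single",
                use_gpsa=use_gpsa, masks=masks if use_gpsa else None)
            loss = dice_loss(masks, _soft_tumor_prob(logits))
            if use_attention_loss and aux["attention"] is not None:
                targets = np.stack([
                    gpsa.attention_supervision_target(m, grid) for m in masks])
                usable = (targets.sum(axis=1) > 0) & aux["gpsa_valid"]
                att = attention_supervision_loss_t(aux["attention"], targets, usable)
                if att is not None:
                    loss = total_loss(loss, att, train_config.supervision_alpha)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            losses.append(loss.item())
            step += 1
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
    return history


def pretrain_venous(cases, model_config: ModelConfig, train_config: TrainConfig,
                    enhancement: weem.EnhancementConfig | None = None,
                    use_gpsa: bool = False) -> dict:
    """Phase 1: train the full model on venous-phase cases with Dice loss.

    Attention supervision is off in this phase by default. Returns a
    checkpoint dict whose encoder weights are designated transferable.
    """
    if not cases:
        raise ConfigurationError("empty pre-training dataset")
    model = CrossPhaseNet(model_config, seed=train_config.seed)
    rng = np.random.default_rng([train_config.seed, 1])
    data = [(xv, xv, m) for _, xv, m in _prepare_dataset(cases, enhancement)]
    history = _train_loop(model, data, train_config, paired=False,
                          use_gpsa=use_gpsa, use_attention_loss=False, rng=rng)
    return {"state": model.state_dict(), "model_config": model.config,
            "history": history, "phase": "pretrain_venous"}


def transfer_and_freeze(checkpoint: dict, model: CrossPhaseNet) -> CrossPhaseNet:
    """Load pre-trained weights and freeze the venous-branch encoder.

    The whole pre-trained state initializes the model; the venous-branch
    encoder is marked non-trainable (the transfer contract), while the
    non-contrast branch, GPSA scale, transformer and decoder stay
    learnable.
    """
    state = checkpoint["state"]
    expected = {k: v.data.shape for k, v in model.named_parameters()}
    got = {k: np.shape(v) for k, v in state.items()}
    if expected != got:
        raise ConfigurationError("checkpoint architecture does not match model")
    instrumentation.record("training.transfer")
    model.load_state_dict(state)
    model.enc_v.set_trainable(False)
    return model


def train_noncontrast(cases, model: CrossPhaseNet, train_config: TrainConfig,
                      enhancement: weem.EnhancementConfig | None = None,
                      use_gpsa: bool = True, allow_unfrozen: bool = False):
    """Phase 2: adapt the learnable modules on paired cases.

    Refuses to run with an unfrozen venous encoder unless explicitly
    overridden (the ablation path). Returns (checkpoint, sidecar) where the
    sidecar holds the pooled population Gaussian statistics.
    """
    if not cases:
        raise ConfigurationError("empty training dataset")
    enc_v_trainable = any(p.requires_grad for p in model.enc_v.parameters())
    if enc_v_trainable:
        if not allow_unfrozen:
            raise ConfigurationError(
                "venous encoder is trainable; call transfer_and_freeze first "
                "or pass allow_unfrozen=True (ablation mode)")
        warnings.warn("training with an unfrozen venous encoder (ablation mode)",
                      stacklevel=2)
    rng = np.random.default_rng([train_config.seed, 2])
    data = _prepare_dataset(cases, enhancement)
    history = _train_loop(model, data, train_config, paired=True,
                          use_gpsa=use_gpsa, use_attention_loss=use_gpsa, rng=rng)

    sidecar = {"mu_learned": None, "sigma_learned": None, "n_train": len(cases),
               "per_case_mu": [], "per_case_sigma": []}
    if use_gpsa:
        collected = []
        with no_grad():
            for xnc, xv, mask in data:
                _, aux = model.forward(Tensor(xnc[None, None]), Tensor(xv[None, None]),
                                       use_gpsa=True, masks=mask[None])
                collected.extend(aux["case_stats"])
        if collected:
            pooled = gpsa.population_stats(collected)
            sidecar.update(mu_learned=pooled.mu, sigma_learned=pooled.sigma,
                           per_case_mu=[s.mu for s in collected],
                           per_case_sigma=[s.sigma for s in collected])
    checkpoint = {"state": model.state_dict(), "model_config": model.config,
                  "history": history, "phase": "transfer_noncontrast",
                  "sidecar": sidecar}
    return checkpoint, sidecar


# -- end-to-end protocol -------------------------------------------------

class Pipeline:
    """A trained model bundled with its preprocessing and inference mode."""

    def __init__(self, model: CrossPhaseNet, enhancement=None, use_gpsa=True,
                 stats: gpsa.GaussianStats | None = None, mode: str = "paired"):
        self.model = model
        self.enhancement = enhancement
        self.use_gpsa = use_gpsa
        self.stats = stats
        self.mode = mode

    def predict(self, case) -> np.ndarray:
        xnc, xv, _ = prepare_case(case, self.enhancement)
        pred = self.model.predict_mask(
            xnc[None, None], xv[None, None] if self.mode == "paired" else None,
            mode=self.mode, use_gpsa=self.use_gpsa, stats=self.stats)
        return pred[0]


def run_protocol(train_cases, flags=None, seed: int = 0,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 enhancement: weem.EnhancementConfig | None = None) -> Pipeline:
    """Run the full (optionally ablated) protocol and return a Pipeline.

    ``flags``: {"transfer": bool, "gpsa": bool, "weem": bool}; with
    everything off this reduces to a plain CNN-transformer segmentation
    forward with no code path through any of the three components.
    """
    flags = dict({"transfer": True, "gpsa": True, "weem": True}, **(flags or {}))
    model_config = model_config or ModelConfig.tiny()
    train_config = train_config or TrainConfig.tiny(seed=seed)
    enh = (enhancement or weem.EnhancementConfig()) if flags["weem"] else None

    model = CrossPhaseNet(model_config, seed=train_config.seed)
    if flags["transfer"]:
        ckpt = pretrain_venous(train_cases, model_config, train_config,
                               enhancement=enh)
        transfer_and_freeze(ckpt, model)
    with warnings.catch_warnings():
        if not flags["transfer"]:  # the unfrozen path is requested explicitly
            warnings.simplefilter("ignore", UserWarning)
        _, sidecar = train_noncontrast(
            train_cases, model, train_config, enhancement=enh,
            use_gpsa=flags["gpsa"], allow_unfrozen=not flags["transfer"])
    stats = None
    if flags["gpsa"] and sidecar["mu_learned"] is not None:
        stats = gpsa.GaussianStats(sidecar["mu_learned"], sidecar["sigma_learned"])
    return Pipeline(model, enhancement=enh, use_gpsa=flags["gpsa"], stats=stats)


# -- persistence ---------------------------------------------------------

def save_checkpoint(checkpoint: dict, path) -> None:
    """Weights as .npz plus a JSON sidecar (config, stats, version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **checkpoint["state"])
    meta = {
        "version": "1",
        "phase": checkpoint.get("phase"),
        "model_config": vars(checkpoint["model_config"]).copy(),
        "history": checkpoint.get("history", []),
        "sidecar": checkpoint.get("sidecar"),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> dict:
    path = Path(path)
    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    meta = json.loads(Path(str(path) + ".json").read_text())
    return {"state": state, "model_config": ModelConfig(**meta["model_config"]),
            "history": meta.get("history", []), "phase": meta.get("phase"),
            "sidecar": meta.get("sidecar")}
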