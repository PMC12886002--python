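"""CT preprocessing: HU windowing, resampling, training-time augmentation.

The pipeline rule is: intensities are clipped to a liver window (default
[-150, 250] HU) and scaled to [0, 1]; volumes are resampled to a uniform
target spacing with linear interpolation (masks nearest-neighbour, so they
stay binary); random rotation (+-15 deg), isotropic scaling (0.9-1.1) and
horizontal flipping (p = 0.5) are applied during training only, with the
same sampled transform applied to image and mask. Rotation and scale are
combined into a single affine so the image is interpolated once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ShapeMismatchError
from .phantom import CTVolume

DEFAULT_HU_WINDOW = (-150.0, 250.0)


@dataclass
class AugmentConfig:
    rotation_deg: float = 15.0
    scale_range: tuple = (0.9, 1.1)
    hflip_prob: float = 0.5
    enabled: bool = True

    def __post_init__(self):
        if not (self.scale_range[0] < self.scale_range[1]):
            raise ConfigurationError(f"scale_range invalid: {self.scale_range}")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ConfigurationError("hflip_prob must be in [0, 1]")


@dataclass
class PreprocessConfig:
    hu_window: tuple = DEFAULT_HU_WINDOW
    target_spacing_mm: tuple = (0.75, 0.75, 1.5)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if not (self.hu_window[0] < self.hu_window[1]):
            raise ConfigurationError(f"HU window invalid: {self.hu_window}")


def hu_clip_normalize(volume, window=DEFAULT_HU_WINDOW):
    """Clip to the HU window and scale linearly to [0, 1].

    Accepts a :class:`CTVolume` (returns one) or a bare array.
    """
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise ConfigurationError(f"degenerate HU window: {window}")
    if isinstance(volume, CTVolume):
        out = (np.clip(volume.data, low, high) - low) / (high - low)
        return CTVolume(out, volume.spacing, volume.phase)
    return (np.clip(np.asarray(volume, dtype=float), low, high) - low) / (high - low)


def resample(volume: CTVolume, target_spacing, is_mask: bool = False) -> CTVolume:
    """Resample to ``target_spacing`` (mm per axis).

    Output shape is round(shape * spacing / target); images use linear
    interpolation, masks nearest-neighbour.
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (volume.data.ndim,):
        raise ConfigurationError("target spacing length must match dimensionality")
    if np.any(target <= 0):
        raise ConfigurationError(f"non-positive target spacing: {target.tolist()}")
    src = np.asarray(volume.spacing, dtype=float)
    out_shape = np.maximum(1, np.round(np.asarray(volume.data.shape) * src / target)).astype(int)
    grids = np.meshgrid(*[np.arange(n) * t / s for n, t, s in zip(out_shape, target, src)],
                        indexing="ij")
    out = ndimage.map_coordinates(volume.data, np.stack(grids),
                                  order=0 if is_mask else 1, mode="nearest")
    return CTVolume(out, tuple(target), volume.phase)


def apply_affine(image: np.ndarray, mask, angle_deg: float = 0.0,
                 scale: float = 1.0, flip: bool = False):
    """Apply one rotation+scale affine about the centre, then an optional
    left-right flip, identically to image (linear) and mask (nearest)."""
    image = np.asarray(image, dtype=float)
    if mask is not None and np.shape(mask) != image.shape:
        raise ShapeMismatchError("image and mask must be aligned")
    theta = math.radians(angle_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    matrix = rot.T / scale  # output -> input mapping
    center = (np.asarray(image.shape, dtype=float) - 1) / 2.0
    offset = center - matrix @ center

    def _one(arr, order):
        out = ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                       mode="nearest")
        return out[:, ::-1].copy() if flip else out

    img_out = _one(image, order=1)
    if mask is None:
        return img_out, None
    mask_out = _one(np.asarray(mask, dtype=float), order=0)
    return img_out, mask_out.astype(np.asarray(mask).dtype)


def augment(image, mask, config: AugmentConfig, rng) -> tuple:
    """Sample one transform and apply it to the (image, mask) pair.

    With augmentation disabled the pair is returned bit-identical.
    """
    if config is None or not config.enabled:
        return image, mask
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    scale = rng.uniform(*config.scale_range)
    flip = bool(rng.random() < config.hflip_prob)
    return apply_affine(image, mask, angle_deg=angle, scale=scale, flip=flip)
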