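"""Slice-level augmentation.

Training draws: resize to the model input size, random horizontal flip
(p=0.5), random rotation (±15°), random affine translation (±5% of the
side) and scaling (95–105%), then intensity normalization to [0, 1].
Evaluation applies resizing and normalization only.

Normalization maps the fixed [0, 1000] intensity scale linearly onto
``normalize_range`` (default [0, 1]); inputs already inside the target
range pass through untouched, so the eval pipeline is idempotent and
absolute intensity relations between ROI variants are preserved (a
per-image min-max would re-stretch each crop's contrast and distort the
comparison between masked and unmasked variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from .errors import ConfigurationError

__all__ = ["AugmentParams", "draw_augment_params", "augment_slice"]

INTENSITY_SCALE = 1000.0


@dataclass(frozen=True)
class AugmentParams:
    target_size: int = 64
    hflip_prob: float = 0.5
    rotation_deg: float = 15.0
    translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.95, 1.05)
    normalize_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.target_size < 8:
            raise ConfigurationError("target_size must be >= 8")
        if not (0.0 <= self.hflip_prob <= 1.0):
            raise ConfigurationError("hflip_prob must be a probability")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ConfigurationError("scale_range must be an increasing positive interval")


def draw_augment_params(params: AugmentParams, rng: np.random.Generator) -> dict[str, float]:
    """Draw one set of stochastic transform parameters."""
    return {
        "flip": float(rng.random() < params.hflip_prob),
        "angle_deg": float(rng.uniform(-params.rotation_deg, params.rotation_deg)),
        "tx_frac": float(rng.uniform(-params.translate_frac, params.translate_frac)),
        "ty_frac": float(rng.uniform(-params.translate_frac, params.translate_frac)),
        "scale": float(rng.uniform(*params.scale_range)),
    }


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape == (size, size):
        return image.astype(np.float64, copy=False)
    return sktransform.resize(
        image.astype(np.float64), (size, size), order=1, mode="constant", anti_aliasing=True
    )


def _normalize(image: np.ndarray, normalize_range: tuple[float, float]) -> np.ndarray:
    lo, hi = normalize_range
    if image.min() >= lo and image.max() <= hi:
        return image  # already conforming: identity
    unit = np.clip(image / INTENSITY_SCALE, 0.0, 1.0)
    return lo + unit * (hi - lo)


def augment_slice(
    image: np.ndarray,
    params: AugmentParams,
    mode: str = "train",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Apply the augmentation pipeline to one 2D slice.

    ``mode="eval"`` applies resize + normalize only (deterministic);
    ``mode="train"`` additionally applies flip/rotation/affine draws from
    ``rng`` (an integer seed or a Generator).
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ConfigurationError("image contains non-finite values")
    if mode not in ("train", "eval"):
        raise ConfigurationError(f"unknown augmentation mode {mode!r}")
    out = _resize(image, params.target_size)
    if mode == "train":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        draw = draw_augment_params(params, rng)
        if draw["flip"]:
            out = out[:, ::-1]
        if (
            draw["angle_deg"] == 0.0
            and draw["tx_frac"] == 0.0
            and draw["ty_frac"] == 0.0
            and draw["scale"] == 1.0
        ):
            return _normalize(out, params.normalize_range)
        size = params.target_size
        center = (size - 1) / 2.0
        shift = sktransform.AffineTransform(translation=(-center, -center))
        core = sktransform.AffineTransform(
            rotation=np.deg2rad(draw["angle_deg"]),
            scale=(draw["scale"], draw["scale"]),
            translation=(draw["tx_frac"] * size, draw["ty_frac"] * size),
        )
        unshift = sktransform.AffineTransform(translation=(center, center))
        tform = shift + core + unshift
        out = sktransform.warp(out, tform.inverse, order=1, mode="constant", cval=0.0)
    return _normalize(out, params.normalize_range)
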