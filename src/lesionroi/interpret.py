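"""Interpretability: Grad-CAM attention maps and confidence-curve analysis.

Grad-CAM weights each channel of the designated convolutional feature
layer by the spatial mean of the target-class score gradient, rectifies
the weighted sum, min-max normalizes to [0, 1] and upsamples bilinearly
to the model input size.

A confidence curve is the ordered sequence of a patient's slice-level
predicted probabilities; its population standard deviation measures
diagnostic consistency. A case is flagged low-confidence when the SD is
large or the mean hugs the 0.5 decision line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import transform as sktransform

from .errors import DegenerateInputError

__all__ = ["Heatmap", "ConfidenceCurve", "cam_from_activations", "grad_cam", "confidence_curve"]


@dataclass
class Heatmap:
    values: np.ndarray  # 2D in [0, 1], upsampled to input size
    layer: str
    target_class: int


@dataclass
class ConfidenceCurve:
    patient_id: str
    probabilities: np.ndarray  # sequential slice order
    mean: float
    sd: float  # population SD over the patient's slices
    flag: str  # "high" | "low"


def cam_from_activations(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Core Grad-CAM map (un-upsampled) from (C, h, w) activations/gradients.

    Channel weights are the spatially averaged gradients; the map is the
    rectified weighted sum, min-max normalized to [0, 1]. An identically
    zero rectified map stays zero (no division-by-zero).
    """
    if activations.shape != gradients.shape:
        raise DegenerateInputError("activations and gradients must share a shape")
    weights = gradients.mean(axis=(1, 2))
    cam = np.tensordot(weights, activations, axes=([0], [0]))
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam


def grad_cam(backend, image: np.ndarray, target_class: int = 1) -> Heatmap:
    """Grad-CAM attention map for one slice on a trained backend.

    The backend must expose ``activations_and_gradients(image, target)``
    returning the feature-layer activations, the gradients of the
    target-class score, and the preprocessed input (whose size the map is
    upsampled to).
    """
    activations, gradients, x = backend.activations_and_gradients(image, target_class)
    cam = cam_from_activations(activations, gradients)
    up = sktransform.resize(cam, x.shape, order=1, mode="edge", anti_aliasing=False)
    peak = up.max()
    if peak > 0:
        up = up / peak
    return Heatmap(values=np.clip(up, 0.0, 1.0), layer=backend.feature_layer_, target_class=int(target_class))


def confidence_curve(
    slice_probs: Sequence[float],
    sd_threshold: float = 0.15,
    mean_band: float = 0.10,
    patient_id: str = "",
) -> ConfidenceCurve:
    """Summarize a patient's slice probabilities into a confidence pattern.

    Low-confidence iff the population SD exceeds ``sd_threshold`` OR the
    mean probability lies within ``mean_band`` of the 0.5 decision line.
    """
    probs = np.asarray(slice_probs, dtype=float)
    if probs.size == 0:
        raise DegenerateInputError("empty probability sequence")
    mean = float(probs.mean())
    sd = float(probs.std(ddof=0))
    low = sd > sd_threshold or abs(mean - 0.5) <= mean_band
    return ConfidenceCurve(
        patient_id=patient_id,
        probabilities=probs,
        mean=mean,
        sd=sd,
        flag="low" if low else "high",
    )


def heatmap_mass_in_band(heatmap: Heatmap, band_mask: np.ndarray) -> float:
    """Fraction of total heatmap mass inside a binary region of interest."""
    total = float(heatmap.values.sum())
    if total == 0:
        return 0.0
    if band_mask.shape != heatmap.values.shape:
        band_mask = sktransform.resize(band_mask.astype(float), heatmap.values.shape, order=0) > 0.5
    return float(heatmap.values[band_mask].sum() / total)


def save_heatmap_overlay(image: np.ndarray, heatmap: Heatmap, path: str | Path) -> None:
    """Write a PNG of the slice with the attention map overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray")
    hm = heatmap.values
    if hm.shape != image.shape:
        hm = sktransform.resize(hm, image.shape, order=1)
    ax.imshow(hm, cmap="jet", alpha=0.4, vmin=0, vmax=1)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def save_confidence_plot(curves: Sequence[ConfidenceCurve], path: str | Path) -> None:
    """Plot per-patient probability trajectories against the 0.5 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.probabilities, marker="o", label=f"{curve.patient_id} ({curve.flag})")
    ax.axhline(0.5, color="red", linestyle="--", linewidth=1)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("slice (sequential order)")
    ax.set_ylabel("P(AME)")
    if len(curves) <= 10:
        ax.legend(fontsize=7)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
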