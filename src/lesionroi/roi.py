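"""Segmentation-guided ROI extraction.

Implements the three-step preprocessing workflow and the four model-input
variants compared by the pipeline:

``original``
    the untouched axial slice;
``bbox``
    a square crop centered on the lesion bounding box, side enlarged by a
    configurable fraction (default 20%);
``precise``
    the same crop with every pixel outside the lesion mask zeroed;
``expanded``
    the crop masked with a morphologically dilated lesion mask, retaining
    a band of peri-lesional tissue (the bone-lesion interface).

Slice selection keeps only axial slices whose lesion area exceeds a
fraction of the patient's maximum lesion area (default: strictly greater
than 50%), then subsamples every ``stride``-th retained slice.

Everything here is deterministic, purely geometric, and 0-based; axial
slices run along axis 0 of the stored arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cohort import LesionMask, VolumeRecord
from .errors import AlignmentError, ConfigurationError, DegenerateInputError

__all__ = [
    "ROI_VARIANTS",
    "SliceSelection",
    "SliceSample",
    "select_slices",
    "bbox_square_roi",
    "mask_out",
    "dilate_mask",
    "make_input",
    "extract_patient_samples",
]

#: Closed enumeration of input variants.
ROI_VARIANTS = ("original", "bbox", "precise", "expanded")


def _check_variant(variant: str) -> None:
    if variant not in ROI_VARIANTS:
        raise ConfigurationError(f"unknown ROI variant {variant!r}; expected one of {ROI_VARIANTS}")


@dataclass(frozen=True)
class SliceSelection:
    """Axial slices retained for one patient."""

    patient_id: str
    slice_indices: tuple[int, ...]
    max_area_vox: int
    area_fraction: float
    stride: int


@dataclass
class SliceSample:
    """One 2D model input: a slice rendered under a given ROI variant."""

    patient_id: str
    slice_index: int
    variant: str
    image: np.ndarray
    label: int


def select_slices(mask: LesionMask, area_fraction: float = 0.5, stride: int = 5) -> SliceSelection:
    """Select axial slices by per-slice lesion area.

    A slice survives iff its lesion area is strictly greater than
    ``area_fraction`` times the maximum per-slice area; the ``stride`` is
    then applied to the ordered retained list, anchored at its first
    element. The maximum-area slice always survives.
    """
    if not (0.0 < area_fraction <= 1.0):
        raise ConfigurationError("area_fraction must lie in (0, 1]")
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    areas = np.count_nonzero(mask.mask.reshape(mask.mask.shape[0], -1), axis=1)
    max_area = int(areas.max(initial=0))
    if max_area == 0:
        raise DegenerateInputError("lesion mask is empty; cannot select slices")
    retained = np.flatnonzero(areas > area_fraction * max_area)
    chosen = tuple(int(i) for i in retained[::stride])
    return SliceSelection(
        patient_id=mask.patient_id,
        slice_indices=chosen,
        max_area_vox=max_area,
        area_fraction=area_fraction,
        stride=stride,
    )


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def _square_window(mask: np.ndarray, expand: float) -> tuple[int, int, int]:
    """(row_start, col_start, side) of the mask-centered square crop window."""
    r0, r1, c0, c1 = _bbox(mask)
    h, w = r1 - r0 + 1, c1 - c0 + 1
    side = int(math.ceil((1.0 + expand) * max(h, w)))
    cr, cc = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    rs = int(round(cr - (side - 1) / 2.0))
    cs = int(round(cc - (side - 1) / 2.0))
    return rs, cs, side


def _crop_padded(image: np.ndarray, rs: int, cs: int, side: int) -> np.ndarray:
    """Extract a ``side x side`` window; out-of-bounds regions are zero."""
    out = np.zeros((side, side), dtype=image.dtype)
    r_lo, r_hi = max(rs, 0), min(rs + side, image.shape[0])
    c_lo, c_hi = max(cs, 0), min(cs + side, image.shape[1])
    if r_lo < r_hi and c_lo < c_hi:
        out[r_lo - rs : r_hi - rs, c_lo - cs : c_hi - cs] = image[r_lo:r_hi, c_lo:c_hi]
    return out


def bbox_square_roi(image: np.ndarray, mask: np.ndarray, expand: float = 0.20) -> np.ndarray:
    """Step 1: crop a mask-centered square, side enlarged by ``expand``.

    The square side is ``ceil((1 + expand) * max(bbox_height, bbox_width))``,
    centered on the bounding-box center; regions falling outside the image
    are zero-padded so the lesion stays centered.
    """
    if expand < 0:
        raise ConfigurationError("expand must be >= 0")
    if image.shape != mask.shape:
        raise AlignmentError(f"image {image.shape} and mask {mask.shape} differ")
    if not np.any(mask):
        raise DegenerateInputError("empty mask: no bounding box")
    rs, cs, side = _square_window(np.asarray(mask) > 0, expand)
    return _crop_padded(np.asarray(image), rs, cs, side)


def mask_out(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Step 2: zero every pixel outside the (binarized) mask."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise AlignmentError(f"image {image.shape} and mask {mask.shape} differ")
    return image * (mask > 0).astype(image.dtype)


def dilate_mask(mask: np.ndarray, margin_mm: float, spacing_mm: float) -> np.ndarray:
    """Step 3: binary dilation by a disk of radius ``round(margin_mm / spacing)``.

    The structuring element is the digital Euclidean disk, so a dilated mask
    is always a pixelwise superset of the input.
    """
    if margin_mm < 0:
        raise ConfigurationError("margin_mm must be >= 0")
    mask = np.asarray(mask) > 0
    radius = int(round(margin_mm / float(spacing_mm)))
    if radius == 0:
        return mask.copy()
    extent = np.arange(-radius, radius + 1)
    footprint = (extent[:, None] ** 2 + extent[None, :] ** 2) <= radius**2
    return ndimage.binary_dilation(mask, structure=footprint)


def make_input(
    image_slice: np.ndarray,
    mask_slice: np.ndarray,
    variant: str,
    expand: float = 0.20,
    margin_mm: float = 3.0,
    spacing_mm: float = 0.5,
) -> np.ndarray:
    """Render one slice under the requested ROI variant.

    ``expanded`` computes the crop window from the *dilated* mask's bounding
    box so the peri-lesional margin is never clipped by the crop itself.
    """
    _check_variant(variant)
    image_slice = np.asarray(image_slice)
    mask_slice = np.asarray(mask_slice)
    if variant == "original":
        return image_slice.copy()
    if image_slice.shape != mask_slice.shape:
        raise AlignmentError(f"slice {image_slice.shape} and mask {mask_slice.shape} differ")
    if variant == "bbox":
        return bbox_square_roi(image_slice, mask_slice, expand)
    if variant == "precise":
        crop = bbox_square_roi(image_slice, mask_slice, expand)
        mcrop = bbox_square_roi(mask_slice.astype(np.uint8), mask_slice, expand)
        return mask_out(crop, mcrop)
    # expanded
    dilated = dilate_mask(mask_slice, margin_mm, spacing_mm)
    crop = bbox_square_roi(image_slice, dilated, expand)
    mcrop = bbox_square_roi(dilated.astype(np.uint8), dilated, expand)
    return mask_out(crop, mcrop)


def extract_patient_samples(
    record: VolumeRecord,
    lesion: LesionMask,
    variant: str,
    area_fraction: float = 0.5,
    stride: int = 5,
    expand: float = 0.20,
    margin_mm: float = 3.0,
    selection: SliceSelection | None = None,
) -> list[SliceSample]:
    """Select slices for one patient and render them under ``variant``.

    Pass a precomputed ``selection`` to guarantee all variants of a study
    share the identical slice set.
    """
    _check_variant(variant)
    if record.volume.shape != lesion.mask.shape:
        raise AlignmentError("volume and mask shapes differ")
    if selection is None:
        selection = select_slices(lesion, area_fraction=area_fraction, stride=stride)
    in_plane = float(np.mean(record.spacing_mm[1:]))
    samples = []
    for idx in selection.slice_indices:
        img = make_input(
            record.volume[idx],
            lesion.mask[idx],
            variant,
            expand=expand,
            margin_mm=margin_mm,
            spacing_mm=in_plane,
        )
        samples.append(
            SliceSample(
                patient_id=record.patient_id,
                slice_index=int(idx),
                variant=variant,
                image=img,
                label=record.label,
            )
        )
    return samples
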