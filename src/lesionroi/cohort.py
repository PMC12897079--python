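"""Synthetic phantom cohort generator.

Produces 3D grayscale volumes with voxel-aligned binary lesion masks that
mimic the statistical structure of a two-class jaw-lesion cohort
(ameloblastoma-like, label 1, vs. odontogenic-keratocyst-like, label 0):

* class 1 lesions are preferentially **multilocular** — several merged
  ellipsoidal locules separated by thin high-intensity septal walls;
* class 0 lesions are preferentially **unilocular** with smooth margins;
* a corticated (bright) rim is rendered just outside the lesion boundary
  when cortical integrity is "intact"; "disrupted" lesions lose a sector
  of the rim, so rim smoothness carries class signal at the margin;
* 2–4 bright distractor ellipsoids (spine/airway analogues) are placed
  well away from the lesion in every volume, regardless of class, so the
  background distribution is label-independent by construction.

All class-discriminative signal therefore lives in the lesion and its
immediate interface, never in the background — which is exactly what a
segmentation-guided region-of-interest pipeline is supposed to exploit.

Intensities are arbitrary units on a CT-like [0, 1000] scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "VolumeRecord",
    "LesionMask",
    "draw_features",
    "generate_lesion_volume",
    "generate_cohort",
    "write_cohort",
]

#: Default per-class probabilities of the three discriminative features.
#: Multilocularity and cortical disruption follow the frequencies reported
#: for surgical AME/OKC cohorts (~77%/28% multilocular, ~28%/52% disrupted);
#: septa accompany multilocular growth.
DEFAULT_CLASS_FEATURE_PROBS: dict[int, dict[str, float]] = {
    1: {"multilocular": 0.766, "cortical_disruption": 0.281, "septa_present": 0.766},
    0: {"multilocular": 0.281, "cortical_disruption": 0.516, "septa_present": 0.281},
}

FEATURE_NAMES = ("multilocular", "cortical_disruption", "septa_present")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the phantom cohort.

    Intensities are arbitrary units in [0, 1000]; geometry is metric (mm)
    and converted to voxels through ``spacing_mm``.
    """

    n_patients: int = 128
    class_ratio: float = 0.5
    volume_shape: tuple[int, int, int] = (64, 160, 160)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    class_feature_probs: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_FEATURE_PROBS.items()}
    )
    lesion_radius_mm: tuple[float, float] = (6.0, 15.0)
    background_intensity: float = 150.0
    lumen_intensity: float = 60.0
    septum_intensity: float = 650.0
    rim_intensity: float = 750.0
    distractor_intensity: float = 500.0
    n_distractors: tuple[int, int] = (2, 4)
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not (0.0 < self.class_ratio < 1.0):
            raise ConfigurationError("class_ratio must lie strictly in (0, 1)")
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must be three axes of >= 8 voxels")
        if len(self.spacing_mm) != 3 or any(not (0.1 <= s <= 1.0) for s in self.spacing_mm):
            raise ConfigurationError("spacing_mm must be in [0.1, 1.0] mm per axis")
        for label in (0, 1):
            probs = self.class_feature_probs.get(label)
            if probs is None:
                raise ConfigurationError(f"class_feature_probs missing class {label}")
            for name in FEATURE_NAMES:
                p = probs.get(name)
                if p is None or not (0.0 <= p <= 1.0):
                    raise ConfigurationError(f"probability {name!r} for class {label} not in [0, 1]")
        if self.lesion_radius_mm[0] <= 0 or self.lesion_radius_mm[1] < self.lesion_radius_mm[0]:
            raise ConfigurationError("lesion_radius_mm must be an increasing positive range")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class VolumeRecord:
    """One patient's intensity volume plus metadata."""

    patient_id: str
    label: int
    volume: np.ndarray  # (z, y, x) float32, axial slices along axis 0
    spacing_mm: tuple[float, float, float]
    features: dict[str, bool] = field(default_factory=dict)


@dataclass
class LesionMask:
    """Binary lesion mask aligned voxel-for-voxel with its volume."""

    patient_id: str
    mask: np.ndarray  # (z, y, x) bool


def draw_features(label: int, config: CohortConfig, rng: np.random.Generator) -> dict[str, bool]:
    """Draw the three discriminative feature flags for one lesion."""
    probs = config.class_feature_probs[label]
    return {name: bool(rng.random() < probs[name]) for name in FEATURE_NAMES}


def _ellipsoid_box(
    shape: Sequence[int], center: np.ndarray, semi: np.ndarray, pad: float
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Local bounding box of an ellipsoid and the normalized quadratic form
    ``q(x) = sum(((x - c) / a)^2)`` evaluated inside it (q <= 1 is interior)."""
    lo = np.maximum(np.floor(center - semi * pad).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi * pad).astype(int) + 1, np.asarray(shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.ogrid[sl]
    q = np.zeros(tuple(int(b - a) for a, b in zip(lo, hi)), dtype=np.float32)
    for g, c, a in zip(grids, center, semi):
        q = q + (((g - c) / a) ** 2).astype(np.float32)
    return sl, q


def generate_lesion_volume(
    label: int,
    config: CohortConfig,
    seed: int,
    patient_id: str = "synthetic",
) -> tuple[VolumeRecord, LesionMask]:
    """Render one phantom volume/mask pair.

    Deterministic in ``(label, config, seed)``. The lesion is a union of
    overlapping ellipsoidal locules (one if unilocular), guaranteed to form
    a single connected component; septa are thin walls at locule junctions,
    the corticated rim a band just outside the mask.
    """
    if label not in (0, 1):
        raise ConfigurationError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = np.asarray(config.volume_shape)
    spacing = np.asarray(config.spacing_mm, dtype=float)

    features = draw_features(label, config, rng)

    radius_mm = rng.uniform(*config.lesion_radius_mm)
    radius_vox = radius_mm / spacing  # per-axis equivalent radius

    # keep lesion + rim + a little slack inside the volume
    margin = radius_vox * 1.35 + 2.0
    lo = margin
    hi = shape - 1 - margin
    center = np.where(hi > lo, rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi)), shape / 2.0)

    # --- locules ---------------------------------------------------------
    n_locules = int(rng.integers(2, 5)) if features["multilocular"] else 1
    locules: list[tuple[np.ndarray, np.ndarray]] = []
    main_semi = radius_vox * rng.uniform(0.85, 1.15, size=3)
    locules.append((center.copy(), main_semi))
    for _ in range(n_locules - 1):
        base_c, base_s = locules[int(rng.integers(len(locules)))]
        semi = main_semi * rng.uniform(0.45, 0.75, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # center offset < sum of semi-axes along the offset direction -> overlap
        dist = 0.6 * (np.abs(direction) @ (base_s + semi)) / max(np.abs(direction).sum(), 1e-9)
        c = base_c + direction * dist
        c = np.clip(c, semi * 1.2 + 1, shape - 1 - semi * 1.2 - 1)
        locules.append((c, semi))

    mask = np.zeros(config.volume_shape, dtype=bool)
    boxes = []
    for c, s in locules:
        sl, q = _ellipsoid_box(config.volume_shape, c, s, pad=1.45)
        boxes.append((sl, q))
        mask[sl] |= q <= 1.0

    # enforce single connected component (overlap construction makes
    # disconnection rare; discretization at small radii can still split)
    labeled, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))

    volume = np.full(config.volume_shape, config.background_intensity, dtype=np.float32)
    volume[mask] = config.lumen_intensity

    # --- septal walls at locule junctions --------------------------------
    if features["septa_present"] and n_locules > 1:
        full_q = np.full(config.volume_shape, np.inf, dtype=np.float32)
        count_in = np.zeros(config.volume_shape, dtype=np.int8)
        for sl, q in boxes:
            count_in[sl] += q <= 1.0
            np.minimum(full_q[sl], q, out=full_q[sl])
        # shell of the overlap lens: inside >= 2 locules, near the surface
        near_max = np.zeros(config.volume_shape, dtype=np.float32)
        for sl, q in boxes:
            inside = q <= 1.0
            np.maximum(near_max[sl], np.where(inside, q, 0.0), out=near_max[sl])
        septum = mask & (count_in >= 2) & (near_max >= 0.7)
        volume[septum] = config.septum_intensity

    # --- corticated rim ---------------------------------------------------
    min_q = np.full(config.volume_shape, np.inf, dtype=np.float32)
    for sl, q in boxes:
        np.minimum(min_q[sl], q, out=min_q[sl])
    rim = (~mask) & (min_q > 1.0) & (min_q <= 1.35)
    if features["cortical_disruption"]:
        # remove a random solid-angle sector: the margin loses its smooth rim
        zz, yy, xx = np.nonzero(rim)
        if zz.size:
            vec = np.stack([yy - center[1], xx - center[2]], axis=0).astype(float)
            ang = np.arctan2(vec[0], vec[1])
            gap_center = rng.uniform(-math.pi, math.pi)
            gap_half = rng.uniform(0.6, 1.2)  # 69-137 degree sector
            d = np.angle(np.exp(1j * (ang - gap_center)))
            keep = np.abs(d) > gap_half
            rim_kept = (zz[keep], yy[keep], xx[keep])
            volume[rim_kept] = 0.65 * config.rim_intensity
        # dropped sector stays at background: disrupted cortex
    else:
        volume[rim] = config.rim_intensity

    # --- distractors (label-independent background structures) ------------
    n_dist = int(rng.integers(config.n_distractors[0], config.n_distractors[1] + 1))
    min_dist_mm = 2.0 * radius_mm  # two lesion-radii from the lesion centroid
    placed = 0
    attempts = 0
    while placed < n_dist and attempts < 400:
        attempts += 1
        if attempts > 200:
            # very large lesions leave little room at 2 radii; fall back to
            # "outside the rim band" so every volume still has distractors
            min_dist_mm = 1.2 * radius_mm
        semi = rng.uniform(2.0, 6.0) / spacing * rng.uniform(0.6, 1.4, size=3)
        if np.any(semi + 2 >= shape - semi - 2):
            break
        c = rng.uniform(semi + 1, shape - 1 - semi - 1)
        if np.linalg.norm((c - center) * spacing) < min_dist_mm:
            continue
        sl, q = _ellipsoid_box(config.volume_shape, c, semi, pad=1.05)
        inside = q <= 1.0
        if np.any(mask[sl] & inside) or np.any((min_q[sl] <= 1.35) & inside):
            continue
        volume[sl][inside] = config.distractor_intensity
        placed += 1

    if config.noise_sd > 0:
        volume += rng.normal(0.0, config.noise_sd, size=volume.shape).astype(np.float32)
    np.clip(volume, 0.0, 1000.0, out=volume)

    record = VolumeRecord(
        patient_id=patient_id,
        label=label,
        volume=volume,
        spacing_mm=tuple(float(s) for s in config.spacing_mm),
        features=features,
    )
    return record, LesionMask(patient_id=patient_id, mask=mask)


def _patient_seeds(config: CohortConfig, n: int) -> list[int]:
    ss = np.random.SeedSequence(config.seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def cohort_labels(config: CohortConfig) -> list[int]:
    """Deterministic label sequence: class-1 count = round(n * ratio)."""
    n1 = int(round(config.n_patients * config.class_ratio))
    n1 = min(max(n1, 1), config.n_patients - 1)
    labels = [1] * n1 + [0] * (config.n_patients - n1)
    return labels


def generate_cohort(config: CohortConfig) -> list[tuple[VolumeRecord, LesionMask]]:
    """Generate the full phantom cohort, deterministically in ``config``."""
    labels = cohort_labels(config)
    seeds = _patient_seeds(config, config.n_patients)
    out = []
    for i, (label, seed) in enumerate(zip(labels, seeds)):
        pid = f"P{i:03d}"
        out.append(generate_lesion_volume(label, config, seed, patient_id=pid))
    return out


def iter_cohort(config: CohortConfig) -> Iterator[tuple[VolumeRecord, LesionMask]]:
    """Memory-light variant of :func:`generate_cohort`."""
    labels = cohort_labels(config)
    seeds = _patient_seeds(config, config.n_patients)
    for i, (label, seed) in enumerate(zip(labels, seeds)):
        yield generate_lesion_volume(label, config, seed, patient_id=f"P{i:03d}")


def write_cohort(pairs: Sequence[tuple[VolumeRecord, LesionMask]], outdir: str | Path) -> Path:
    """Write ``<pid>_img.nii.gz`` / ``<pid>_mask.nii.gz`` pairs + ``cohort.csv``."""
    import nibabel as nib
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, lesion in pairs:
        affine = np.diag(list(rec.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(rec.volume.astype(np.float32), affine), outdir / f"{rec.patient_id}_img.nii.gz")
        nib.save(
            nib.Nifti1Image(lesion.mask.astype(np.uint8), affine),
            outdir / f"{rec.patient_id}_mask.nii.gz",
        )
        rows.append({"patient_id": rec.patient_id, "label": rec.label, **rec.features})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "cohort.csv", index=False)
    return outdir
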