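"""Experiment orchestration.

One call trains and evaluates all ROI input variants of the comparative
study over the *same* slice selections, the *same* patient-level fold
partition and the *same* training seeds, so that variant differences are
attributable to the input representation alone. Emits per-fold metrics,
fold aggregates (mean +/- SD), pairwise DeLong p-value matrices at the
slice and patient level, per-patient confidence summaries, and a
provenance block sufficient to regenerate the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .augment import AugmentParams
from .backend import SliceCNNClassifier
from .cohort import CohortConfig, LesionMask, VolumeRecord, generate_cohort
from .errors import AlignmentError, ConfigurationError
from .evaluation import (
    CrossValResult,
    aggregate_fold_metrics,
    cross_validate,
    delong_test,
    partition_patients,
)
from .interpret import confidence_curve
from .roi import ROI_VARIANTS, extract_patient_samples, select_slices
from .schedule import LrSchedule

logger = logging.getLogger("lesionroi")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "read_volume_pair", "load_cohort"]


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    dataset_path: str | None = None  # load NIfTI cohort instead of generating
    variants: tuple[str, ...] = ROI_VARIANTS
    area_fraction: float = 0.5
    stride: int = 5
    expand: float = 0.20
    margin_mm: float = 3.0
    k: int = 5
    seed_partition: int = 0
    seed_training: int = 0
    schedule: LrSchedule = field(default_factory=LrSchedule)
    augment: AugmentParams = field(default_factory=AugmentParams)
    backend_params: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in ROI_VARIANTS:
                raise ConfigurationError(f"unknown variant {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            c = dict(kwargs["cohort"])
            for tup in ("volume_shape", "spacing_mm", "lesion_radius_mm", "n_distractors"):
                if tup in c:
                    c[tup] = tuple(c[tup])
            if "class_feature_probs" in c:
                c["class_feature_probs"] = {int(k): dict(v) for k, v in c["class_feature_probs"].items()}
            kwargs["cohort"] = CohortConfig(**c)
        if "schedule" in kwargs and isinstance(kwargs["schedule"], dict):
            kwargs["schedule"] = LrSchedule(**kwargs["schedule"])
        if "augment" in kwargs and isinstance(kwargs["augment"], dict):
            a = dict(kwargs["augment"])
            for tup in ("scale_range", "normalize_range"):
                if tup in a:
                    a[tup] = tuple(a[tup])
            kwargs["augment"] = AugmentParams(**a)
        if "variants" in kwargs:
            kwargs["variants"] = tuple(kwargs["variants"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            return obj

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class ExperimentReport:
    config: dict
    results: dict[str, CrossValResult]
    per_fold: pd.DataFrame
    aggregates: pd.DataFrame
    delong_slice: pd.DataFrame  # symmetric p-value matrix, unit diagonal
    delong_patient: pd.DataFrame
    confidence: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_fold.to_csv(outdir / "metrics_per_fold.csv", index=False)
        self.aggregates.to_csv(outdir / "metrics_aggregate.csv", index=False)
        self.delong_slice.to_csv(outdir / "delong_slice.csv")
        self.delong_patient.to_csv(outdir / "delong_patient.csv")
        self.confidence.to_csv(outdir / "confidence_summary.csv", index=False)
        for variant, res in self.results.items():
            res.predictions.to_csv(outdir / f"predictions_slice_{variant}.csv", index=False)
            res.patient_predictions().to_csv(outdir / f"predictions_patient_{variant}.csv", index=False)
            _roc_points(res).to_csv(outdir / f"roc_points_{variant}.csv", index=False)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump({"config": self.config, **self.provenance}, fh, indent=2, sort_keys=True)
        return outdir


def _roc_points(res: CrossValResult) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    frames = []
    for level, df in (("slice", res.predictions), ("patient", res.patient_predictions())):
        fpr, tpr, thr = roc_curve(df["label"], df["prob"])
        frames.append(pd.DataFrame({"level": level, "fpr": fpr, "tpr": tpr, "threshold": thr}))
    return pd.concat(frames, ignore_index=True)


def read_volume_pair(image_path: str | Path, mask_path: str | Path) -> tuple[VolumeRecord, LesionMask]:
    """Load a NIfTI volume/mask pair; spacing is read from the affine."""
    import nibabel as nib

    for p in (image_path, mask_path):
        if not Path(p).exists():
            raise IOError(f"file not found: {p}")
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    vol = np.asanyarray(img.dataobj).astype(np.float32)
    mask = np.asanyarray(msk.dataobj) > 0
    if vol.shape != mask.shape:
        raise AlignmentError(f"volume {vol.shape} and mask {mask.shape} shapes differ")
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise AlignmentError("volume and mask affines differ")
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(img.affine))
    pid = Path(image_path).name.replace("_img.nii.gz", "").replace(".nii.gz", "")
    rec = VolumeRecord(patient_id=pid, label=-1, volume=vol, spacing_mm=spacing)
    return rec, LesionMask(patient_id=pid, mask=mask)


def load_cohort(directory: str | Path) -> list[tuple[VolumeRecord, LesionMask]]:
    """Load a cohort written by :func:`lesionroi.cohort.write_cohort`."""
    directory = Path(directory)
    table = pd.read_csv(directory / "cohort.csv")
    pairs = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        rec, lesion = read_volume_pair(directory / f"{pid}_img.nii.gz", directory / f"{pid}_mask.nii.gz")
        rec.label = int(row["label"])
        pairs.append((rec, lesion))
    return pairs


def _pairwise_delong(results: dict[str, CrossValResult], level: str) -> pd.DataFrame:
    variants = list(results)
    mat = pd.DataFrame(np.ones((len(variants), len(variants))), index=variants, columns=variants)
    merged: dict[str, pd.DataFrame] = {}
    for v, res in results.items():
        if level == "slice":
            df = res.predictions.copy()
            df["key"] = df["patient_id"] + ":" + df["slice_index"].astype(str)
        else:
            df = res.patient_predictions().copy()
            df["key"] = df["patient_id"]
        merged[v] = df.set_index("key").sort_index()
    for i, a in enumerate(variants):
        for b in variants[i + 1 :]:
            ka, kb = merged[a], merged[b]
            common = ka.index.intersection(kb.index)
            _, _, _, p = delong_test(
                ka.loc[common, "label"].to_numpy(),
                ka.loc[common, "prob"].to_numpy(),
                kb.loc[common, "prob"].to_numpy(),
            )
            mat.loc[a, b] = p
            mat.loc[b, a] = p
    return mat


def _confidence_summary(results: dict[str, CrossValResult]) -> pd.DataFrame:
    rows = []
    for variant, res in results.items():
        preds = res.predictions
        for pid, grp in preds.groupby("patient_id", sort=True):
            grp = grp.sort_values("slice_index")
            curve = confidence_curve(grp["prob"].to_numpy(), patient_id=pid)
            rows.append(
                {
                    "variant": variant,
                    "patient_id": pid,
                    "label": int(grp["label"].iloc[0]),
                    "mean": curve.mean,
                    "sd": curve.sd,
                    "flag": curve.flag,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full comparative experiment defined by ``config``."""
    t0 = time.time()
    if config.dataset_path:
        logger.info("loading cohort from %s", config.dataset_path)
        pairs = load_cohort(config.dataset_path)
    else:
        logger.info("generating synthetic cohort (n=%d)", config.cohort.n_patients)
        pairs = generate_cohort(config.cohort)

    # one shared slice selection per patient, reused by every variant
    selections = {
        lesion.patient_id: select_slices(lesion, config.area_fraction, config.stride)
        for _, lesion in pairs
    }
    pids = [rec.patient_id for rec, _ in pairs]
    labels = [rec.label for rec, _ in pairs]
    partition = partition_patients(pids, labels, k=config.k, seed=config.seed_partition, stratify=True)

    results: dict[str, CrossValResult] = {}
    for variant in config.variants:
        tv = time.time()
        samples = []
        for rec, lesion in pairs:
            samples.extend(
                extract_patient_samples(
                    rec,
                    lesion,
                    variant,
                    expand=config.expand,
                    margin_mm=config.margin_mm,
                    selection=selections[rec.patient_id],
                )
            )

        def make_backend() -> SliceCNNClassifier:
            return SliceCNNClassifier(
                schedule=config.schedule, augment=config.augment, **config.backend_params
            )

        results[variant] = cross_validate(
            samples,
            partition,
            make_backend,
            variant=variant,
            seed=config.seed_training,
            eval_seed=config.seed_partition,
        )
        logger.info("variant %-9s done in %.1fs", variant, time.time() - tv)

    per_fold = pd.concat(
        [
            pd.DataFrame(
                [
                    {
                        "variant": v,
                        "fold": f.fold,
                        "level": level,
                        **(f.slice_metrics if level == "slice" else f.patient_metrics).as_dict(),
                        "auc": (f.slice_roc if level == "slice" else f.patient_roc).auc,
                    }
                    for f in res.folds
                    for level in ("slice", "patient")
                ]
            )
            for v, res in results.items()
        ],
        ignore_index=True,
    )
    aggregates = pd.concat([aggregate_fold_metrics(res) for res in results.values()], ignore_index=True)
    report = ExperimentReport(
        config=config.to_dict(),
        results=results,
        per_fold=per_fold,
        aggregates=aggregates,
        delong_slice=_pairwise_delong(results, "slice"),
        delong_patient=_pairwise_delong(results, "patient"),
        confidence=_confidence_summary(results),
        provenance={
            "package_version": __version__,
            "seeds": {
                "cohort": config.cohort.seed,
                "partition": config.seed_partition,
                "training": config.seed_training,
            },
            "runtime_s": round(time.time() - t0, 2),
        },
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report
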