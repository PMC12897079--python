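"""Mode-adaptive patient-centric sampling (MAPS).

Patients contribute very different numbers of slices, so naive per-slice
sampling biases training toward large lesions. MAPS weights each patient by

    N_bar = N_total / P          (mean image count per patient)
    r_p   = N_p / N_bar          (patient-specific ratio)
    W_p   = min(r_p, 2.0)        (final weight, capped)

For **training**, patients are drawn with replacement with probability
proportional to ``W_p`` and one of the patient's images is then drawn
uniformly (a flat per-image mode weighting each image by ``W_p / N_p`` is
also available). For **evaluation**, every patient is visited exactly once
per pass in a random order and all of that patient's images are emitted
contiguously, so each case contributes equally to the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["PatientWeights", "maps_weights", "training_sampler", "uniform_patient_batches"]

WEIGHT_CAP = 2.0


@dataclass(frozen=True)
class PatientWeights:
    """Per-patient MAPS quantities plus the cohort-level aggregates."""

    n_p: dict[str, int]
    n_total: int
    n_patients: int
    n_bar: float
    r_p: dict[str, float]
    w_p: dict[str, float]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.n_p)


def maps_weights(image_counts: Mapping[str, int]) -> PatientWeights:
    """Compute the MAPS sampling weights from per-patient image counts."""
    if not image_counts:
        raise ConfigurationError("need at least one patient")
    for pid, n in image_counts.items():
        if n < 1:
            raise ConfigurationError(f"patient {pid!r} has non-positive image count {n}")
    n_p = {pid: int(n) for pid, n in image_counts.items()}
    n_total = sum(n_p.values())
    p = len(n_p)
    n_bar = n_total / p
    r_p = {pid: n / n_bar for pid, n in n_p.items()}
    w_p = {pid: min(r, WEIGHT_CAP) for pid, r in r_p.items()}
    return PatientWeights(n_p=n_p, n_total=n_total, n_patients=p, n_bar=n_bar, r_p=r_p, w_p=w_p)


def training_sampler(
    weights: PatientWeights,
    seed: int,
    n_draws: int | None = None,
    mode: str = "patient",
) -> Iterator[tuple[str, int]]:
    """Yield ``(patient_id, image_index)`` training draws, with replacement.

    ``mode="patient"`` (default): draw a patient with probability
    proportional to ``W_p``, then one of its images uniformly, so the
    per-image draw probability is ``(W_p / sum W) / N_p``.
    ``mode="image"``: draw images directly with flat weights ``W_p / N_p``
    (identical marginal probabilities, no hierarchical step).

    ``n_draws`` defaults to one epoch of ``N_total`` draws. Deterministic
    for a fixed seed.
    """
    if mode not in ("patient", "image"):
        raise ConfigurationError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    if n_draws is None:
        n_draws = weights.n_total
    pids = list(weights.n_p)
    counts = np.array([weights.n_p[p] for p in pids])
    w = np.array([weights.w_p[p] for p in pids], dtype=float)

    if mode == "patient":
        prob = w / w.sum()
        patient_idx = rng.choice(len(pids), size=n_draws, p=prob)
        # uniform image within the drawn patient
        u = rng.random(n_draws)
        for i in range(n_draws):
            pi = int(patient_idx[i])
            yield pids[pi], int(u[i] * counts[pi])
    else:
        per_image_w = np.repeat(w / counts, counts)
        owners = np.repeat(np.arange(len(pids)), counts)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        flat = rng.choice(owners.size, size=n_draws, p=per_image_w / per_image_w.sum())
        for f in flat:
            pi = int(owners[f])
            yield pids[pi], int(f - offsets[pi])


def uniform_patient_batches(
    patients: Sequence[str] | Mapping[str, int],
    seed: int,
) -> list[tuple[str, int]]:
    """Evaluation plan: a random patient permutation, slices contiguous.

    ``patients`` is either a mapping ``patient_id -> n_slices`` or a bare
    list of ids (then one item per patient). Each patient appears exactly
    once per pass; once sampled, *all* of its images are included, in
    slice order.
    """
    if len(patients) == 0:
        raise ConfigurationError("need at least one patient")
    if isinstance(patients, Mapping):
        counts = {pid: int(n) for pid, n in patients.items()}
    else:
        counts = {pid: 1 for pid in patients}
    rng = np.random.default_rng(seed)
    order = list(counts)
    rng.shuffle(order)
    plan: list[tuple[str, int]] = []
    for pid in order:
        plan.extend((pid, i) for i in range(counts[pid]))
    return plan
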