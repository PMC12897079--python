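"""Two-phase learning-rate schedule.

Phase 1: linear warm-up from ``warmup_start_lr`` to ``peak_lr`` over
``warmup_epochs``, then cosine decay toward ``eta_min`` reaching it at
``phase2_start_epoch - 1``. Phase 2: the rate jumps back up to
``phase2_lr`` at ``phase2_start_epoch`` (the single upward discontinuity,
used to escape plateaus) and cosine-decays to ``eta_min`` by
``max_epochs``. Epochs are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["LrSchedule", "lr_at_epoch"]


@dataclass(frozen=True)
class LrSchedule:
    warmup_epochs: int = 5
    warmup_start_lr: float = 1e-4
    peak_lr: float = 1e-3
    eta_min: float = 1e-5
    phase2_start_epoch: int = 51
    phase2_lr: float = 5e-4
    max_epochs: int = 100
    early_stop_patience: int = 10

    def __post_init__(self) -> None:
        if self.phase2_start_epoch <= self.warmup_epochs:
            raise ConfigurationError("phase2_start_epoch must exceed warmup_epochs")
        for name in ("warmup_start_lr", "peak_lr", "eta_min", "phase2_lr"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.max_epochs < self.phase2_start_epoch:
            raise ConfigurationError("max_epochs must be >= phase2_start_epoch")
        if self.warmup_epochs < 1:
            raise ConfigurationError("warmup_epochs must be >= 1")


def _cosine(start: float, end: float, t: float) -> float:
    return end + (start - end) * 0.5 * (1.0 + math.cos(math.pi * t))


def lr_at_epoch(epoch: int, schedule: LrSchedule) -> float:
    """Learning rate at a (1-based) epoch."""
    s = schedule
    if epoch < 1 or epoch > s.max_epochs:
        raise ConfigurationError(f"epoch {epoch} outside [1, {s.max_epochs}]")
    if epoch <= s.warmup_epochs:
        if s.warmup_epochs == 1:
            return s.peak_lr
        frac = (epoch - 1) / (s.warmup_epochs - 1)
        return s.warmup_start_lr + frac * (s.peak_lr - s.warmup_start_lr)
    if epoch < s.phase2_start_epoch:
        span = (s.phase2_start_epoch - 1) - s.warmup_epochs
        t = (epoch - s.warmup_epochs) / span if span > 0 else 1.0
        return _cosine(s.peak_lr, s.eta_min, t)
    span = s.max_epochs - s.phase2_start_epoch
    t = (epoch - s.phase2_start_epoch) / span if span > 0 else 1.0
    return _cosine(s.phase2_lr, s.eta_min, t)
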