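import numpy as np
import pytest

from lesionroi import (
    AugmentParams,
    CohortConfig,
    LrSchedule,
    SliceCNNClassifier,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight phantom patients, enough to exercise every geometric path."""
    config = CohortConfig(n_patients=8, seed=5)
    return config, generate_cohort(config)


def make_texture_task(n: int, seed: int = 1, size: int = 64):
    """Noise-free toy in the spirit of the lesion variants: a plain
    low-intensity disk (class 0) versus a disk crossed by bright stripes,
    a septation analogue (class 1). The signal is textural, so it survives
    flips/rotations and the classifier's translation-invariant pooling."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, size, size))
    y = np.arange(n) % 2
    rr, cc = np.ogrid[:size, :size]
    lo, hi = size // 3, size - size // 3
    for i in range(n):
        r0, c0 = rng.integers(lo, hi, 2)
        rad = rng.integers(size // 6, size // 4)
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        X[i][disk] = 300.0
        if y[i]:
            stripes = (rr // 3) % 2 == 0
            X[i][disk & stripes] = 800.0
    return X, y


@pytest.fixture(scope="session")
def trained_toy_backend():
    """A quickly trained backend for attribution / prediction contracts."""
    X, y = make_texture_task(48, seed=3)
    schedule = LrSchedule(
        warmup_epochs=2,
        peak_lr=3e-3,
        eta_min=3e-4,
        phase2_start_epoch=8,
        phase2_lr=1.5e-3,
        max_epochs=10,
        early_stop_patience=10,
    )
    augment = AugmentParams(hflip_prob=0.0, rotation_deg=0.0, translate_frac=0.0, scale_range=(1.0, 1.0))
    clf = SliceCNNClassifier(schedule=schedule, augment=augment, random_state=0)
    clf.fit(X, y)
    return clf, X, y
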