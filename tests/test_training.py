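"""Augmentation, learning-rate schedule, and classifier backend contracts."""

import numpy as np
import pytest

from lesionroi import (
    AugmentParams,
    ConfigurationError,
    LeakageError,
    LrSchedule,
    SliceCNNClassifier,
    augment_slice,
    lr_at_epoch,
)
from lesionroi.augment import draw_augment_params
from tests.conftest import make_texture_task


class TestAugment:
    def test_eval_mode_is_resize_plus_normalize_only(self):
        rng = np.random.default_rng(0)
        img = rng.random((100, 100)) * 500
        out1 = augment_slice(img, AugmentParams(target_size=64), mode="eval")
        out2 = augment_slice(img, AugmentParams(target_size=64), mode="eval", rng=123)
        np.testing.assert_array_equal(out1, out2)  # no stochastic ops
        assert out1.shape == (64, 64)
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        # fixed-scale normalization: proportional to the resized raw image
        from skimage.transform import resize

        expected = resize(img, (64, 64), order=1, mode="constant", anti_aliasing=True) / 1000.0
        np.testing.assert_allclose(out1, expected, atol=1e-12)

    def test_eval_idempotent_on_conforming_image(self):
        img = np.random.default_rng(1).random((64, 64))
        once = augment_slice(img, AugmentParams(target_size=64), mode="eval")
        twice = augment_slice(once, AugmentParams(target_size=64), mode="eval")
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_draw_bounds_over_many_samples(self):
        params = AugmentParams()
        rng = np.random.default_rng(7)
        draws = [draw_augment_params(params, rng) for _ in range(10_000)]
        assert all(abs(d["angle_deg"]) <= 15.0 for d in draws)
        assert all(0.95 <= d["scale"] <= 1.05 for d in draws)
        assert all(abs(d["tx_frac"]) <= 0.05 and abs(d["ty_frac"]) <= 0.05 for d in draws)
        flips = np.mean([d["flip"] for d in draws])
        assert abs(flips - 0.5) < 4 * np.sqrt(0.25 / 10_000)

    def test_train_mode_deterministic_per_seed(self):
        img = np.random.default_rng(2).random((80, 80))
        a = augment_slice(img, AugmentParams(), mode="train", rng=11)
        b = augment_slice(img, AugmentParams(), mode="train", rng=11)
        c = augment_slice(img, AugmentParams(), mode="train", rng=12)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_nonfinite_input_rejected(self):
        img = np.full((10, 10), np.nan)
        with pytest.raises(ConfigurationError):
            augment_slice(img, AugmentParams(), mode="eval")


class TestSchedule:
    def test_phase2_reset_is_an_upward_jump(self):
        s = LrSchedule()
        before = lr_at_epoch(s.phase2_start_epoch - 1, s)
        at = lr_at_epoch(s.phase2_start_epoch, s)
        assert at == pytest.approx(s.phase2_lr)
        assert at > before

    def test_cosine_reaches_floor_before_reset(self):
        s = LrSchedule(warmup_epochs=2, phase2_start_epoch=40)
        assert lr_at_epoch(39, s) == pytest.approx(s.eta_min)

    def test_warmup_linear_interpolation(self):
        s = LrSchedule(warmup_epochs=5, warmup_start_lr=1e-4, peak_lr=1e-3)
        assert lr_at_epoch(1, s) == pytest.approx(1e-4)
        assert lr_at_epoch(5, s) == pytest.approx(1e-3)
        assert lr_at_epoch(3, s) == pytest.approx(1e-4 + 0.5 * (1e-3 - 1e-4))

    def test_single_upward_discontinuity_after_warmup(self):
        s = LrSchedule()
        rates = [lr_at_epoch(e, s) for e in range(1, s.max_epochs + 1)]
        ups = [e for e in range(s.warmup_epochs + 1, s.max_epochs) if rates[e] > rates[e - 1] + 1e-15]
        assert ups == [s.phase2_start_epoch - 1]  # 0-based offset of the jump

    def test_out_of_range_epoch_rejected(self):
        s = LrSchedule(max_epochs=60)
        for bad in (0, 61):
            with pytest.raises(ConfigurationError):
                lr_at_epoch(bad, s)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            LrSchedule(warmup_epochs=10, phase2_start_epoch=5)


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self):
        """Central-difference check of the full backward pass (conv, batch
        norm, pooling, dense head) on a tiny network."""
        from lesionroi._nn import CompactCNN, cross_entropy, softmax

        rng = np.random.default_rng(0)
        net = CompactCNN(input_size=16, channels=(3, 4, 5), hidden=6, dropout=(0, 0, 0), rng=rng)
        x = rng.random((4, 16, 16)).astype(np.float32)
        y = np.array([0, 1, 1, 0])

        def loss():
            logits, _ = net.forward(x, train=True, rng=rng)
            return cross_entropy(softmax(logits), y)

        _, _, grads = net.loss_and_grads(x, y, rng)
        for k, p in net.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-3, p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[k][idx] == pytest.approx(numeric, rel=0.05, abs=1e-4), k


def quick_schedule(max_epochs=3):
    return LrSchedule(
        warmup_epochs=1, peak_lr=1e-3, phase2_start_epoch=max_epochs, phase2_lr=5e-4, max_epochs=max_epochs, early_stop_patience=99
    )


class TestBackend:
    def test_leakage_guard_raises(self):
        X, y = make_texture_task(8, size=32)
        clf = SliceCNNClassifier(schedule=quick_schedule(), augment=AugmentParams(target_size=32))
        with pytest.raises(LeakageError):
            clf.fit(
                X,
                y,
                patient_ids=["p1"] * 4 + ["p2"] * 4,
                X_val=X[:2],
                y_val=y[:2],
                val_patient_ids=["p2", "p3"],
            )

    def test_history_reproducible_for_fixed_seed(self):
        X, y = make_texture_task(12, size=32)
        kw = dict(schedule=quick_schedule(), augment=AugmentParams(target_size=32), random_state=4)
        h1 = SliceCNNClassifier(**kw).fit(X, y).history_
        h2 = SliceCNNClassifier(**kw).fit(X, y).history_
        assert h1.equals(h2)

    def test_probabilities_valid_and_deterministic(self, trained_toy_backend):
        clf, X, y = trained_toy_backend
        probs = clf.predict_proba(X[:8])
        assert probs.shape == (8, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        again = clf.predict_proba(X[:8])
        np.testing.assert_array_equal(probs, again)
        # duplicated input -> identical output
        dup = clf.predict_proba([X[0], X[0]])
        np.testing.assert_array_equal(dup[0], dup[1])

    def test_unfitted_predict_rejected(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            SliceCNNClassifier().predict_proba(np.zeros((1, 64, 64)))

    def test_early_stopping_and_overfit_monitor(self):
        X, y = make_texture_task(16, size=32)
        Xv, yv = make_texture_task(8, seed=9, size=32)
        sched = LrSchedule(
            warmup_epochs=1, peak_lr=1e-3, phase2_start_epoch=5, phase2_lr=5e-4, max_epochs=30, early_stop_patience=3
        )
        clf = SliceCNNClassifier(schedule=sched, augment=AugmentParams(target_size=32), random_state=0)
        clf.fit(X, y, patient_ids=[f"p{i}" for i in range(16)], X_val=Xv, y_val=yv, val_patient_ids=[f"q{i}" for i in range(8)])
        h = clf.history_
        assert {"val_accuracy", "accuracy_gap", "overfit_flag", "lr"} <= set(h.columns)
        # patience: training must not run past best epoch + patience
        assert clf.n_epochs_ <= 30
        best = h.val_accuracy.max()
        assert clf.best_val_accuracy_ == pytest.approx(best)

    def test_flipping_output_layer_complements_probabilities(self, trained_toy_backend):
        """Swapping the two output units turns p into 1 - p (softmax
        symmetry), so class encodings are interchangeable."""
        import copy

        clf, X, _ = trained_toy_backend
        p = clf.predict_proba(X[:6])[:, 1]
        flipped = copy.deepcopy(clf)
        flipped.net_.params["fc3_w"] = flipped.net_.params["fc3_w"][:, ::-1].copy()
        flipped.net_.params["fc3_b"] = flipped.net_.params["fc3_b"][::-1].copy()
        q = flipped.predict_proba(X[:6])[:, 1]
        np.testing.assert_allclose(q, 1.0 - p, atol=1e-6)

    def test_sklearn_param_interface(self):
        clf = SliceCNNClassifier(hidden=16)
        params = clf.get_params()
        assert params["hidden"] == 16
        clf.set_params(batch_size=8)
        assert clf.batch_size == 8

    def test_save_load_roundtrip(self, trained_toy_backend, tmp_path):
        clf, X, _ = trained_toy_backend
        path = tmp_path / "ckpt.npz"
        clf.save(path)
        other = SliceCNNClassifier.load(path)
        np.testing.assert_allclose(other.predict_proba(X[:4]), clf.predict_proba(X[:4]), atol=1e-12)
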