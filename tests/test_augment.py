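"""Augmentation: mixing identities, mask/area exactness, balancing, selection."""

import numpy as np
import pytest

from lmnet.augment import (RPDD_MULTIPLIERS, BalancePlan, apply_balance_plan,
                           apply_traditional, build_balance_plan, cutmix,
                           mix_batch, mixup, sample_lambda, select_augmentation)
from lmnet.datagen import (RPDD_TABLE, DatasetManifest, ManifestRecord,
                           rpdd_original_counts)


def one_hot(labels, k):
    out = np.zeros((len(labels), k), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1
    return out


# -- lambda sampling ---------------------------------------------------

def test_lambda_uniform_for_alpha_one(rng):
    draws = np.array([sample_lambda(1.0, rng) for _ in range(100_000)])
    # Beta(1,1) = Uniform(0,1): mean 0.5, sd of the mean = 1/sqrt(12 n)
    assert abs(draws.mean() - 0.5) < 3 / np.sqrt(12 * draws.size)
    assert draws.min() >= 0 and draws.max() <= 1


def test_lambda_moments_for_alpha_two(rng):
    draws = np.array([sample_lambda(2.0, rng) for _ in range(100_000)])
    var = 4 / (16 * 5)   # alpha*beta / ((a+b)^2 (a+b+1)) = 0.05
    assert abs(draws.mean() - 0.5) < 3 * np.sqrt(var / draws.size)
    assert abs(draws.var() - var) < 0.005


def test_lambda_seeded_replay():
    a = [sample_lambda(1.0, np.random.default_rng(9)) for _ in range(10)]
    b = [sample_lambda(1.0, np.random.default_rng(9)) for _ in range(10)]
    assert a == b
    with pytest.raises(ValueError):
        sample_lambda(0.0, np.random.default_rng(0))


# -- mixup -------------------------------------------------------------

def test_mixup_endpoint_identity(rng):
    x1 = rng.random((3, 3, 4, 4)).astype(np.float32)
    x2 = rng.random((3, 3, 4, 4)).astype(np.float32)
    y1, y2 = one_hot([0, 1, 2], 3), one_hot([2, 0, 1], 3)
    out = mixup(x1, y1, x2, y2, 1.0)
    np.testing.assert_array_equal(out.images, x1)
    np.testing.assert_array_equal(out.soft_labels, y1)


def test_mixup_half_blend():
    x1 = np.zeros((1, 1, 2, 2), np.float32)
    x2 = np.ones((1, 1, 2, 2), np.float32)
    out = mixup(x1, one_hot([0], 2), x2, one_hot([1], 2), 0.5)
    np.testing.assert_array_equal(out.images, 0.5)
    np.testing.assert_array_equal(out.soft_labels, [[0.5, 0.5]])


def test_mixup_matches_hand_formula(rng):
    x1 = rng.random((2, 1, 2, 2)).astype(np.float32)
    x2 = rng.random((2, 1, 2, 2)).astype(np.float32)
    y1, y2 = one_hot([0, 1], 2), one_hot([1, 0], 2)
    out = mixup(x1, y1, x2, y2, 0.3)
    np.testing.assert_allclose(out.images, 0.3 * x1 + 0.7 * x2, rtol=1e-6)
    np.testing.assert_allclose(out.soft_labels, 0.3 * y1 + 0.7 * y2, rtol=1e-6)
    with pytest.raises(ValueError):
        mixup(x1, y1, x2[:1], y2[:1], 0.3)


# -- cutmix ------------------------------------------------------------

def test_cutmix_zero_area_box_is_identity(rng):
    xa = rng.random((2, 3, 4, 4)).astype(np.float32)
    xb = rng.random((2, 3, 4, 4)).astype(np.float32)
    ya, yb = one_hot([0, 1], 2), one_hot([1, 0], 2)
    out = cutmix(xa, ya, xb, yb, 1.0, rng, box=(0, 0, 0, 0))
    np.testing.assert_array_equal(out.images, xa)
    np.testing.assert_array_equal(out.soft_labels, ya)
    assert out.lambda_ == 1.0


def test_cutmix_forced_half_mask(rng):
    """Mask over rows 0-1 of a 4x4 image: label weight on yb is 8/16 = 0.5."""
    xa = np.zeros((1, 1, 4, 4), np.float32)
    xb = np.ones((1, 1, 4, 4), np.float32)
    out = cutmix(xa, one_hot([0], 2), xb, one_hot([1], 2), 1.0, rng,
                 box=(0, 2, 0, 4))
    np.testing.assert_array_equal(out.images[0, 0, :2], 1.0)   # from xb
    np.testing.assert_array_equal(out.images[0, 0, 2:], 0.0)   # from xa
    assert out.lambda_ == 0.5
    np.testing.assert_array_equal(out.soft_labels, [[0.5, 0.5]])


def test_cutmix_lambda_equals_mask_area_over_many_draws(rng):
    """lambda/area identity and pixel provenance for 10^4 sampled masks."""
    xa = np.zeros((1, 1, 13, 17), np.float32)
    xb = np.ones((1, 1, 13, 17), np.float32)
    ya, yb = one_hot([0], 2), one_hot([1], 2)
    for _ in range(10_000):
        out = cutmix(xa, ya, xb, yb, 1.0, rng)
        assert set(np.unique(out.mask)) <= {0.0, 1.0}
        assert out.mask.mean() == pytest.approx(1 - out.lambda_, abs=1e-12)
        # every output pixel comes from exactly one source
        assert set(np.unique(out.images)) <= {0.0, 1.0}
        np.testing.assert_array_equal(out.images[0, 0], out.mask)
        # soft labels: convex, at most two support points
        assert out.soft_labels.sum() == pytest.approx(1.0, abs=1e-6)
        assert (out.soft_labels >= 0).all()


def test_mix_batch_seeded_determinism(rng):
    x = rng.random((8, 3, 6, 6)).astype(np.float32)
    y = one_hot(rng.integers(0, 3, 8), 3)
    for method in ("mixup", "cutmix"):
        a = mix_batch(x, y, method, 1.0, np.random.default_rng(4))
        b = mix_batch(x, y, method, 1.0, np.random.default_rng(4))
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.soft_labels, b.soft_labels)
        assert (np.abs(a.soft_labels.sum(axis=1) - 1) < 1e-6).all()
        assert ((a.soft_labels > 0).sum(axis=1) <= 2).all()


# -- traditional ops ---------------------------------------------------

def test_rotate_four_quarter_turns_is_identity(rng):
    img = rng.random((6, 6, 3)).astype(np.float32)
    out = img
    for _ in range(4):
        out = apply_traditional(out, "rotate", angle=90)
    np.testing.assert_array_equal(out, img)


def test_identity_parameters(rng):
    img = rng.random((5, 5, 3)).astype(np.float32)
    np.testing.assert_allclose(apply_traditional(img, "contrast", factor=1.0),
                               img, rtol=1e-6, atol=1e-6)
    np.testing.assert_array_equal(apply_traditional(img, "gaussian_blur", sigma=0),
                                  img)
    with pytest.raises(ValueError):
        apply_traditional(img, "gaussian_blur", sigma=-1)
    with pytest.raises(ValueError):
        apply_traditional(img, "contrast", factor=0)


def test_blur_preserves_constant_images():
    """A normalised Gaussian kernel maps constants to themselves."""
    img = np.full((9, 9, 3), 0.42, np.float32)
    out = apply_traditional(img, "gaussian_blur", sigma=1.0)
    np.testing.assert_allclose(out, img, rtol=1e-5)


# -- balance plan ------------------------------------------------------

def test_default_multipliers_reproduce_published_training_counts():
    originals = rpdd_original_counts()
    plan = build_balance_plan(originals, multipliers=RPDD_MULTIPLIERS)
    augmented = plan.augmented_counts(originals)
    for cls, (test, train, val, orig) in RPDD_TABLE.items():
        assert augmented[cls] == train, cls


def test_unit_multipliers_are_identity():
    plan = build_balance_plan({"a": 10, "b": 20}, multipliers=[1, 1])
    assert plan.augmented_counts({"a": 10, "b": 20}) == {"a": 10, "b": 20}
    with pytest.raises(ValueError):
        BalancePlan(multipliers={"a": 0})


def test_materialised_counts_match_file_enumeration(tmp_path, rng):
    """Total augmented files on disk equal sum of m_c * n_c exactly."""
    from PIL import Image
    src = tmp_path / "src"
    src.mkdir()
    records = []
    for cls, n in (("a", 3), ("b", 2)):
        for i in range(n):
            p = src / f"{cls}_{i}.png"
            Image.fromarray(
                (rng.random((8, 8, 3)) * 255).astype(np.uint8)).save(p)
            records.append(ManifestRecord(cls, "original_train", str(p)))
    manifest = DatasetManifest(records)
    plan = build_balance_plan({"a": 3, "b": 2}, multipliers={"a": 3, "b": 2})
    out = apply_balance_plan(manifest, plan, tmp_path / "aug", seed=0)
    counts = out.counts()
    assert counts["a"]["train"] == 9 and counts["b"]["train"] == 4
    written = list((tmp_path / "aug").rglob("*.png"))
    assert len(written) == (9 - 3) + (4 - 2)      # originals are reused in place
    assert out.validate_files(root="/") == [] or out.validate_files() == []


# -- selection protocol ------------------------------------------------

def test_selection_picks_higher_accuracy_arm():
    report = select_augmentation(
        "mixup", "cutmix", {"mixup": 0.91, "cutmix": 0.89}.__getitem__)
    assert report.chosen == "mixup"
    assert report.accuracies == {"mixup": 0.91, "cutmix": 0.89}


def test_selection_tie_breaks_to_cutmix():
    report = select_augmentation("mixup", "cutmix", lambda m: 0.9)
    assert report.chosen == "cutmix"


def test_selection_records_arm_failure_without_crashing():
    def run_arm(method):
        if method == "mixup":
            raise ArithmeticError("non-finite training loss")
        return 0.8

    report = select_augmentation("mixup", "cutmix", run_arm)
    assert report.chosen == "cutmix"
    assert "mixup" in report.failures
    with pytest.raises(RuntimeError):
        select_augmentation("a", "b", lambda m: float("nan"))
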