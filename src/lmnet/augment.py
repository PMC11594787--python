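"""Data augmentation: traditional ops, MixUp, CutMix, class balancing.

MixUp forms a pixelwise convex combination of two samples,

    lambda ~ Beta(alpha, alpha),  X = lambda*X1 + (1-lambda)*X2,

with labels mixed by the same weight.  CutMix transplants a rectangular
patch of one image into another through a binary mask M and mixes the
labels by the surviving area fraction; after the patch is clipped to the
image the mixing weight is recomputed as ``lambda = 1 - area(M)/(W*H)``
so the label weight and the mask area agree exactly.

The balance plan replicates each class by an integer multiplier (the
original counts as one copy) using the traditional ops, which is how the
published per-class training counts arise from the raw ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .datagen import DatasetManifest, ManifestRecord

__all__ = [
    "MixParams", "AugmentedBatch", "BalancePlan", "SelectionReport",
    "sample_lambda", "mixup", "cutmix", "apply_traditional",
    "build_balance_plan", "apply_balance_plan", "select_augmentation",
    "RPDD_MULTIPLIERS",
]

# default per-class multipliers reproducing the published balanced
# training counts from the raw ones (416*6=2496, 1009*2=2018, ...)
RPDD_MULTIPLIERS = (6, 6, 6, 2, 5, 5, 5)


@dataclass
class MixParams:
    alpha: float = 1.0
    lambda_: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.lambda_ is not None and not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must lie in [0, 1]")


@dataclass
class AugmentedBatch:
    images: np.ndarray          # (N, C, H, W) float32
    soft_labels: np.ndarray     # (N, K), rows sum to 1
    lambda_: float              # mixing weight actually applied
    mask: np.ndarray | None = None   # (H, W) binary, CutMix only


def sample_lambda(alpha: float, rng: np.random.Generator) -> float:
    """One draw of the Beta(alpha, alpha) mixing coefficient."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(rng.beta(alpha, alpha))


def _check_pair(x1, y1, x2, y2):
    if x1.shape != x2.shape or y1.shape != y2.shape:
        raise ValueError(
            f"shape mismatch: images {x1.shape} vs {x2.shape}, "
            f"labels {y1.shape} vs {y2.shape}")


def mixup(x1: np.ndarray, y1: np.ndarray, x2: np.ndarray, y2: np.ndarray,
          lambda_: float) -> AugmentedBatch:
    """Convex combination with weight ``lambda_`` on the first batch."""
    x1, x2 = np.asarray(x1, dtype=np.float32), np.asarray(x2, dtype=np.float32)
    y1, y2 = np.asarray(y1, dtype=np.float32), np.asarray(y2, dtype=np.float32)
    _check_pair(x1, y1, x2, y2)
    lam = float(lambda_)
    return AugmentedBatch(images=lam * x1 + (1 - lam) * x2,
                          soft_labels=lam * y1 + (1 - lam) * y2,
                          lambda_=lam)


def _sample_box(h: int, w: int, lam0: float, rng: np.random.Generator):
    """CutMix rectangle: sides scale with sqrt(1-lambda), uniform centre, clipped."""
    ratio = np.sqrt(1.0 - lam0)
    cut_h, cut_w = int(round(h * ratio)), int(round(w * ratio))
    cy, cx = rng.integers(0, h), rng.integers(0, w)
    y0, y1 = np.clip([cy - cut_h // 2, cy + (cut_h + 1) // 2], 0, h)
    x0, x1 = np.clip([cx - cut_w // 2, cx + (cut_w + 1) // 2], 0, w)
    return int(y0), int(y1), int(x0), int(x1)


def cutmix(xa: np.ndarray, ya: np.ndarray, xb: np.ndarray, yb: np.ndarray,
           alpha: float, rng: np.random.Generator,
           box: tuple[int, int, int, int] | None = None) -> AugmentedBatch:
    """Patch transplant from ``xb`` into ``xa`` with area-exact label mixing.

    ``box=(y0, y1, x0, x1)`` forces the patch (used by tests); otherwise it
    is sampled from lambda0 ~ Beta(alpha, alpha) as in the original recipe.
    """
    xa, xb = np.asarray(xa, dtype=np.float32), np.asarray(xb, dtype=np.float32)
    ya, yb = np.asarray(ya, dtype=np.float32), np.asarray(yb, dtype=np.float32)
    _check_pair(xa, ya, xb, yb)
    h, w = xa.shape[-2:]
    if box is None:
        lam0 = sample_lambda(alpha, rng)
        box = _sample_box(h, w, lam0, rng)
    y0, y1, x0, x1 = box
    mask = np.zeros((h, w), dtype=np.float32)
    mask[y0:y1, x0:x1] = 1.0
    lam = 1.0 - float(mask.sum()) / (h * w)    # recomputed after clipping
    images = (1.0 - mask) * xa + mask * xb
    return AugmentedBatch(images=images,
                          soft_labels=lam * ya + (1 - lam) * yb,
                          lambda_=lam, mask=mask)


def mix_batch(x: np.ndarray, y: np.ndarray, method: str, alpha: float,
              rng: np.random.Generator) -> AugmentedBatch:
    """Apply MixUp/CutMix within a batch against a random permutation of it."""
    if method == "none":
        return AugmentedBatch(images=x.astype(np.float32),
                              soft_labels=y.astype(np.float32), lambda_=1.0)
    perm = rng.permutation(x.shape[0])
    if method == "mixup":
        return mixup(x, y, x[perm], y[perm], sample_lambda(alpha, rng))
    if method == "cutmix":
        return cutmix(x, y, x[perm], y[perm], alpha, rng)
    raise ValueError(f"unknown mixing method {method!r}")


# ---------------------------------------------------------------------
# traditional augmentation
# ---------------------------------------------------------------------

def apply_traditional(image: np.ndarray, op: str, **params) -> np.ndarray:
    """Rotation, Gaussian blur or contrast adjustment on an (H, W, C) image.

    Right-angle rotations are lossless (``np.rot90``); arbitrary angles use
    spline interpolation with reflective borders.  Contrast scales the
    deviation from the image mean; blur is per-channel Gaussian filtering.
    """
    image = np.asarray(image, dtype=np.float32)
    if op == "rotate":
        angle = float(params["angle"]) % 360
        if angle % 90 == 0:
            return np.rot90(image, k=int(angle // 90), axes=(0, 1)).copy()
        return ndimage.rotate(image, angle, axes=(1, 0), reshape=False,
                              mode="reflect", order=1)
    if op == "gaussian_blur":
        sigma = float(params["sigma"])
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        if sigma == 0:
            return image.copy()
        return ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0))
    if op == "contrast":
        factor = float(params["factor"])
        if factor <= 0:
            raise ValueError("contrast factor must be positive")
        mean = image.mean()
        lo, hi = (0.0, 1.0) if image.max() <= 1.0 else (0.0, 255.0)
        return np.clip(mean + factor * (image - mean), lo, hi)
    raise ValueError(f"unknown traditional op {op!r}")


# ---------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------

DEFAULT_OP_POOL = (
    ("rotate", {"angle": 90}), ("rotate", {"angle": 180}),
    ("rotate", {"angle": 270}), ("gaussian_blur", {"sigma": 1.0}),
    ("contrast", {"factor": 1.3}), ("contrast", {"factor": 0.7}),
)


@dataclass
class BalancePlan:
    """Per-class integer multipliers with the op pool used for extra copies.

    ``multipliers[c] = m`` means class c ends with ``m * original`` images,
    the originals counting as one copy each.
    """

    multipliers: dict[str, int]
    op_pool: tuple = DEFAULT_OP_POOL

    def __post_init__(self):
        for cls, m in self.multipliers.items():
            if m < 1:
                raise ValueError(f"multiplier for {cls!r} must be >= 1, got {m}")

    def augmented_counts(self, original: dict[str, int]) -> dict[str, int]:
        return {cls: self.multipliers[cls] * n for cls, n in original.items()}


def build_balance_plan(manifest_or_counts, multipliers=None,
                       op_pool=DEFAULT_OP_POOL) -> BalancePlan:
    """Balance plan from per-class original counts (or a manifest).

    Without explicit multipliers each class is scaled toward the largest
    class: ``m_c = max(1, round(max_count / n_c))`` — more augmentation for
    rarer classes.
    """
    if isinstance(manifest_or_counts, DatasetManifest):
        counts = {cls: len([r for r in manifest_or_counts.records
                            if r.class_name == cls])
                  for cls in manifest_or_counts.class_names}
    else:
        counts = dict(manifest_or_counts)
    if multipliers is None:
        biggest = max(counts.values())
        multipliers = {cls: max(1, round(biggest / n)) for cls, n in counts.items()}
    elif not isinstance(multipliers, dict):
        multipliers = dict(zip(counts, multipliers))
    return BalancePlan(multipliers=multipliers, op_pool=op_pool)


def apply_balance_plan(manifest: DatasetManifest, plan: BalancePlan,
                       out_dir: str | Path, seed: int = 0,
                       root: str | Path = ".") -> DatasetManifest:
    """Materialise the augmented training set to disk.

    Each original image contributes itself plus ``m_c - 1`` transformed
    copies drawn from the op pool; returns the manifest of the augmented
    set (split "train").
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records: list[ManifestRecord] = []
    for rec in manifest.records:
        m = plan.multipliers.get(rec.class_name, 1)
        records.append(ManifestRecord(rec.class_name, "train", rec.path))
        if m == 1:
            continue
        with Image.open(Path(root) / rec.path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
        stem = Path(rec.path).stem
        cls_dir = out_dir / rec.class_name.replace(" ", "_")
        cls_dir.mkdir(exist_ok=True)
        for j in range(m - 1):
            op, params = plan.op_pool[rng.integers(len(plan.op_pool))]
            aug = apply_traditional(arr, op, **params)
            out_path = cls_dir / f"{stem}_aug{j}.png"
            Image.fromarray((np.clip(aug, 0, 1) * 255).astype(np.uint8)).save(out_path)
            records.append(ManifestRecord(rec.class_name, "train", str(out_path)))
    return DatasetManifest(records)


# ---------------------------------------------------------------------
# augmentation-selection protocol
# ---------------------------------------------------------------------

@dataclass
class SelectionReport:
    chosen: str
    accuracies: dict[str, float] = field(default_factory=dict)
    reports: dict[str, object] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def select_augmentation(method_a: str, method_b: str, run_arm,
                        tie_break: str = "cutmix") -> SelectionReport:
    """Train/evaluate one arm per augmentation method; keep the winner.

    ``run_arm(method)`` trains a fresh backbone on the method's augmented
    training set under identical configuration and returns either an
    accuracy or an object with an ``accuracy`` attribute.  A diverging arm
    (exception / non-finite accuracy) is recorded as a failure, not
    raised.  Exact ties go to ``tie_break``.
    """
    report = SelectionReport(chosen="")
    for method in (method_a, method_b):
        try:
            result = run_arm(method)
            acc = result if isinstance(result, (int, float)) else result.accuracy
            if not np.isfinite(acc):
                raise ArithmeticError(f"non-finite accuracy {acc}")
            report.accuracies[method] = float(acc)
            report.reports[method] = result
        except Exception as exc:  # per-arm failure, not a crash
            report.failures[method] = str(exc)
    if not report.accuracies:
        raise RuntimeError(f"both arms failed: {report.failures}")
    best = max(report.accuracies.values())
    winners = [m for m, a in report.accuracies.items() if a == best]
    report.chosen = tie_break if len(winners) > 1 and tie_break in winners else winners[0]
    return report
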