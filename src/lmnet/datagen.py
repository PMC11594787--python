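"""Synthetic labeled-image generation, dataset partitioning and manifests.

The real seven-class rice pest/disease collection (field photographs of
planthoppers, leaf-rollers, blast lesions, ...) is not redistributable,
so :func:`generate_synthetic_dataset` emulates its statistical skeleton:
K classes of textured leaf-like backgrounds in class-specific hue bands
overlaid with class-specific motifs (elliptical lesions, stripes, spots)
plus pixel noise.  The classes are separable by colour/texture, which is
what desk-scale training tests need; nothing about real rice imagery is
claimed.

:data:`RPDD_TABLE` carries the published per-class partition of the real
dataset (test / training / validation / original-training counts) and
:func:`rpdd_manifest` expands it into a record-level manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SynthSpec", "DatasetManifest", "ManifestRecord", "RPDD_CLASSES",
    "RPDD_TABLE", "RPDD_TOTALS", "rpdd_manifest", "rpdd_original_counts", "generate_synthetic_dataset", "partition",
    "read_manifest", "write_manifest", "load_images",
]

SPLITS = ("train", "val", "test", "original_train")

RPDD_CLASSES = (
    "White-backed Planthopper", "Rice Water Weevil", "Rice Leaf-roller",
    "Rice Blast", "Rice Tungro Spherical Virus", "Helminthosporium Leaf Spot",
    "Bacterial Leaf Streak",
)

# Per-class (test, train, val, original_train) counts of the published
# seven-class rice pest/disease partition.
RPDD_TABLE: dict[str, tuple[int, int, int, int]] = {
    "White-backed Planthopper": (139, 2496, 139, 416),
    "Rice Water Weevil": (139, 2490, 138, 415),
    "Rice Leaf-roller": (165, 2970, 165, 495),
    "Rice Blast": (337, 2018, 337, 1009),
    "Rice Tungro Spherical Virus": (210, 3150, 210, 630),
    "Helminthosporium Leaf Spot": (187, 2800, 187, 560),
    "Bacterial Leaf Streak": (165, 2465, 165, 493),
}


@dataclass(frozen=True)
class ManifestRecord:
    class_name: str
    split: str
    path: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.class_name, None)
        return list(seen)

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-class, per-split record counts."""
        out: dict[str, dict[str, int]] = {}
        for r in self.records:
            out.setdefault(r.class_name, {}).setdefault(r.split, 0)
            out[r.class_name][r.split] += 1
        return out

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def validate_files(self, root: str | Path = ".") -> list[str]:
        """Paths referenced by the manifest that do not exist on disk."""
        root = Path(root)
        return [r.path for r in self.records if not (root / r.path).is_file()]


def rpdd_manifest() -> DatasetManifest:
    """Record-level manifest reproducing every cell of the published partition.

    Paths are synthetic placeholders (the images themselves are not
    redistributable); counts per class and split are the published ones.
    """
    records = []
    for cls, (test, train, val, orig) in RPDD_TABLE.items():
        slug = cls.lower().replace(" ", "_").replace("-", "_")
        for split, n in (("test", test), ("train", train), ("val", val)):
            records.extend(
                ManifestRecord(cls, split, f"rpdd/{slug}/{split}_{i:05d}.png")
                for i in range(n))
    return DatasetManifest(records)


def rpdd_original_counts() -> dict[str, int]:
    """Per-class raw training-image counts before class balancing."""
    return {cls: orig for cls, (_, _, _, orig) in RPDD_TABLE.items()}


# printed per-class totals of the published partition (= test + train + val)
RPDD_TOTALS: dict[str, int] = {
    "White-backed Planthopper": 2774, "Rice Water Weevil": 2767,
    "Rice Leaf-roller": 3300, "Rice Blast": 2692,
    "Rice Tungro Spherical Virus": 3570, "Helminthosporium Leaf Spot": 3174,
    "Bacterial Leaf Streak": 2795,
}


# ---------------------------------------------------------------------
# synthetic image generation
# ---------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Recipe for a K-class separable synthetic image set.

    Each class gets a distinct motif parameter tuple (hue centre, motif
    kind/density, stripe frequency); ``noise_sigma`` is i.i.d. pixel noise
    on the 0-1 intensity scale.
    """

    num_classes: int = 4
    n_per_class: int = 200
    image_size: int = 64
    seed: int = 0
    noise_sigma: float = 0.06

    def class_params(self) -> list[dict]:
        """Deterministic, pairwise-distinct motif parameters per class."""
        params = []
        for k in range(self.num_classes):
            params.append({
                "hue": (0.08 + 0.71 * k / max(self.num_classes - 1, 1)),
                "motif": ("lesion", "stripes", "spots")[k % 3],
                "density": 3 + 2 * (k % 4),
                "stripe_freq": 2 + k,
            })
        return params


def _hsv_to_rgb(h, s, v):
    from matplotlib.colors import hsv_to_rgb

    return hsv_to_rgb(np.stack([h, s, v], axis=-1))


def _render_image(rng: np.random.Generator, params: dict, size: int,
                  noise_sigma: float) -> np.ndarray:
    """One (size, size, 3) uint8 image: hued textured background + motifs."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    # low-frequency background texture in the class hue band
    phase = rng.uniform(0, 2 * np.pi, 4)
    tex = (np.sin(2 * np.pi * yy * rng.uniform(1, 3) + phase[0])
           + np.sin(2 * np.pi * xx * rng.uniform(1, 3) + phase[1])) / 4 + 0.5
    hue = np.clip(params["hue"] + 0.05 * (tex - 0.5), 0, 1)
    val = 0.45 + 0.35 * tex
    sat = np.full_like(val, 0.65)
    img = _hsv_to_rgb(hue, sat, val)
    # class motifs
    kind, dens = params["motif"], params["density"]
    if kind == "stripes":
        stripes = np.sin(2 * np.pi * params["stripe_freq"]
                         * (xx + 0.3 * yy) + rng.uniform(0, 2 * np.pi)) > 0.4
        img[stripes] = img[stripes] * 0.45 + np.array([0.35, 0.25, 0.08]) * 0.55
    else:
        for _ in range(dens):
            cy, cx = rng.uniform(0.15, 0.85, 2)
            ry = rng.uniform(0.04, 0.12)
            rx = ry * (rng.uniform(1.5, 3.0) if kind == "lesion" else 1.0)
            mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1
            col = (np.array([0.45, 0.30, 0.10]) if kind == "lesion"
                   else np.array([0.12, 0.10, 0.08]))
            img[mask] = img[mask] * 0.35 + col * 0.65
    img = img + rng.normal(0, noise_sigma, img.shape)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def generate_synthetic_dataset(spec: SynthSpec, out_dir: str | Path) -> DatasetManifest:
    """Write class-per-directory PNGs and return their manifest.

    Deterministic for a given spec (one child RNG per class keeps images
    independent of generation order).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    params = spec.class_params()
    for k in range(spec.num_classes):
        cls = f"class_{k}"
        cls_dir = out_dir / cls
        cls_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng([spec.seed, k])
        for i in range(spec.n_per_class):
            img = _render_image(rng, params[k], spec.image_size, spec.noise_sigma)
            rel = f"{cls}/img_{i:04d}.png"
            Image.fromarray(img).save(out_dir / rel)
            records.append(ManifestRecord(cls, "train", str(out_dir / rel)))
    return DatasetManifest(records)


# ---------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------

def partition(manifest: DatasetManifest, ratios: tuple[int, int, int] = (6, 2, 2),
              seed: int = 0) -> DatasetManifest:
    """Per-class shuffled train/val/test split honouring ``ratios``.

    Counts follow largest-remainder rounding with remainder preference
    train > val > test; splits are disjoint and exhaustive.  A class with
    fewer images than splits degenerates (with a warning) to train.
    """
    import warnings

    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if not manifest.records:
        raise ValueError("empty manifest")
    total_r = sum(ratios)
    rng = np.random.default_rng(seed)
    out: list[ManifestRecord] = []
    by_class: dict[str, list[ManifestRecord]] = {}
    for r in manifest.records:
        by_class.setdefault(r.class_name, []).append(r)
    for cls, recs in by_class.items():
        n = len(recs)
        order = rng.permutation(n)
        if n < 3:
            warnings.warn(f"class {cls!r} has only {n} image(s); all assigned to train")
            out.extend(ManifestRecord(cls, "train", recs[i].path) for i in order)
            continue
        exact = [n * r / total_r for r in ratios]
        counts = [int(e) for e in exact]
        remainders = [e - c for e, c in zip(exact, counts)]
        # hand out leftover slots by largest remainder, ties to earlier splits
        for _ in range(n - sum(counts)):
            best = max(range(3), key=lambda i: (remainders[i], -i))
            counts[best] += 1
            remainders[best] = -1.0
        splits = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
        out.extend(ManifestRecord(cls, s, recs[i].path)
                   for s, i in zip(splits, order))
    return DatasetManifest(out)


# ---------------------------------------------------------------------
# manifest I/O and image loading
# ---------------------------------------------------------------------

def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_name", "split", "path"])
        for r in manifest.records:
            writer.writerow([r.class_name, r.split, r.path])


def read_manifest(path: str | Path) -> DatasetManifest:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["class_name", "split", "path"]:
            raise ValueError(f"{path}: unexpected manifest header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            cls, split, p = row
            if split not in SPLITS:
                raise ValueError(f"{path}:{lineno}: unknown split {split!r}")
            records.append(ManifestRecord(cls, split, p))
    return DatasetManifest(records)


def load_images(manifest: DatasetManifest, image_size: int | None = None,
                root: str | Path = ".") -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load manifest images as (N, 3, H, W) float32 in [0, 1] plus labels.

    PNG/JPEG accepted; images are resized with bilinear interpolation when
    ``image_size`` is given.  Returns (images, integer labels, class names).
    """
    classes = manifest.class_names
    index = {c: i for i, c in enumerate(classes)}
    imgs, labels = [], []
    root = Path(root)
    for r in manifest.records:
        p = root / r.path
        with Image.open(p) as im:
            im = im.convert("RGB")
            if image_size is not None and im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            imgs.append(np.asarray(im, dtype=np.float32) / 255.0)
        labels.append(index[r.class_name])
    x = np.stack(imgs).transpose(0, 3, 1, 2)
    return x, np.asarray(labels, dtype=np.int64), classes
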