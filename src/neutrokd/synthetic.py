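"""Procedural generation of balanced retina-like RGB image datasets.

Each image is a dark-red circular fundus-like background with low-contrast
texture (so CLAHE has something to enhance), a bright elliptical optic-disk
analogue, random-walk vessel-like curves, and a class-conditional lesion
motif.  The healthy analogue class carries no lesion motif.  The generator is
fully deterministic under its seed and produces exactly balanced classes, so
every downstream stage (preprocessing, training, evaluation, explanation) can
be exercised without the real ultra-widefield fundus dataset the pipeline is
designed for (seven balanced classes of 100 images each).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from sklearn.model_selection import train_test_split

__all__ = [
    "SyntheticSpec",
    "LabeledImageSet",
    "LESION_MOTIFS",
    "generate",
    "stratified_split",
    "write_to_disk",
    "read_from_disk",
]

#: Lesion motifs in fixed class-index order; index 2 is the healthy analogue.
LESION_MOTIFS = (
    "bright_blobs",
    "dark_blobs",
    "healthy",
    "diffuse_haze",
    "peripheral_arc",
    "central_ring",
    "streaks",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated dataset (balanced K-class layout)."""

    n_classes: int = 7
    images_per_class: int = 100
    image_size: int = 96
    seed: int = 0
    noise_sigma: float = 0.08
    class_separability: float = 0.8

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 <= self.noise_sigma <= 1.0:
            raise ValueError("noise_sigma must lie in [0, 1]")
        if not 0.0 < self.class_separability <= 1.0:
            raise ValueError("class_separability must lie in (0, 1]")


@dataclass
class LabeledImageSet:
    """Images plus integer labels; the unit consumed by training/evaluation."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    provenance: str = "synthetic"
    filenames: list[str] | None = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and not set(np.unique(self.labels)) <= set(range(len(self.class_names))):
            raise ValueError("labels must index class_names")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices)
        return LabeledImageSet(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            provenance=self.provenance,
            filenames=None if self.filenames is None else [self.filenames[i] for i in indices],
        )


def _grid(size: int):
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    return (y - c) / c, (x - c) / c  # normalized to roughly [-1, 1]


def _soft_disc(yy, xx, cy, cx, ry, rx, softness=0.15):
    d = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    return np.clip((1.0 - d) / softness, 0.0, 1.0)


def _render_image(rng: np.random.Generator, spec: SyntheticSpec, motif: str) -> np.ndarray:
    size = spec.image_size
    yy, xx = _grid(size)
    r = np.sqrt(yy**2 + xx**2)
    img = np.zeros((size, size, 3), dtype=np.float64)

    # fundus-like dark-red radial background inside a circular aperture
    aperture = np.clip((0.98 - r) / 0.06, 0.0, 1.0)
    shade = (1.0 - 0.45 * r**2) * aperture
    img[..., 0] = 95.0 * shade
    img[..., 1] = 42.0 * shade
    img[..., 2] = 30.0 * shade

    # low-contrast smooth texture so CLAHE measurably changes local contrast
    tex = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 24.0)
    tex = tex / (np.abs(tex).max() + 1e-9)
    img += (6.0 * tex * aperture)[..., None] * np.array([1.0, 0.8, 0.5])

    # optic-disk analogue: bright ellipse off-center
    cy, cx = rng.uniform(-0.35, 0.35, 2)
    ry = rng.uniform(0.10, 0.16)
    disk = _soft_disc(yy, xx, cy, cx, ry, ry * rng.uniform(1.0, 1.4))
    img += disk[..., None] * np.array([95.0, 80.0, 40.0])

    # vessel-like dark random-walk curves leaving the disk
    vessel = np.zeros((size, size))
    c = (size - 1) / 2.0
    for _ in range(rng.integers(3, 6)):
        py, px = cy * c + c, cx * c + c
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(size * 1.2)):
            ang += rng.normal(0.0, 0.25)
            py += np.sin(ang)
            px += np.cos(ang)
            iy, ix = int(round(py)), int(round(px))
            if not (0 <= iy < size and 0 <= ix < size):
                break
            vessel[max(iy - 1, 0) : iy + 1, max(ix - 1, 0) : ix + 1] = 1.0
    vessel = gaussian_filter(vessel, 0.6)
    img -= (vessel * aperture)[..., None] * np.array([38.0, 22.0, 10.0])

    # class-conditional lesion motif, scaled by the separability setting
    s = spec.class_separability
    if motif == "bright_blobs":
        for _ in range(rng.integers(3, 7)):
            by, bx = rng.uniform(-0.6, 0.6, 2)
            blob = _soft_disc(yy, xx, by, bx, rng.uniform(0.04, 0.09), rng.uniform(0.04, 0.09))
            img += (s * blob)[..., None] * np.array([120.0, 110.0, 30.0])
    elif motif == "dark_blobs":
        for _ in range(rng.integers(3, 7)):
            by, bx = rng.uniform(-0.6, 0.6, 2)
            blob = _soft_disc(yy, xx, by, bx, rng.uniform(0.05, 0.10), rng.uniform(0.05, 0.10))
            img -= (s * blob)[..., None] * np.array([70.0, 32.0, 22.0])
    elif motif == "diffuse_haze":
        hy, hx = rng.uniform(-0.4, 0.4, 2)
        haze = _soft_disc(yy, xx, hy, hx, 0.8, 0.8, softness=0.9)
        img += (0.45 * s * haze * aperture)[..., None] * np.array([70.0, 70.0, 75.0])
    elif motif == "peripheral_arc":
        a0 = rng.uniform(0, 2 * np.pi)
        ang = np.arctan2(yy, xx)
        dang = np.abs((ang - a0 + np.pi) % (2 * np.pi) - np.pi)
        band = np.exp(-(((r - 0.75) / 0.10) ** 2)) * (dang < rng.uniform(0.9, 1.4))
        img += (s * band * aperture)[..., None] * np.array([110.0, 95.0, 45.0])
    elif motif == "central_ring":
        ring = np.exp(-(((r - rng.uniform(0.22, 0.32)) / 0.06) ** 2))
        img += (s * ring)[..., None] * np.array([100.0, 85.0, 40.0])
    elif motif == "streaks":
        for _ in range(rng.integers(3, 6)):
            a = rng.uniform(0, np.pi)
            off = rng.uniform(-0.5, 0.5)
            dist = np.abs(np.cos(a) * yy - np.sin(a) * xx - off)
            along = np.abs(np.sin(a) * yy + np.cos(a) * xx) < rng.uniform(0.3, 0.7)
            img += (s * np.exp(-((dist / 0.03) ** 2)) * along * aperture)[..., None] * np.array(
                [105.0, 95.0, 35.0]
            )
    elif motif == "healthy":
        pass
    else:  # pragma: no cover - motif list is fixed
        raise ValueError(f"unknown motif {motif!r}")

    img += rng.normal(0.0, spec.noise_sigma * 255.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def motif_for_class(class_index: int) -> str:
    """Fixed motif assignment; cycles for more than seven classes."""
    return LESION_MOTIFS[class_index % len(LESION_MOTIFS)]


def generate(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate a balanced synthetic dataset deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    class_names = [f"class{k}_{motif_for_class(k)}" for k in range(spec.n_classes)]
    for k in range(spec.n_classes):
        motif = motif_for_class(k)
        for _ in range(spec.images_per_class):
            images.append(_render_image(rng, spec, motif))
            labels.append(k)
    return LabeledImageSet(images, np.array(labels), class_names, provenance="synthetic")


def stratified_split(
    dataset: LabeledImageSet, test_fraction: float, seed: int
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Class-stratified train/test partition, deterministic under the seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    counts = np.bincount(dataset.labels, minlength=dataset.n_classes)
    if np.any((counts > 0) & (counts < 2)):
        raise ValueError("every represented class needs >= 2 images to stratify")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=int(seed), stratify=dataset.labels
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def write_to_disk(dataset: LabeledImageSet, directory) -> None:
    """Class-per-subdirectory PNG layout plus a ``labels.csv`` manifest."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {name: 0 for name in dataset.class_names}
    for img, label in zip(dataset.images, dataset.labels):
        name = dataset.class_names[label]
        (root / name).mkdir(exist_ok=True)
        fname = f"{name}/{counters[name]:04d}.png"
        counters[name] += 1
        Image.fromarray(img).save(root / fname)
        rows.append((fname, int(label), name))
    with open(root / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "class_name"])
        writer.writerows(rows)


def read_from_disk(directory) -> LabeledImageSet:
    """Read a dataset written by :func:`write_to_disk` (PNG or JPEG images)."""
    root = Path(directory)
    manifest = root / "labels.csv"
    images, labels, filenames = [], [], []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            rows = list(csv.DictReader(fh))
        class_names = sorted({row["class_name"] for row in rows})
        name_to_label = {n: i for i, n in enumerate(class_names)}
        for row in rows:
            images.append(np.asarray(Image.open(root / row["filename"]).convert("RGB")))
            labels.append(name_to_label[row["class_name"]])
            filenames.append(row["filename"])
    else:
        class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
        if not class_dirs:
            raise ValueError(f"no class subdirectories under {root}")
        class_names = [p.name for p in class_dirs]
        for label, cdir in enumerate(class_dirs):
            for f in sorted(cdir.iterdir()):
                if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                    images.append(np.asarray(Image.open(f).convert("RGB")))
                    labels.append(label)
                    filenames.append(f"{cdir.name}/{f.name}")
    return LabeledImageSet(
        images, np.array(labels), class_names, provenance="disk", filenames=filenames
    )
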