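"""Synthetic fundus-like image datasets for exercising the searches.

Real severity grading of diabetic retinopathy rests on counting and sizing
small bright lesions (microaneurysms, exudates) on the retinal disc.  The
generator emulates exactly that monotone structure: a class-``k`` image is
a dark background with a circular "retina" disc, one bright optic-disc
ellipse, and exactly ``k`` small high-intensity lesion blobs at
non-overlapping random positions inside the disc, plus additive Gaussian
pixel noise.  Severity is therefore lesion count, an analytically known
ground truth — which is what makes search-quality tests possible without
any download.

Class imbalance defaults to the 5-class APTOS-style proportions
1805 : 370 : 999 : 193 : 295.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SynthSpec",
    "SynthDataset",
    "APTOS_PROPORTIONS",
    "generate_image",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "blob_count_oracle",
]

#: APTOS-style class counts (No DR, Mild, Moderate, Severe, Proliferative).
APTOS_COUNTS = (1805, 370, 999, 193, 295)
APTOS_PROPORTIONS = tuple(c / sum(APTOS_COUNTS) for c in APTOS_COUNTS)


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters for a 5-class toy fundus dataset."""

    n_total: int = 600
    n_classes: int = 5
    image_size: int = 64  # pixels, square
    noise_sigma: float = 0.02  # additive Gaussian, on the [0,1] pixel scale
    class_proportions: tuple[float, ...] = APTOS_PROPORTIONS
    lesion_intensity: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < self.n_classes:
            raise ValueError("need at least one sample per class")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("one proportion per class required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SynthDataset:
    images: np.ndarray  # (n, H, W, 3) float32 in [0, 1]
    labels: np.ndarray  # (n,) int class indices
    manifest: list[str]  # per-image id_code strings
    blob_coords: list[list[tuple[int, int]]] = field(default_factory=list)


def _disc_geometry(size: int, rng: np.random.Generator):
    """Retina disc + optic-disc ellipse parameters."""
    cx = size / 2 + rng.uniform(-0.02, 0.02) * size
    cy = size / 2 + rng.uniform(-0.02, 0.02) * size
    radius = 0.45 * size
    # optic disc sits off-centre on the horizontal axis
    ox = cx + rng.choice((-1, 1)) * 0.22 * size
    oy = cy + rng.uniform(-0.05, 0.05) * size
    return cx, cy, radius, ox, oy


def generate_image(
    class_k: int, spec: SynthSpec, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Render one class-``k`` image; returns (image, lesion centres).

    The image is (H, W, 3) float32 on [0, 1].  Exactly ``k`` lesion blobs
    are placed by rejection sampling at non-overlapping positions inside
    the retinal disc (away from the optic disc), then Gaussian noise of
    ``spec.noise_sigma`` is added and the result clipped to [0, 1].
    """
    if not 0 <= class_k < spec.n_classes:
        raise ValueError(f"class index {class_k} outside 0..{spec.n_classes - 1}")
    rng = np.random.default_rng(rng)
    size = spec.image_size
    blob_r = max(1.6, 0.05 * size)
    if class_k * (3 * blob_r) ** 2 > (0.8 * size) ** 2:
        raise ValueError(f"image of size {size} too small to place {class_k} blobs")

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    cx, cy, radius, ox, oy = _disc_geometry(size, rng)
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    disc = d2 <= radius**2

    img = np.zeros((size, size, 3), dtype=np.float32)
    # reddish-brown retina with a gentle radial falloff
    base = 1.0 - 0.4 * np.sqrt(d2) / radius
    img[..., 0] += disc * 0.55 * base
    img[..., 1] += disc * 0.28 * base
    img[..., 2] += disc * 0.12 * base

    # bright yellowish optic-disc ellipse
    od = ((xx - ox) / (0.10 * size)) ** 2 + ((yy - oy) / (0.13 * size)) ** 2 <= 1.0
    od &= disc
    img[..., 0][od] = 0.92
    img[..., 1][od] = 0.82
    img[..., 2][od] = 0.45

    coords: list[tuple[int, int]] = []
    tries = 0
    while len(coords) < class_k:
        tries += 1
        if tries > 10_000:
            raise ValueError(
                f"could not place {class_k} non-overlapping blobs at size {size}"
            )
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.15, 0.85) * radius
        bx, by = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        if ((bx - ox) / (0.14 * size)) ** 2 + ((by - oy) / (0.17 * size)) ** 2 <= 1.0:
            continue  # keep lesions off the optic disc
        if any((bx - px) ** 2 + (by - py) ** 2 < (3 * blob_r) ** 2 for px, py in coords):
            continue
        coords.append((bx, by))
        # hard-exudate-like lesions: bright, near-white, unlike the yellow
        # optic disc (blue channel is the discriminating cue)
        blob = np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * blob_r**2)))
        img[..., 0] += spec.lesion_intensity * blob
        img[..., 1] += spec.lesion_intensity * 0.95 * blob
        img[..., 2] += spec.lesion_intensity * 0.9 * blob

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0).astype(np.float32), [
        (int(round(x)), int(round(y))) for x, y in coords
    ]


def _largest_remainder(n_total: int, proportions: tuple[float, ...]) -> list[int]:
    raw = [n_total * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    short = n_total - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in order[:short]:
        counts[int(i)] += 1
    return counts


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    """Generate a full shuffled dataset; deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    counts = _largest_remainder(spec.n_total, tuple(spec.class_proportions))
    if any(c == 0 for c in counts):
        raise ValueError(f"class counts {counts} contain an empty class")
    labels = np.repeat(np.arange(spec.n_classes), counts)
    order = rng.permutation(spec.n_total)
    labels = labels[order]
    images = np.empty((spec.n_total, spec.image_size, spec.image_size, 3), np.float32)
    blob_coords: list[list[tuple[int, int]]] = []
    for i, k in enumerate(labels):
        images[i], coords = generate_image(int(k), spec, rng)
        blob_coords.append(coords)
    manifest = [f"synth_{i:05d}" for i in range(spec.n_total)]
    return SynthDataset(images, labels.astype(np.int64), manifest, blob_coords)


def blob_count_oracle(ds: SynthDataset) -> np.ndarray:
    """Ground-truth classifier: the stored lesion count IS the class."""
    return np.array([len(c) for c in ds.blob_coords])


def write_dataset(ds: SynthDataset, out_dir: str) -> str:
    """Write one 8-bit PNG per image plus an ``id_code,diagnosis`` CSV.

    Returns the CSV path.
    """
    os.makedirs(out_dir, exist_ok=True)
    for img, id_code in zip(ds.images, ds.manifest):
        arr = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(out_dir, f"{id_code}.png"))
    csv_path = os.path.join(out_dir, "labels.csv")
    pd.DataFrame({"id_code": ds.manifest, "diagnosis": ds.labels}).to_csv(
        csv_path, index=False
    )
    return csv_path


def read_dataset(
    image_dir: str, csv_path: str, image_size: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load an APTOS-dialect directory (PNGs + id_code,diagnosis CSV).

    Images are optionally resized (bilinear) and scaled to [0, 1].
    """
    df = pd.read_csv(csv_path)
    if list(df.columns[:2]) != ["id_code", "diagnosis"]:
        raise ValueError("labels CSV must have header id_code,diagnosis")
    images, labels, ids = [], [], []
    for id_code, diag in zip(df["id_code"], df["diagnosis"]):
        path = os.path.join(image_dir, f"{id_code}.png")
        if not os.path.exists(path):
            raise FileNotFoundError(f"image for id_code {id_code!r} missing: {path}")
        im = Image.open(path).convert("RGB")
        if image_size is not None and im.size != (image_size, image_size):
            im = im.resize((image_size, image_size), Image.BILINEAR)
        images.append(np.asarray(im, dtype=np.float32) / 255.0)
        labels.append(int(diag))
        ids.append(str(id_code))
    return np.stack(images), np.asarray(labels, dtype=np.int64), ids


def easy_profile(
    n_total: int = 600, image_size: int = 32, noise_sigma: float = 0.02, seed: int = 0
) -> SynthSpec:
    """The separable desk-scale profile: uniform classes, low noise."""
    k = 5
    return SynthSpec(
        n_total=n_total,
        n_classes=k,
        image_size=image_size,
        noise_sigma=noise_sigma,
        class_proportions=tuple([1.0 / k] * k),
        rng_seed=seed,
    )
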