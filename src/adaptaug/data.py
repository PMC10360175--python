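"""Synthetic leaf/rust image generation, dataset splitting and on-disk layout.

A generated scene is a single elliptical leaf on a contrasting background with
zero or more reddish-orange rust spots rendered fully inside the leaf.  Exact
pixel masks for the leaf and for the rust spots accompany every image, so the
generator doubles as ground truth for both the feature extractor and the
segmentation backends.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk, ellipse

__all__ = [
    "LabeledImage",
    "ImageVector",
    "GeneratorConfig",
    "generate_leaf_image",
    "generate_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class LabeledImage:
    """An RGB image with its rust mask and leaf mask.

    ``image`` is H×W×3 uint8; ``rust_label`` and ``leaf_label`` are H×W uint8
    rasters over {0, 1}.  Rust pixels are a subset of leaf pixels for
    generated data.  ``id`` is a stable string identifier that survives
    augmentation and dataset round-trips.
    """

    image: np.ndarray
    rust_label: np.ndarray
    leaf_label: np.ndarray
    id: str

    def __post_init__(self) -> None:
        img, rust, leaf = self.image, self.rust_label, self.leaf_label
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"image must be H×W×3, got {img.shape}")
        if rust.shape != img.shape[:2] or leaf.shape != img.shape[:2]:
            raise ValueError("label rasters must match image height/width")
        for name, lab in (("rust_label", rust), ("leaf_label", leaf)):
            vals = np.unique(lab)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} must contain only {{0,1}}, got {vals}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def label(self, target: str) -> np.ndarray:
        if target == "rust":
            return self.rust_label
        if target == "leaf":
            return self.leaf_label
        raise ValueError(f"unknown label target {target!r}")


@dataclass(frozen=True)
class ImageVector:
    """An ordered sequence of labelled images with positional identity.

    Position i of a child vector is derived from position i of its father, so
    order is part of the data.  ``generation_index`` counts augmentation
    rounds (0 for an original dataset).
    """

    items: tuple[LabeledImage, ...]
    generation_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if self.generation_index < 0:
            raise ValueError("generation_index must be >= 0")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[LabeledImage]:
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(item.id for item in self.items)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic leaf/rust scene generator.

    ``image_size`` defaults to 64 px (desk scale); 512 mirrors the source
    imagery resolution.  Hues are mean RGB triples; each image draws its own
    per-region hue offset uniform in ±``hue_shift`` (lighting/variety
    variation between photographs) and each pixel a further uniform jitter
    of ±``hue_jitter`` (texture).  Both are deliberately large enough that
    the foreground/background colour distributions overlap across images —
    a segmentation model must generalize, not memorize one colour.  The same
    (config, seed) always produces a bit-identical dataset; per-image random
    streams are derived independently from the root seed so generation order
    does not matter.
    """

    image_size: int = 64
    n_images: int = 20
    rust_spot_count_range: tuple[int, int] = (0, 4)
    rust_spot_radius_range: tuple[float, float] = (1.5, 4.0)
    leaf_axis_range: tuple[float, float] = (0.28, 0.45)  # fraction of image size
    leaf_hue: tuple[int, int, int] = (60, 140, 50)
    rust_hue: tuple[int, int, int] = (190, 100, 40)
    background_hue: tuple[int, int, int] = (30, 30, 35)
    hue_jitter: int = 30
    hue_shift: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        lo, hi = self.rust_spot_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid rust_spot_count_range")

    def rng_for(self, index: int) -> np.random.Generator:
        """Independent stream for image ``index`` (order-independent)."""
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(index,)))
        )


def _fill_hue(rng: np.random.Generator, mask: np.ndarray,
              canvas: np.ndarray, hue: Sequence[int], jitter: int) -> None:
    n = int(mask.sum())
    noise = rng.integers(-jitter, jitter + 1, size=(n, 3))
    vals = np.clip(np.asarray(hue)[None, :] + noise, 0, 255).astype(np.uint8)
    canvas[mask] = vals


def generate_leaf_image(config: GeneratorConfig, index: int) -> LabeledImage:
    """Render one synthetic scene: elliptical leaf + rust spot discs + masks.

    Spots are rejected-sampled until fully inside the leaf; if a spot cannot
    be placed after a bounded number of attempts the config is inconsistent
    (leaf too small for the requested spot radii) and a ValueError is raised.
    """
    if index >= config.n_images:
        raise ValueError(f"index {index} out of range for n_images={config.n_images}")
    rng = config.rng_for(index)
    size = config.image_size
    shape = (size, size)

    lo, hi = config.leaf_axis_range
    a = rng.uniform(lo, hi) * size
    b = rng.uniform(lo, hi) * size
    # keep the whole leaf in frame
    margin = max(a, b) + 1
    cy = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
    cx = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
    theta = rng.uniform(0.0, math.pi)

    leaf_mask = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(cy, cx, a, b, shape=shape, rotation=theta)
    leaf_mask[rr, cc] = True

    n_spots = int(rng.integers(config.rust_spot_count_range[0],
                               config.rust_spot_count_range[1] + 1))
    rust_mask = np.zeros(shape, dtype=bool)
    leaf_rows, leaf_cols = np.nonzero(leaf_mask)
    for _ in range(n_spots):
        placed = False
        for _attempt in range(200):
            r = rng.uniform(*config.rust_spot_radius_range)
            k = int(rng.integers(len(leaf_rows)))
            sy, sx = int(leaf_rows[k]), int(leaf_cols[k])
            rr, cc = disk((sy, sx), r, shape=shape)
            if leaf_mask[rr, cc].all():
                rust_mask[rr, cc] = True
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place a rust spot inside the leaf; "
                "leaf_axis_range too small for rust_spot_radius_range"
            )

    canvas = np.empty((size, size, 3), dtype=np.uint8)
    regions = (
        (~leaf_mask, config.background_hue),
        (leaf_mask & ~rust_mask, config.leaf_hue),
        (rust_mask, config.rust_hue),
    )
    for mask, hue in regions:
        shifted = np.clip(
            np.asarray(hue) + rng.integers(-config.hue_shift,
                                           config.hue_shift + 1, size=3),
            0, 255)
        _fill_hue(rng, mask, canvas, shifted, config.hue_jitter)

    width = max(4, len(str(config.n_images)))
    return LabeledImage(
        image=canvas,
        rust_label=rust_mask.astype(np.uint8),
        leaf_label=leaf_mask.astype(np.uint8),
        id=f"img{index:0{width}d}",
    )


def generate_dataset(config: GeneratorConfig) -> ImageVector:
    """Generate ``config.n_images`` scenes with sequential zero-padded ids."""
    items = [generate_leaf_image(config, i) for i in range(config.n_images)]
    return ImageVector(items=tuple(items), generation_index=0)


def split_dataset(images: ImageVector, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[ImageVector, ImageVector]:
    """Random train/test split; an image never separates from its labels.

    The test size is round-half-up of ``test_fraction * n`` (438 images at
    0.2 give the canonical 350/88 split).  Sampling is without replacement
    and seeded.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(images)
    if n == 0:
        raise ValueError("cannot split an empty image vector")
    n_test = int(math.floor(test_fraction * n + 0.5))
    n_train = n - n_test
    if n_test == 0 or n_train == 0:
        raise ValueError(f"split of {n} images at {test_fraction} leaves an empty side")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    pretrain = ImageVector(items=tuple(images[i] for i in train_idx))
    test = ImageVector(items=tuple(images[i] for i in test_idx))
    return pretrain, test


# ---------------------------------------------------------------------------
# On-disk layout: images/<id>.png, rust_labels/<id>.png, leaf_labels/<id>.png,
# manifest.tsv (id, image_path, rust_label_path, leaf_label_path).


def save_dataset(vec: ImageVector, out_dir: str) -> str:
    """Write PNGs plus a manifest.tsv; returns the manifest path."""
    rows = []
    for sub in ("images", "rust_labels", "leaf_labels"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for item in vec:
        paths = {
            "image_path": os.path.join("images", f"{item.id}.png"),
            "rust_label_path": os.path.join("rust_labels", f"{item.id}.png"),
            "leaf_label_path": os.path.join("leaf_labels", f"{item.id}.png"),
        }
        Image.fromarray(item.image).save(os.path.join(out_dir, paths["image_path"]))
        # store labels as 0/255 so they are viewable; normalized on read
        Image.fromarray(item.rust_label * 255).save(
            os.path.join(out_dir, paths["rust_label_path"]))
        Image.fromarray(item.leaf_label * 255).save(
            os.path.join(out_dir, paths["leaf_label_path"]))
        rows.append({"id": item.id, **paths})
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def _read_label(path: str) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(f"label file {path} has values outside {{0,1,255}}: {vals}")
    return (arr > 0).astype(np.uint8)


def load_dataset(in_dir: str) -> ImageVector:
    """Read a dataset directory written by :func:`save_dataset`.

    Labels stored as {0,255} are normalized to {0,1}.
    """
    manifest = os.path.join(in_dir, "manifest.tsv")
    if not os.path.exists(manifest):
        raise FileNotFoundError(f"no manifest.tsv under {in_dir}")
    table = pd.read_csv(manifest, sep="\t", dtype=str)
    items = []
    for row in table.itertuples():
        image = np.asarray(Image.open(os.path.join(in_dir, row.image_path)).convert("RGB"))
        items.append(LabeledImage(
            image=image,
            rust_label=_read_label(os.path.join(in_dir, row.rust_label_path)),
            leaf_label=_read_label(os.path.join(in_dir, row.leaf_label_path)),
            id=str(row.id),
        ))
    return ImageVector(items=tuple(items), generation_index=0)
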