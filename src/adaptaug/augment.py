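"""The eight augmentation actions, applied identically to image and masks.

Action set:

====  ==========================  =======================================
id    name                        effect
====  ==========================  =======================================
0     original                    identity copy
1     vflip                       mirror top<->bottom
2     hflip                       mirror left<->right
3     vhflip                      both flips (180° point reflection)
4     rotate30                    30° clockwise about the image centre
5     affine_shear                forward map x' = x + 0.2*y, y' = y
6     crop_resize                 drop the first 25 rows/columns, resize back
7     gauss_noise                 additive white Gaussian noise, image only
====  ==========================  =======================================

Geometric actions (1-6) move image and both label masks through the identical
coordinate map; the image is resampled bilinearly, labels with nearest
neighbour so they stay binary.  Out-of-frame regions are filled with 0
(black / background).  The noise action perturbs only the image; labels pass
through bit-identically.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, rotate, warp

from .data import ImageVector, LabeledImage

__all__ = [
    "N_ACTIONS",
    "ACTION_NAMES",
    "CROP_MARGIN",
    "NOISE_SIGMA",
    "apply_action",
    "apply_action_vector",
    "action_name",
]

N_ACTIONS = 8
ACTION_NAMES = (
    "original",
    "vflip",
    "hflip",
    "vhflip",
    "rotate30",
    "affine_shear",
    "crop_resize",
    "gauss_noise",
)
ROTATION_DEG = 30.0          # clockwise
SHEAR_MATRIX = np.array([[1.0, 0.2, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
CROP_MARGIN = 25             # rows and columns trimmed before resizing back
NOISE_SIGMA = 35.0           # 8-bit scale; at the synthetic texture-jitter scale


def action_name(action: int) -> str:
    _check_action(action)
    return ACTION_NAMES[action]


def _check_action(action: int) -> None:
    if not 0 <= int(action) < N_ACTIONS:
        raise ValueError(f"unknown action {action}; valid ids are 0..{N_ACTIONS - 1}")


def _warp_image(img: np.ndarray, tform: AffineTransform) -> np.ndarray:
    # warp() expects the inverse (output->input) map, hence tform.inverse
    out = warp(img.astype(float), tform.inverse, order=1, cval=0.0,
               preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _warp_label(lab: np.ndarray, tform: AffineTransform) -> np.ndarray:
    out = warp(lab.astype(float), tform.inverse, order=0, cval=0.0,
               preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def _rotate_pair(img: np.ndarray, labels: Sequence[np.ndarray]):
    # skimage's positive angle is counter-clockwise; pass the negative
    out_img = rotate(img.astype(float), -ROTATION_DEG, resize=False, order=1,
                     cval=0.0, preserve_range=True)
    out_img = np.clip(np.rint(out_img), 0, 255).astype(np.uint8)
    out_labels = [
        (rotate(lab.astype(float), -ROTATION_DEG, resize=False, order=0,
                cval=0.0, preserve_range=True) > 0.5).astype(np.uint8)
        for lab in labels
    ]
    return out_img, out_labels


def _crop_resize_pair(img: np.ndarray, labels: Sequence[np.ndarray]):
    h, w = img.shape[:2]
    if h <= CROP_MARGIN or w <= CROP_MARGIN:
        raise ValueError(
            f"crop needs height and width > {CROP_MARGIN}, got {h}×{w}")
    out_img = resize(img[CROP_MARGIN:, CROP_MARGIN:].astype(float), (h, w),
                     order=1, preserve_range=True, anti_aliasing=False)
    out_img = np.clip(np.rint(out_img), 0, 255).astype(np.uint8)
    out_labels = [
        (resize(lab[CROP_MARGIN:, CROP_MARGIN:].astype(float), (h, w),
                order=0, preserve_range=True, anti_aliasing=False) > 0.5
         ).astype(np.uint8)
        for lab in labels
    ]
    return out_img, out_labels


def apply_action(item: LabeledImage, action: int,
                 noise_rng: np.random.Generator | None = None,
                 noise_sigma: float = NOISE_SIGMA) -> LabeledImage:
    """Apply one augmentation action to an image and its two label masks.

    ``noise_rng`` is only consulted by action 7; pass a seeded generator for
    reproducible noise.  Output dimensions always equal input dimensions.
    """
    _check_action(action)
    img = item.image
    labels = (item.rust_label, item.leaf_label)

    if action == 0:
        out_img, out_labels = img.copy(), [lab.copy() for lab in labels]
    elif action == 1:
        out_img = img[::-1].copy()
        out_labels = [lab[::-1].copy() for lab in labels]
    elif action == 2:
        out_img = img[:, ::-1].copy()
        out_labels = [lab[:, ::-1].copy() for lab in labels]
    elif action == 3:
        out_img = img[::-1, ::-1].copy()
        out_labels = [lab[::-1, ::-1].copy() for lab in labels]
    elif action == 4:
        out_img, out_labels = _rotate_pair(img, labels)
    elif action == 5:
        tform = AffineTransform(matrix=SHEAR_MATRIX)
        out_img = _warp_image(img, tform)
        out_labels = [_warp_label(lab, tform) for lab in labels]
    elif action == 6:
        out_img, out_labels = _crop_resize_pair(img, labels)
    else:  # action == 7
        if noise_rng is None:
            noise_rng = np.random.default_rng(0)
        noise = noise_rng.normal(0.0, noise_sigma, size=img.shape)
        out_img = np.clip(np.rint(img.astype(float) + noise), 0, 255).astype(np.uint8)
        out_labels = [lab.copy() for lab in labels]

    return LabeledImage(image=out_img, rust_label=out_labels[0],
                        leaf_label=out_labels[1], id=item.id)


def apply_action_vector(vec: ImageVector, actions: Sequence[int],
                        noise_rng: np.random.Generator | None = None,
                        noise_sigma: float = NOISE_SIGMA) -> ImageVector:
    """Augment every image of a vector with its own action.

    Element i of the child is produced from element i of the father, so the
    father/child positional correspondence is preserved; the child's
    generation index is the father's plus one.
    """
    actions = list(actions)
    if len(actions) != len(vec):
        raise ValueError(
            f"action vector length {len(actions)} != image vector length {len(vec)}")
    if noise_rng is None:
        noise_rng = np.random.default_rng(0)
    children = [apply_action(item, a, noise_rng=noise_rng, noise_sigma=noise_sigma)
                for item, a in zip(vec, actions)]
    return ImageVector(items=tuple(children),
                       generation_index=vec.generation_index + 1)
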