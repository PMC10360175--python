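"""The eight augmentation actions and their invariants."""

import numpy as np
import pytest

import adaptaug as aa
from adaptaug.augment import N_ACTIONS, apply_action, apply_action_vector
from adaptaug.data import GeneratorConfig, ImageVector, LabeledImage


def _item(seed=0, size=64):
    cfg = GeneratorConfig(image_size=size, n_images=2, seed=seed)
    return aa.generate_leaf_image(cfg, 0)


def _marker_item(size=64, markers=()):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    for (row, col) in markers:
        img[row, col] = 255
    zeros = np.zeros((size, size), dtype=np.uint8)
    return LabeledImage(image=img, rust_label=zeros.copy(),
                        leaf_label=zeros.copy(), id="marker")


def _equal(a: LabeledImage, b: LabeledImage) -> bool:
    return ((a.image == b.image).all() and (a.rust_label == b.rust_label).all()
            and (a.leaf_label == b.leaf_label).all())


def test_action_zero_is_identity():
    item = _item()
    assert _equal(apply_action(item, 0), item)


@pytest.mark.parametrize("flip", [1, 2])
def test_flips_are_involutions(flip):
    item = _item(seed=1)
    assert _equal(apply_action(apply_action(item, flip), flip), item)


def test_double_flip_equals_composition():
    item = _item(seed=2)
    both = apply_action(item, 3)
    composed = apply_action(apply_action(item, 1), 2)
    assert _equal(both, composed)


@pytest.mark.parametrize("flip", [1, 2, 3])
def test_flips_conserve_pixel_multiset(flip):
    item = _item(seed=3)
    out = apply_action(item, flip)
    assert np.array_equal(np.sort(item.image, axis=None),
                          np.sort(out.image, axis=None))
    assert out.rust_label.sum() == item.rust_label.sum()
    assert out.leaf_label.sum() == item.leaf_label.sum()


def test_shear_displaces_markers_by_fifth_of_row():
    # forward map x' = x + 0.2*y: a marker on row y moves 0.2*y columns right
    markers = [(10, 5), (20, 5), (40, 5)]
    out = apply_action(_marker_item(markers=markers), 5)
    for (row, col) in markers:
        ys, xs = np.nonzero(out.image[:, :, 0] > 127)
        found = [(y, x) for y, x in zip(ys, xs) if y == row]
        assert len(found) == 1
        assert abs(found[0][1] - (col + 0.2 * row)) <= 1.0


def test_rotation_is_thirty_degrees_clockwise_about_center():
    size = 64
    c = (size - 1) / 2
    row, col = 5, 32
    out = apply_action(_marker_item(size, [(row, col)]), 4)
    ys, xs = np.nonzero(out.image[:, :, 0] > 50)
    assert len(ys) > 0
    got = (ys.mean(), xs.mean())
    theta = np.deg2rad(30.0)
    dx, dy = col - c, row - c
    # clockwise in display coordinates (y axis points down)
    want = (c + dx * np.sin(theta) + dy * np.cos(theta),
            c + dx * np.cos(theta) - dy * np.sin(theta))
    assert abs(got[0] - want[0]) <= 1.5 and abs(got[1] - want[1]) <= 1.5


def test_crop_requires_large_enough_image():
    small = _marker_item(size=25)
    with pytest.raises(ValueError, match="crop"):
        apply_action(small, 6)


def test_crop_moves_content_toward_origin():
    # the pixel at (25, 25) becomes the new top-left corner before resizing
    out = apply_action(_marker_item(64, [(25, 25)]), 6)
    ys, xs = np.nonzero(out.image[:, :, 0] > 50)
    assert ys.min() <= 1 and xs.min() <= 1


@pytest.mark.parametrize("action", range(N_ACTIONS))
def test_all_actions_preserve_dimensions_and_binary_labels(action):
    item = _item(seed=4)
    out = apply_action(item, action, noise_rng=np.random.default_rng(1))
    assert out.image.shape == item.image.shape
    assert set(np.unique(out.rust_label)) <= {0, 1}
    assert set(np.unique(out.leaf_label)) <= {0, 1}
    assert out.id == item.id


@pytest.mark.parametrize("action", [1, 2, 3, 4, 5, 6])
def test_geometric_actions_keep_rust_inside_leaf(action):
    # the same coordinate map moves both masks, so subset-ness survives
    item = _item(seed=5)
    out = apply_action(item, action)
    assert (out.rust_label <= out.leaf_label).all()


@pytest.mark.parametrize("action", [1, 2, 3, 4, 5, 6])
def test_label_image_cotransformation(action):
    # encoding a mask in the image channels and transforming it must agree
    # with transforming the mask itself
    item = _item(seed=6)
    encoded = LabeledImage(image=np.stack([item.rust_label * 255] * 3, axis=-1),
                           rust_label=item.rust_label,
                           leaf_label=item.leaf_label, id="enc")
    out = apply_action(encoded, action)
    mask_from_image = (out.image[:, :, 0] > 127).astype(np.uint8)
    assert np.mean(mask_from_image == out.rust_label) > 0.995


def test_noise_perturbs_image_only_with_zero_mean():
    item = _item(seed=7, size=64)
    rng = np.random.default_rng(42)
    out = apply_action(item, 7, noise_rng=rng, noise_sigma=10.0)
    assert (out.rust_label == item.rust_label).all()
    assert (out.leaf_label == item.leaf_label).all()
    assert not (out.image == item.image).all()
    diff = out.image.astype(float) - item.image.astype(float)
    se = 10.0 / np.sqrt(diff.size)
    assert abs(diff.mean()) < 3 * se + 0.5  # clipping adds a small bias


def test_noise_is_reproducible_under_seed():
    item = _item(seed=8)
    a = apply_action(item, 7, noise_rng=np.random.default_rng(5))
    b = apply_action(item, 7, noise_rng=np.random.default_rng(5))
    assert _equal(a, b)


def test_unknown_action_raises():
    with pytest.raises(ValueError, match="unknown action"):
        apply_action(_item(), 8)


def test_vector_application_preserves_positions():
    cfg = GeneratorConfig(image_size=64, n_images=2, seed=9)
    vec = aa.generate_dataset(cfg)
    child = apply_action_vector(vec, [1, 2])
    assert child.generation_index == vec.generation_index + 1
    assert _equal(child[0], apply_action(vec[0], 1))
    assert _equal(child[1], apply_action(vec[1], 2))


def test_vector_identity_and_determinism():
    cfg = GeneratorConfig(image_size=64, n_images=3, seed=10)
    vec = aa.generate_dataset(cfg)
    same = apply_action_vector(vec, [0, 0, 0])
    assert all(_equal(a, b) for a, b in zip(same, vec))
    a = apply_action_vector(vec, [7, 4, 7], noise_rng=np.random.default_rng(3))
    b = apply_action_vector(vec, [7, 4, 7], noise_rng=np.random.default_rng(3))
    assert all(_equal(x, y) for x, y in zip(a, b))


def test_vector_length_mismatch_raises():
    cfg = GeneratorConfig(image_size=64, n_images=2, seed=11)
    vec = aa.generate_dataset(cfg)
    with pytest.raises(ValueError, match="length"):
        apply_action_vector(vec, [0])
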