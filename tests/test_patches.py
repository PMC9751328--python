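"""Patch extraction, object masks, labels and splits."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semssl.patches import (MultiLabel, Patch, SplitPlan, derive_labels,
                            extract_patches, make_object_masks, save_patches,
                            split_dataset, label_table)
from semssl.synthetic import SceneSpec, generate_image
from semssl.types import AnnotatedImage, ClassLabel, ImageMeta


def _image(h, w):
    return AnnotatedImage(pixels=np.arange(h * w, dtype=np.uint64).reshape(h, w)
                          .astype(np.uint8),
                          annotation=np.zeros((h, w), np.uint8))


def _brute_force_count(H, W, k, s):
    return sum(1 for r in range(0, H - k + 1, s) for c in range(0, W - k + 1, s))


def test_single_window_when_kernel_equals_image():
    patches = extract_patches(_image(128, 128), kernel=128, stride=64)
    assert len(patches) == 1
    assert patches[0].origin == (0, 0)


def test_nonoverlapping_tiling_count():
    assert len(extract_patches(_image(256, 256), 128, 128)) == 4


def test_kernel_larger_than_image_rejected():
    with pytest.raises(ValueError, match="kernel"):
        extract_patches(_image(64, 64), kernel=65, stride=8)


def test_patch_count_matches_brute_force_on_random_geometries():
    rng = np.random.default_rng(0)
    for _ in range(50):
        H, W = rng.integers(20, 200, 2)
        k = int(rng.integers(4, min(H, W) + 1))
        s = int(rng.integers(1, k + 1))
        got = len(extract_patches(_image(H, W), k, s))
        rows = (H - k) // s + 1
        cols = (W - k) // s + 1
        assert got == _brute_force_count(H, W, k, s) == rows * cols


def test_average_of_overlapping_patches_reconstructs_interior():
    img = _image(96, 96)
    k, s = 32, 16
    patches = extract_patches(img, k, s)
    acc = np.zeros(img.pixels.shape)
    cnt = np.zeros(img.pixels.shape)
    for p in patches:
        r, c = p.origin
        acc[r:r + k, c:c + k] += p.pixels
        cnt[r:r + k, c:c + k] += 1
    recon = acc / cnt
    np.testing.assert_allclose(recon, img.pixels.astype(float))


def test_object_masks_partition_patch(small_image):
    patch = extract_patches(small_image, 64, 64)[0]
    masks = make_object_masks(patch)
    support = {c: masks[c].pixels > 0 for c in masks}
    union = np.zeros_like(patch.pixels, bool)
    for c, sup in support.items():
        # nonzero pixels belong to the target class
        assert (patch.annotation[sup] == int(c)).all()
        assert not (union & sup).any()          # pairwise disjoint
        union |= sup
    # union covers every source pixel that is nonzero
    np.testing.assert_array_equal(union, patch.pixels > 0)


def test_all_surface_patch_masks(flat_image):
    patch = extract_patches(flat_image, 32, 32)[0]
    masks = make_object_masks(patch)
    assert np.array_equal(masks[ClassLabel.SURFACE].pixels, patch.pixels)
    assert (masks[ClassLabel.CELL].pixels == 0).all()
    assert (masks[ClassLabel.BYPRODUCT].pixels == 0).all()


def test_derive_labels_pure_class():
    ann = np.zeros((16, 16), np.uint8)          # all surface
    lab = derive_labels(ann, 0.01)
    assert lab == MultiLabel(byproduct=False, cell=False, surface=True)


def test_derive_labels_threshold_counting():
    ann = np.zeros((50, 50), np.uint8)
    ann[:1, :10] = int(ClassLabel.CELL)          # 10/2500 = 0.4% cell
    assert derive_labels(ann, 0.01).cell is False
    assert derive_labels(ann, 0.001).cell is True
    assert derive_labels(ann, 0.0).cell is True  # a single pixel suffices


@given(frac1=st.floats(0, 0.99), frac2=st.floats(0, 0.99))
@settings(max_examples=50, deadline=None)
def test_derive_labels_monotone_in_threshold(frac1, frac2):
    rng = np.random.default_rng(9)
    ann = rng.integers(0, 3, (20, 20)).astype(np.uint8)
    lo, hi = sorted((frac1, frac2))
    flags_lo = derive_labels(ann, lo).as_array()
    flags_hi = derive_labels(ann, hi).as_array()
    # raising the threshold can only clear flags, never set them
    assert not (flags_hi & ~flags_lo).any()


def test_split_sizes_and_determinism(small_image):
    patches = extract_patches(small_image, 16, 12)
    patches = patches[:100]
    plan = SplitPlan(seed=5)
    s1 = split_dataset(patches, plan)
    s2 = split_dataset(patches, plan)
    assert s1 == s2
    assert len(s1["repr"]) == 80
    assert len(s1["finetune"]) == 10
    assert len(s1["test"]) == 10
    all_idx = sorted(s1["repr"] + s1["finetune"] + s1["test"])
    assert all_idx == list(range(100))


def test_split_fraction_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SplitPlan(repr_fraction=0.9, finetune_fraction=0.2,
                  test_fraction=0.1).validate()


def test_split_too_few_patches_for_folds(small_image):
    patches = extract_patches(small_image, 64, 64)[:5]
    with pytest.raises(ValueError, match="folds"):
        split_dataset(patches, SplitPlan(folds=10))


def test_spatial_block_split_has_no_cross_pool_pixel_sharing(small_spec):
    imgs = [generate_image(dataclasses.replace(small_spec), seed=s)
            for s in range(6)]
    for i, img in enumerate(imgs):
        img.source_id = f"img{i}"
    patches = [p for img in imgs for p in extract_patches(img, 32, 16)]
    splits = split_dataset(patches, SplitPlan(strategy="spatial_block", seed=1))

    def windows(idx):
        return {(patches[i].source_id, patches[i].origin) for i in idx}

    def overlap(a, b):
        (sa, (ra, ca)), (sb, (rb, cb)) = a, b
        return (sa == sb and ra < rb + 32 and rb < ra + 32
                and ca < cb + 32 and cb < ca + 32)

    test_w = windows(splits["test"])
    for pool in ("finetune", "repr"):
        for wa in windows(splits[pool]):
            assert not any(overlap(wa, wb) for wb in test_w)


def test_label_table_layout(small_image):
    patches = extract_patches(small_image, 32, 32)
    labels = [derive_labels(p.annotation) for p in patches]
    table = label_table(patches, labels)
    assert list(table.columns) == ["source_id", "row", "col", "kernel",
                                   "byproduct", "cell", "surface", "split",
                                   "fold"]
    assert len(table) == len(patches)


def test_save_patches_writes_one_png_per_patch(small_image, tmp_path):
    patches = extract_patches(small_image, 64, 64)
    paths = save_patches(patches, tmp_path)
    assert len(paths) == len(patches)
    assert all(p.endswith(".png") for p in paths)
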