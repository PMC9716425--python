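"""Augmentation protocol, 1x1 meal heads, and top-1 accuracy."""

import warnings

import numpy as np
import pytest

from platevision import synthetic
from platevision.autoencoder import extract_features
from platevision.exceptions import MissingClassError
from platevision.meal import (HeadHyperparams, apply_transform,
                              augment_references, classify, top1_accuracy,
                              train_head)
from platevision.resolution import block_mean, center_sample


def _tiny_reference(tiny_meal, tiny_geometry, factor=2, seed=19):
    scene = synthetic.render_plate(tiny_meal, [1.0] * len(tiny_meal),
                                   tiny_geometry, noise_sd=0.0, seed=seed)
    return (block_mean(scene.rgb, factor),
            center_sample(scene.truth_class_map, factor))


# ------------------------------------------------------------ augmentation
def test_default_augmentation_count_is_300(tiny_meal, tiny_geometry):
    ref = _tiny_reference(tiny_meal, tiny_geometry, factor=4)
    out = augment_references([ref], seed=1)
    assert len(out) == 300
    assert all(rgb.shape[:2] == lab.shape for rgb, lab in out)


def test_identity_transform_keeps_label_map(tiny_meal, tiny_geometry):
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry)
    out_rgb, out_lab = apply_transform(rgb, lab, False, False, 0.0, 1.0)
    assert np.array_equal(out_lab, lab)
    np.testing.assert_allclose(out_rgb, np.clip(rgb / 255.0, 0, 1), atol=1e-6)


def test_quarter_turn_matches_exhaustive_index_oracle():
    rng = np.random.default_rng(8)
    lab = rng.integers(0, 4, size=(9, 9))
    rgb = rng.uniform(size=(9, 9, 3))
    _, out = apply_transform(rgb, lab, False, False, 90.0, 1.0)
    h = lab.shape[0]
    expect = np.empty_like(lab)
    for r in range(h):
        for c in range(h):
            expect[r, c] = lab[c, h - 1 - r]
    assert np.array_equal(out, expect)


def test_augmentation_is_deterministic_given_seed(tiny_meal, tiny_geometry):
    ref = _tiny_reference(tiny_meal, tiny_geometry, factor=4)
    a = augment_references([ref], n_augment=12, seed=5)
    b = augment_references([ref], n_augment=12, seed=5)
    for (ra, la), (rb, lb) in zip(a, b):
        assert np.array_equal(ra, rb) and np.array_equal(la, lb)


# ------------------------------------------------------------- head training
@pytest.fixture(scope="module")
def tiny_head(tiny_extractor, tiny_meal, tiny_geometry):
    ref = _tiny_reference(tiny_meal, tiny_geometry)
    aug = augment_references([ref], n_augment=60, seed=3)
    hp = HeadHyperparams(max_epochs=120, seed=3)
    class_ids = [s.class_id for s in tiny_meal]
    return train_head(tiny_extractor, aug, class_ids, hp)


def test_head_has_one_kernel_per_class(tiny_head, tiny_meal):
    assert tiny_head.n_classes == len(tiny_meal)
    assert tiny_head.n_params == 17 * len(tiny_meal)  # 16 weights + bias each


def test_head_training_leaves_extractor_frozen(tiny_extractor, tiny_meal,
                                               tiny_geometry):
    ref = _tiny_reference(tiny_meal, tiny_geometry)
    aug = augment_references([ref], n_augment=20, seed=9)
    before = tiny_extractor.checksum()
    train_head(tiny_extractor, aug, [s.class_id for s in tiny_meal],
               HeadHyperparams(max_epochs=10, seed=1))
    assert tiny_extractor.checksum() == before


def test_background_perturbation_cannot_reach_the_loss(tiny_extractor,
                                                       tiny_meal, tiny_geometry):
    """Masked inputs make features — hence the head loss — exactly invariant
    to background content."""
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry)
    mask = lab > 0
    rgb2 = rgb.copy()
    rgb2[~mask] = 0.5 * rgb2[~mask] + 17.0
    f1 = extract_features(tiny_extractor, rgb, mask)
    f2 = extract_features(tiny_extractor, rgb2, mask)
    assert np.array_equal(f1, f2)


def test_missing_class_is_rejected(tiny_extractor, tiny_meal, tiny_geometry):
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry)
    lab = lab.copy()
    lab[lab == tiny_meal[2].class_id] = 0  # erase one class everywhere
    with pytest.raises(MissingClassError):
        train_head(tiny_extractor, [(rgb, lab)],
                   [s.class_id for s in tiny_meal],
                   HeadHyperparams(max_epochs=5, seed=1))


def test_head_class_count_follows_menu_size(tiny_extractor, tiny_library,
                                            tiny_geometry):
    scenes = []
    for spec in tiny_library[:5]:
        scene = synthetic.render_plate([spec], [1.0], tiny_geometry,
                                       noise_sd=0.0, seed=spec.class_id)
        scenes.append((block_mean(scene.rgb, 2),
                       center_sample(scene.truth_class_map, 2)))
    head = train_head(tiny_extractor, scenes,
                      [s.class_id for s in tiny_library[:5]],
                      HeadHyperparams(max_epochs=5, seed=1))
    assert head.n_classes == 5


# ------------------------------------------------------------- inference
def test_classify_contract(tiny_head, tiny_extractor, tiny_meal, tiny_geometry):
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry, seed=23)
    mask = lab > 0
    feats = extract_features(tiny_extractor, rgb, mask)
    cmap = classify(tiny_head, feats, mask)
    # scores normalized per pixel
    np.testing.assert_allclose(cmap.scores.sum(axis=-1), 1.0, atol=1e-6)
    # labels only on mask pixels
    assert not cmap.labels[~mask].any()
    assert set(np.unique(cmap.labels[mask])) <= set(tiny_head.class_ids)
    # deterministic
    again = classify(tiny_head, feats, mask)
    assert np.array_equal(cmap.labels, again.labels)
    # and accurate on clean colours
    assert top1_accuracy(cmap, lab, mask) > 90.0


def test_classify_empty_mask_yields_background_only(tiny_head, tiny_extractor,
                                                    tiny_meal, tiny_geometry):
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry)
    feats = extract_features(tiny_extractor, rgb, np.zeros_like(lab, dtype=bool))
    cmap = classify(tiny_head, feats, np.zeros_like(lab, dtype=bool))
    assert not cmap.labels.any()


def test_single_class_meal_labels_every_food_pixel(tiny_extractor, tiny_library,
                                                   tiny_geometry):
    spec = tiny_library[0]
    scene = synthetic.render_plate([spec], [1.0], tiny_geometry, noise_sd=0.0,
                                   seed=29)
    rgb = block_mean(scene.rgb, 2)
    lab = center_sample(scene.truth_class_map, 2)
    mask = lab > 0
    aug = augment_references([(rgb, lab)], n_augment=8, seed=2)
    head = train_head(tiny_extractor, aug, [spec.class_id],
                      HeadHyperparams(max_epochs=5, seed=1))
    cmap = classify(head, extract_features(tiny_extractor, rgb, mask), mask)
    assert np.all(cmap.labels[mask] == spec.class_id)


def test_classify_rejects_channel_mismatch(tiny_head):
    with pytest.raises(ValueError):
        classify(tiny_head, np.zeros((8, 8, 7), dtype=np.float32),
                 np.ones((8, 8), dtype=bool))


def test_item_order_permutation_equivariance(tiny_extractor, tiny_meal,
                                             tiny_geometry):
    """Permuting the menu's item order permutes head channels but leaves the
    pixel decisions identical."""
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry)
    aug = augment_references([(rgb, lab)], n_augment=30, seed=4)
    ids = [s.class_id for s in tiny_meal]
    hp = HeadHyperparams(max_epochs=40, seed=6)
    h1 = train_head(tiny_extractor, aug, ids, hp)
    h2 = train_head(tiny_extractor, aug, ids[::-1], hp)
    mask = lab > 0
    feats = extract_features(tiny_extractor, rgb, mask)
    c1 = classify(h1, feats, mask)
    c2 = classify(h2, feats, mask)
    assert np.array_equal(c1.labels, c2.labels)
    np.testing.assert_allclose(c1.scores, c2.scores[..., ::-1], atol=1e-5)


def test_errors_concentrate_at_segment_edges(tiny_head, tiny_extractor,
                                             tiny_meal, tiny_geometry):
    """Misclassified pixels, when they occur, sit near segment boundaries."""
    from scipy import ndimage

    wrong = interior_wrong = boundary_wrong = 0
    interior_n = boundary_n = 0
    for seed in (41, 43, 47):
        scene = synthetic.render_plate(tiny_meal, [1.0, 0.75, 0.5],
                                       tiny_geometry, noise_sd=3.0, seed=seed)
        rgb = block_mean(scene.rgb, 2)
        lab = center_sample(scene.truth_class_map, 2)
        mask = lab > 0
        cmap = classify(tiny_head, extract_features(tiny_extractor, rgb, mask),
                        mask)
        err = (cmap.labels != lab) & mask
        interior = np.zeros_like(mask)
        for cid in np.unique(lab[mask]):
            interior |= ndimage.binary_erosion(lab == cid, iterations=3)
        boundary = mask & ~interior
        wrong += err.sum()
        interior_wrong += (err & interior).sum()
        boundary_wrong += (err & boundary).sum()
        interior_n += interior.sum()
        boundary_n += boundary.sum()
    if wrong == 0:
        return  # no errors at all: the property holds vacuously
    assert interior_wrong / max(interior_n, 1) <= boundary_wrong / max(boundary_n, 1)


# ------------------------------------------------------------- top-1 metric
def test_top1_accuracy_arithmetic():
    truth = np.array([[1, 1], [2, 2]])
    mask = np.ones((2, 2), dtype=bool)
    assert top1_accuracy(truth, truth, mask) == 100.0
    assert top1_accuracy(np.where(truth == 1, 2, 1), truth, mask) == 0.0
    pred = truth.copy()
    pred[0, 0] = 2  # 3 of 4 correct, by enumeration
    assert top1_accuracy(pred, truth, mask) == 75.0


def test_top1_accuracy_empty_mask_is_nan_with_warning():
    truth = np.ones((2, 2), dtype=int)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        out = top1_accuracy(truth, truth, np.zeros((2, 2), dtype=bool))
    assert np.isnan(out)
    assert any("undefined" in str(w.message) for w in rec)


def test_class_map_serialization(tiny_head, tiny_extractor, tiny_meal,
                                 tiny_geometry, tmp_path):
    rgb, lab = _tiny_reference(tiny_meal, tiny_geometry)
    mask = lab > 0
    cmap = classify(tiny_head, extract_features(tiny_extractor, rgb, mask), mask)
    cmap.save(tmp_path / "cmap")
    assert (tmp_path / "cmap" / "labels.png").exists()
    assert (tmp_path / "cmap" / "class_scores.csv").exists()
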