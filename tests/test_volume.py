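"""Volume integration, differential intake, and the intake error metrics."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

from platevision import imaging, synthetic
from platevision.imaging import HeightMap
from platevision.segmentation import FoodMask, iou
from platevision.volume import (VolumeEstimate, class_volume,
                                intake, intake_error_metrics, plate_volumes,
                                RESIDUAL_CLASS, UNDEFINED_FRACTION,
                                FRACTION_OUT_OF_RANGE)


def _flat_height_map(shape, value=0.0):
    h = np.full(shape, float(value))
    return HeightMap(heights=h, valid_mask=np.ones(shape, dtype=bool))


def _geometry(pixel_area=1.0):
    return dataclasses.replace(synthetic.PlateGeometry(), pixel_area=pixel_area)


def test_uniform_slab_closed_form():
    # 10 mm over 1000 px of 1 mm^2 -> 10 mL
    hm = _flat_height_map((40, 40))
    labels = np.zeros((40, 40), dtype=int)
    labels[:25, :40] = 1  # 1000 px
    hm.heights[labels == 1] = 10.0
    assert class_volume(hm, labels, _geometry(1.0), 1) == pytest.approx(10.0)


def test_absent_class_is_zero_with_warning():
    hm = _flat_height_map((8, 8))
    labels = np.zeros((8, 8), dtype=int)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        v = class_volume(hm, labels, _geometry(), 3)
    assert v == 0.0
    assert any("absent" in str(w.message) for w in rec)


def test_noiseless_scene_volumes_match_generator_truth(tiny_noiseless_scene,
                                                       tiny_geometry):
    """Oracle equivalence: truth masks + truth classes + noiseless depth
    reproduce generator truth within 1% for every profile type."""
    hm = imaging.calibrated_height_map(tiny_noiseless_scene)
    for cid, truth in tiny_noiseless_scene.truth_volumes.items():
        if truth == 0:
            continue
        est = class_volume(hm, tiny_noiseless_scene.truth_class_map,
                           tiny_geometry, cid)
        assert est == pytest.approx(truth, rel=0.01)


def test_plate_total_is_sum_of_classes(tiny_noiseless_scene, tiny_geometry):
    hm = imaging.calibrated_height_map(tiny_noiseless_scene)
    cids = list(tiny_noiseless_scene.truth_volumes)
    est = plate_volumes(hm, tiny_noiseless_scene.truth_class_map, tiny_geometry,
                        cids)
    assert est.total == pytest.approx(sum(est.volumes.values()), rel=1e-9)
    assert all(v >= 0 for v in est.volumes.values())


def test_residual_bucket_collects_unlabelled_food_pixels():
    hm = _flat_height_map((10, 10), 5.0)
    labels = np.zeros((10, 10), dtype=int)
    labels[:4] = 1
    food = np.ones((10, 10), dtype=bool)  # external mask larger than labels
    est = plate_volumes(hm, labels, _geometry(1.0), [1], food_mask=food)
    assert RESIDUAL_CLASS in est.volumes
    assert est.pixel_counts[RESIDUAL_CLASS] == 60


def test_intake_arithmetic_and_flags():
    rec = intake(VolumeEstimate({1: 200.0}), VolumeEstimate({1: 50.0}))
    item = rec.item(1)
    assert item.intake_ml == 150.0 and item.fraction == 0.75

    rec = intake(VolumeEstimate({1: 120.0}), VolumeEstimate({1: 120.0}))
    assert rec.item(1).intake_ml == 0.0 and rec.item(1).fraction == 0.0

    rec = intake(VolumeEstimate({1: 100.0}), VolumeEstimate({1: 130.0}))
    assert rec.item(1).fraction == pytest.approx(-0.3)
    assert FRACTION_OUT_OF_RANGE in rec.item(1).flags  # not clipped

    rec = intake(VolumeEstimate({1: 0.0}), VolumeEstimate({1: 10.0}))
    assert rec.item(1).fraction is None
    assert UNDEFINED_FRACTION in rec.item(1).flags


def test_intake_rejects_mismatched_class_sets():
    with pytest.raises(ValueError):
        intake(VolumeEstimate({1: 1.0}), VolumeEstimate({2: 1.0}))


def _record(est_full, est_left, truth_full, truth_left, plate="p"):
    rec = intake(VolumeEstimate({1: est_full}), VolumeEstimate({1: est_left}))
    rec.truth_full_ml = truth_full
    rec.truth_leftover_ml = truth_left
    rec.truth_intake_ml = truth_full - truth_left
    rec.plate_id = plate
    return rec


def test_error_metrics_match_hand_computation():
    """Ten plates with injected biases reproduce spreadsheet arithmetic."""
    rng = np.random.default_rng(17)
    recs, fv, ie, pe = [], [], [], []
    for i in range(10):
        truth_full = 200.0
        truth_left = float(rng.uniform(20, 180))
        bias_f = float(rng.normal(0, 5))
        bias_l = float(rng.normal(0, 5))
        recs.append(_record(truth_full + bias_f, truth_left + bias_l,
                            truth_full, truth_left, plate=str(i)))
        fv.append(bias_l)
        ie.append(bias_f - bias_l)
        pe.append(100.0 * (bias_f - bias_l) / truth_full)
    out = intake_error_metrics(recs)

    def mean_sd(xs):
        m = sum(xs) / len(xs)
        sd = math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))
        return m, sd

    for name, xs in (("food_volume_error_ml", fv), ("intake_error_ml", ie),
                     ("pct_intake_error", pe)):
        m, sd = mean_sd(xs)
        assert out[name][0] == pytest.approx(m, abs=1e-9)
        assert out[name][1] == pytest.approx(sd, abs=1e-9)
    m, sd = mean_sd([abs(x) for x in ie])
    assert out["absolute_intake_error_ml"][0] == pytest.approx(m, abs=1e-9)
    assert out["absolute_intake_error_ml"][1] == pytest.approx(sd, abs=1e-9)


def test_perfect_estimates_give_zero_metrics():
    recs = [_record(200.0, 80.0, 200.0, 80.0), _record(150.0, 30.0, 150.0, 30.0)]
    out = intake_error_metrics(recs)
    for k, v in out.items():
        if isinstance(v, tuple):
            assert v == (0.0, 0.0)


def test_single_plate_signed_definitions():
    # IN_hat = 90, IN = 100, V_full = 200 -> intake error -10 mL, 3D% -5%
    rec = _record(190.0, 100.0, 200.0, 100.0)  # est intake 90, true 100
    out = intake_error_metrics([rec])
    assert out["intake_error_ml"][0] == pytest.approx(-10.0)
    assert out["pct_intake_error"][0] == pytest.approx(-5.0)


def test_zero_full_volume_plate_excluded_with_warning():
    good = _record(100.0, 40.0, 100.0, 40.0)
    bad = _record(0.0, 0.0, 0.0, 0.0, plate="empty")
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        out = intake_error_metrics([good, bad])
    assert out["n_plates"] == 1
    assert any("excluded" in str(w.message) for w in rec)


def test_constant_height_bias_cancels_to_footprint_difference():
    """A constant height bias b on both plates changes intake volume by
    b x (footprint difference) only — closed form on slabs."""
    geometry = _geometry(1.0)
    shape = (30, 30)
    labels_full = np.zeros(shape, dtype=int)
    labels_full[:20, :20] = 1  # 400 px
    labels_left = np.zeros(shape, dtype=int)
    labels_left[:10, :10] = 1  # 100 px
    b = 0.75  # mm

    def vols(bias):
        hf = _flat_height_map(shape)
        hf.heights[labels_full == 1] = 12.0 + bias
        hl = _flat_height_map(shape)
        hl.heights[labels_left == 1] = 12.0 + bias
        vf = plate_volumes(hf, labels_full, geometry, [1])
        vl = plate_volumes(hl, labels_left, geometry, [1])
        return intake(vf, vl).intake_total_ml

    delta = vols(b) - vols(0.0)
    expect = b * (400 - 100) * geometry.pixel_area / 1000.0
    assert delta == pytest.approx(expect, rel=1e-9)


def test_occlusion_volume_error_positive_at_perfect_iou(tiny_geometry):
    """Overhang inflates estimated volume even when segmentation is perfect."""
    spec = dataclasses.replace(
        synthetic.generate_food_library(1, seed=13)[0],
        height_profile="slab", peak_height_mm=14.0, density_g_ml=0.9,
        full_portion_mass_g=90.0)
    scene = synthetic.render_plate([spec], [1.0], tiny_geometry, noise_sd=0.0,
                                   seed=13)
    occ = synthetic.inject_occlusion(scene, 0.4)
    truth_mask = FoodMask(occ.truth_food_mask, source="ground_truth")
    assert iou(truth_mask, FoodMask(occ.truth_class_map > 0)) == 1.0
    hm = imaging.calibrated_height_map(occ)
    est = class_volume(hm, occ.truth_class_map, tiny_geometry, spec.class_id)
    assert est - occ.truth_volumes[spec.class_id] > 0.0
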