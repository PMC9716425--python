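"""Ground-truth guarantees of the synthetic plate-scene generator."""

import dataclasses

import numpy as np
import pytest

from platevision import synthetic
from platevision.exceptions import PlacementError, UnsupportedSceneError


def test_library_is_deterministic_with_unique_ids():
    a = synthetic.generate_food_library(9, seed=42)
    b = synthetic.generate_food_library(9, seed=42)
    assert [s.to_dict() for s in a] == [s.to_dict() for s in b]
    assert sorted(s.class_id for s in a) == list(range(1, 10))
    colors = {tuple(np.round(s.base_color, 3)) for s in a}
    assert len(colors) == 9  # pairwise distinguishable colour parameters


def test_library_rejects_empty_request():
    with pytest.raises(ValueError):
        synthetic.generate_food_library(0, seed=1)


def test_single_food_minimal_library():
    lib = synthetic.generate_food_library(1, seed=0)
    assert len(lib) == 1 and lib[0].class_id == 1


def test_render_is_bit_identical_for_same_inputs(tiny_meal, tiny_geometry):
    a = synthetic.render_plate(tiny_meal, [1.0, 0.5, 0.25], tiny_geometry, seed=3)
    b = synthetic.render_plate(tiny_meal, [1.0, 0.5, 0.25], tiny_geometry, seed=3)
    assert np.array_equal(a.rgb, b.rgb)
    assert np.array_equal(a.depth_stack, b.depth_stack)
    assert np.array_equal(a.truth_class_map, b.truth_class_map)
    assert a.truth_volumes == b.truth_volumes


def test_scene_structure_invariants(tiny_scene, tiny_geometry):
    assert tiny_scene.depth_stack.shape[0] == synthetic.N_DEPTH_FRAMES
    # labelled pixels all inside the plate circle
    assert not (tiny_scene.truth_food_mask & ~tiny_geometry.plate_mask()).any()


def test_truth_volume_equals_fraction_times_full_portion(tiny_meal, tiny_geometry):
    fractions = [1.0, 0.5, 0.25]
    scene = synthetic.render_plate(tiny_meal, fractions, tiny_geometry, seed=3)
    for spec, frac in zip(tiny_meal, fractions):
        expect = frac * spec.full_portion_volume_ml
        assert scene.truth_volumes[spec.class_id] == pytest.approx(expect, rel=1e-9)
        # and the stated quadrature consistency with the rendered field
        sel = scene.truth_class_map == spec.class_id
        integral = scene.truth_heights[sel].sum() * tiny_geometry.pixel_area / 1000.0
        assert integral == pytest.approx(expect, rel=0.01)


def test_dome_volume_matches_fine_grid_quadrature_oracle(tiny_geometry):
    """The rendered dome's volume agrees with an independent fine-grid
    summation of the analytic height profile."""
    spec = dataclasses.replace(
        synthetic.generate_food_library(1, seed=5)[0],
        height_profile="dome", peak_height_mm=20.0, density_g_ml=1.0,
        full_portion_mass_g=120.0)
    scene = synthetic.render_plate([spec], [1.0], tiny_geometry, noise_sd=0.0, seed=2)
    r = synthetic.footprint_radius(spec, tiny_geometry)
    # independent oracle: quarter-pixel grid over the analytic paraboloid
    step = 0.25
    yy, xx = np.mgrid[-r - 1:r + 1:step, -r - 1:r + 1:step]
    d2 = yy ** 2 + xx ** 2
    h = np.where(d2 <= r * r, spec.peak_height_mm * (1 - d2 / (r * r)), 0.0)
    oracle_ml = h.sum() * step * step * tiny_geometry.pixel_area / 1000.0
    assert scene.truth_volumes[spec.class_id] == pytest.approx(oracle_ml, rel=0.01)


def test_zero_fractions_give_empty_plate(tiny_meal, tiny_geometry):
    scene = synthetic.render_plate(tiny_meal, [0, 0, 0], tiny_geometry, seed=3)
    assert not scene.truth_food_mask.any()
    assert all(v == 0.0 for v in scene.truth_volumes.values())


@pytest.mark.parametrize("frac", [0.25, 0.5, 0.75])
def test_fraction_linearity(tiny_meal, tiny_geometry, frac):
    full = synthetic.render_plate(tiny_meal, [1.0] * 3, tiny_geometry, seed=3)
    part = synthetic.render_plate(tiny_meal, [frac] * 3, tiny_geometry, seed=3)
    for spec in tiny_meal:
        assert part.truth_volumes[spec.class_id] == pytest.approx(
            frac * full.truth_volumes[spec.class_id], rel=0.02)


def test_depth_noise_sd_matches_request(tiny_meal, tiny_geometry):
    noise_sd = 3.0
    scene = synthetic.render_plate(tiny_meal, [1.0, 1.0, 1.0], tiny_geometry,
                                   noise_sd=noise_sd, seed=9)
    per_pixel_sd = scene.depth_stack.std(axis=0, ddof=1)
    assert per_pixel_sd.size >= 10_000
    assert float(per_pixel_sd.mean()) == pytest.approx(noise_sd, rel=0.20)


def test_rtf_permutation_series_enumerates_the_fraction_grid(tiny_meal, tiny_geometry):
    scenes = synthetic.simulate_intake_series(tiny_meal, "rtf_permutation",
                                              tiny_geometry, noise_sd=0.0, seed=4)
    assert len(scenes) == 5 ** 3
    fractions = {tuple(sorted(s.truth_fractions.values())) for s in scenes}
    assert len(fractions) > 30  # grid is actually swept


def test_mtf_series_lengths_and_single_step_identity(tiny_library, tiny_geometry):
    item = [tiny_library[1]]
    scenes = synthetic.simulate_intake_series(item, "mtf_steps", tiny_geometry,
                                              noise_sd=0.0, seed=4)
    assert len(scenes) == 5
    fr = [s.truth_fractions[item[0].class_id] for s in scenes]
    assert fr == [1.0, 0.75, 0.5, 0.25, 0.0]

    single = synthetic.simulate_intake_series(item, "mtf_steps", tiny_geometry,
                                              noise_sd=0.0, seed=4,
                                              fractions=[1.0])
    direct = synthetic.render_plate(
        item, [1.0], tiny_geometry, noise_sd=0.0,
        seed=synthetic.series_plate_seed(4, 0),
        centers=synthetic.place_items(item, tiny_geometry, 4))
    assert len(single) == 1
    assert np.array_equal(single[0].rgb, direct.rgb)
    assert np.array_equal(single[0].depth_stack, direct.depth_stack)


def test_series_input_validation(tiny_library, tiny_geometry):
    with pytest.raises(ValueError):
        synthetic.simulate_intake_series([], "rtf_permutation", tiny_geometry)
    with pytest.raises(ValueError):
        synthetic.simulate_intake_series([tiny_library[0]], "mtf_steps",
                                         tiny_geometry, fractions=[0.5, 0.25])
    with pytest.raises(ValueError):
        synthetic.simulate_intake_series([tiny_library[0]], "nonsense",
                                         tiny_geometry)


def test_placement_failure_raises(tiny_geometry):
    lib = synthetic.generate_food_library(3, seed=8, volume_range_ml=(3000, 3001))
    with pytest.raises(PlacementError):
        synthetic.render_plate(lib, [1.0] * 3, tiny_geometry, seed=0)


def _slab_scene(tiny_geometry, seed=12):
    spec = dataclasses.replace(
        synthetic.generate_food_library(1, seed=seed)[0],
        height_profile="slab", peak_height_mm=15.0, density_g_ml=0.8,
        full_portion_mass_g=80.0)
    return spec, synthetic.render_plate([spec], [1.0], tiny_geometry,
                                        noise_sd=0.0, seed=seed)


def test_occlusion_inflates_naive_volume_but_not_truth(tiny_geometry):
    spec, scene = _slab_scene(tiny_geometry)
    cid = spec.class_id
    truth = scene.truth_volumes[cid]
    assert synthetic.naive_pixel_volume(scene, cid) == pytest.approx(truth, rel=1e-6)

    occluded = synthetic.inject_occlusion(scene, 0.5)
    assert occluded.truth_volumes[cid] == truth  # rigid body: volume unchanged
    naive = synthetic.naive_pixel_volume(occluded, cid)
    assert naive > truth
    # quadrature oracle: inflation equals overhang area x lift
    lifted = (occluded.truth_heights > scene.truth_heights + 1e-6)
    lift = float(scene.truth_heights[scene.truth_class_map == cid].max())
    expect = lifted.sum() * lift * tiny_geometry.pixel_area / 1000.0
    assert naive - truth == pytest.approx(expect, rel=1e-5)


def test_occlusion_zero_overhang_is_identity(tiny_geometry):
    spec, scene = _slab_scene(tiny_geometry)
    out = synthetic.inject_occlusion(scene, 0.0)
    assert np.array_equal(out.depth_stack, scene.depth_stack)
    assert synthetic.naive_pixel_volume(out, spec.class_id) == pytest.approx(
        scene.truth_volumes[spec.class_id], rel=1e-6)


def test_occlusion_requires_a_slab(tiny_geometry):
    spec = dataclasses.replace(synthetic.generate_food_library(1, seed=3)[0],
                               height_profile="dome")
    scene = synthetic.render_plate([spec], [1.0], tiny_geometry, seed=3)
    with pytest.raises(UnsupportedSceneError):
        synthetic.inject_occlusion(scene, 0.3)


def test_scene_round_trip_on_disk(tiny_scene, tmp_path):
    synthetic.save_scene(tiny_scene, tmp_path / "s0")
    back = synthetic.load_scene(tmp_path / "s0")
    assert np.array_equal(back.rgb, tiny_scene.rgb)
    assert np.array_equal(back.truth_class_map, tiny_scene.truth_class_map)
    assert back.truth_volumes == tiny_scene.truth_volumes
    assert back.truth_fractions == tiny_scene.truth_fractions
    # depth survives 16-bit quantization
    assert np.abs(back.depth_stack - tiny_scene.depth_stack).max() <= 0.5 / 16.0
    assert [s.to_dict() for s in back.items] == [s.to_dict() for s in tiny_scene.items]


def test_dataset_manifest(tiny_scene, tmp_path):
    manifest = synthetic.save_dataset([tiny_scene, tiny_scene], tmp_path)
    assert len(manifest) == 2
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "scene_0000" / "rgb.png").exists()
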