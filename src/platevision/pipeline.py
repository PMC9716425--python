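"""End-to-end study runner: simulate -> train -> analyze -> validate -> report.

The pipeline mirrors a tray-to-nutrients deployment: a food library and meal
scenarios are simulated; the autoencoder feature extractor is trained once
on masked food imagery; a small food/no-food segmenter is trained; one 1x1
classification head is trained per meal from its full-portion references;
every evaluation plate is then pushed through depth averaging, plate
detection, segmentation, classification and per-class volume integration;
intake is the differential volume against the classified full-portion
reference, linked to the 13-nutrient panel; and the validation layer
summarises segmentation IOU, top-1 accuracy, bulk intake error, and
volume-vs-mass nutrient agreement.

Any stage can be switched to ground-truth inputs (`use_truth_masks`,
`use_truth_classes`) to decouple error sources.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, Field

from . import imaging, meal as meal_mod, nutrients as nutr, segmentation as seg_mod
from . import stats as stats_mod, synthetic, volume as vol_mod
from .autoencoder import (AutoencoderHyperparams, AutoencoderModel,
                          extract_features, train_autoencoder)
from .exceptions import DetectionError
from .resolution import block_mean, center_sample, upsample_nearest

DEFAULT_SCENARIO_CLASS_COUNTS = (3, 3, 3, 5, 5, 9, 10, 10, 12, 12, 15, 15)
MTF_STEP_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)


class GeometryConfig(BaseModel):
    image_height: int = 480
    image_width: int = 640
    plate_radius: float = 220.0
    plate_surface_depth: float = 1000.0
    depth_scale: float = 0.5
    pixel_area: float = 1.0 / 3.0

    def to_geometry(self) -> synthetic.PlateGeometry:
        return synthetic.PlateGeometry(
            image_height=self.image_height,
            image_width=self.image_width,
            plate_center=(self.image_height / 2.0, self.image_width / 2.0),
            plate_radius=self.plate_radius,
            plate_surface_depth=self.plate_surface_depth,
            depth_scale=self.depth_scale,
            pixel_area=self.pixel_area,
        )


class ExtractorConfig(BaseModel):
    lr: float = 1e-4
    batch_size: int = 32
    tol: float = 1e-4
    patience: int = 5
    max_epochs: int = 400
    n_images: int = 600
    train_height: int = 48
    train_width: int = 64


class SegmenterConfig(BaseModel):
    lr: float = 5e-3
    batch_size: int = 8
    tol: float = 1e-4
    patience: int = 5
    max_epochs: int = 200
    n_train: int = 60
    n_test: int = 40
    # the segmenter trains at working resolution / train_factor; colour-driven
    # food/no-food kernels transfer across scale, and the coarser grid keeps
    # CPU training cheap
    train_factor: int = 2


class HeadConfig(BaseModel):
    lr: float = 0.1
    batch_size: int = 32
    tol: float = 1e-5
    patience: int = 5
    max_epochs: int = 200
    n_augment: int = 300


class RunConfig(BaseModel):
    """Full configuration of a study run; every stochastic stage reads its
    seed from `seed` (sub-seeds are derived deterministically)."""

    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    working_factor: int = 4  # capture resolution / network resolution
    noise_sd: float = 3.0  # depth units per frame
    library_size: int = 76
    scenario_class_counts: list = Field(
        default_factory=lambda: list(DEFAULT_SCENARIO_CLASS_COUNTS))
    full_permutation_scenario: int = 2  # this 3-class meal is scored on all 125 plates
    eval_plates_per_meal: int = 12
    min_height_mm: float = 1.0
    use_truth_masks: bool = False
    use_truth_classes: bool = False
    extractor: ExtractorConfig = Field(default_factory=ExtractorConfig)
    segmenter: SegmenterConfig = Field(default_factory=SegmenterConfig)
    head: HeadConfig = Field(default_factory=HeadConfig)
    out_dir: str | None = None
    plots: bool = False

    def sub_seeds(self, n=64):
        state = np.random.SeedSequence(self.seed).generate_state(n)
        return [int(s) % (2 ** 31) for s in state]


@dataclass
class MealScenario:
    """One meal: its items, reference plates, and on-demand plate rendering.

    style "multi": all items share one plate; the intake series is every
    permutation of the 25% fraction grid. style "single": one item per
    plate, each item imaged as a progressive-removal series.
    """

    meal_id: str
    items: list
    style: str  # multi | single
    geometry: synthetic.PlateGeometry
    noise_sd: float
    seed: int
    plates: list = dc_field(default_factory=list)  # (item_index|None, fractions)
    _centers: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.style == "multi":
            grids = np.meshgrid(*([synthetic.RTF_FRACTION_GRID] * len(self.items)),
                                indexing="ij")
            combos = np.stack([g.ravel() for g in grids], axis=-1)
            self.plates = [(None, combo) for combo in combos]
            self._centers[None] = synthetic.place_items(self.items, self.geometry,
                                                        self.seed)
        else:
            for j, item in enumerate(self.items):
                self._centers[j] = synthetic.place_items([item], self.geometry,
                                                         (self.seed + 7919 * (j + 1))
                                                         % (2 ** 31))
                for frac in MTF_STEP_FRACTIONS:
                    self.plates.append((j, np.array([frac])))

    @property
    def n_plates(self):
        return len(self.plates)

    @property
    def class_ids(self):
        return tuple(s.class_id for s in self.items)

    def render(self, i) -> synthetic.PlateScene:
        item_idx, fractions = self.plates[i]
        meal = self.items if item_idx is None else [self.items[item_idx]]
        return synthetic.render_plate(
            meal, fractions, self.geometry, self.noise_sd,
            seed=synthetic.series_plate_seed(self.seed, i),
            centers=self._centers[item_idx])

    def reference_plates(self):
        """Full-portion reference scenes: one multi-item plate (multi) or one
        plate per item (single). Deterministic; placement matches the series."""
        refs = []
        if self.style == "multi":
            refs.append(synthetic.render_plate(
                self.items, np.ones(len(self.items)), self.geometry, self.noise_sd,
                seed=synthetic.series_plate_seed(self.seed, 99991),
                centers=self._centers[None]))
        else:
            for j, item in enumerate(self.items):
                refs.append(synthetic.render_plate(
                    [item], [1.0], self.geometry, self.noise_sd,
                    seed=synthetic.series_plate_seed(self.seed, 99991 + j),
                    centers=self._centers[j]))
        return refs

    def truth_full_volumes(self):
        return {s.class_id: s.full_portion_volume_ml for s in self.items}


def build_scenarios(library, class_counts, geometry, noise_sd, seeds):
    """Stratified meal construction: class counts as configured, items picked
    evenly around the hue-ordered library so colours stay separable."""
    n = len(library)
    scenarios = []
    for i, k in enumerate(class_counts):
        rng = np.random.default_rng([seeds[i], 41])
        offset = int(rng.integers(n))
        idx = sorted({(offset + round(j * n / k)) % n for j in range(k)})
        while len(idx) < k:  # rounding collisions on tiny libraries
            extra = int(rng.integers(n))
            if extra not in idx:
                idx = sorted(idx + [extra])
        items = [library[j] for j in idx]
        style = "multi" if k <= 3 else "single"
        if style == "multi":
            items = synthetic.scale_meal_to_plate(items, geometry)
        scenarios.append(MealScenario(
            meal_id=f"meal_{i + 1:02d}_{k}cls", items=items, style=style,
            geometry=geometry, noise_sd=noise_sd, seed=seeds[i]))
    return scenarios


@dataclass
class StudyResults:
    """Everything the validation layer reports for one study run."""

    per_meal: list  # dicts: meal_id, n_classes, n_plates, top1_pct
    mean_top1_pct: float
    full_perm_top1_pct: float | None
    seg_mean_iou: float | None
    intake_metrics: dict
    nutrient_results: dict  # nutrient -> (FitResult, AgreementResult)
    nutrient_pairs: dict  # nutrient -> (volume_path, mass_path) arrays
    min_r2: float
    max_abs_bias: float
    all_zero_within_loa: bool
    n_plates: int
    seed: int
    extractor_n_params: int = 0
    segmentation_rows: list = dc_field(default_factory=list)
    intake_records: list = dc_field(default_factory=list)


def _working(scene_or_rgb, factor, labels=False):
    if labels:
        return center_sample(scene_or_rgb, factor)
    return block_mean(scene_or_rgb, factor)


def _detect_geometry(rgb, geometry):
    """Detected plate circle with configured calibration; falls back to the
    configured circle if detection fails."""
    try:
        cy, cx, r = imaging.detect_plate(rgb)
        return dataclasses.replace(geometry, plate_center=(cy, cx), plate_radius=r)
    except DetectionError:
        return geometry


class TrainedSystem:
    """Frozen trained models plus per-meal heads and reference estimates."""

    def __init__(self, config: RunConfig):
        self.config = config
        seeds = config.sub_seeds()
        self.geometry = config.geometry.to_geometry()
        self.factor = config.working_factor
        self.library = synthetic.generate_food_library(config.library_size, seeds[0])
        self.scenarios = build_scenarios(
            self.library, config.scenario_class_counts, self.geometry,
            config.noise_sd, seeds=[seeds[6 + i] for i in
                                    range(len(config.scenario_class_counts))])
        self._seeds = seeds
        self.extractor: AutoencoderModel | None = None
        self.segmenter = None
        self.heads = {}
        self.reference_state = {}

    # ---- training ------------------------------------------------------
    def train_extractor(self):
        cfg = self.config.extractor
        rng = np.random.default_rng([self._seeds[1], 51])
        picks = rng.permutation(max(cfg.n_images, len(self.library)))[:cfg.n_images]
        images = []
        for j in picks:
            # depth is unused by the feature extractor: render noiseless
            # stacks to keep library generation cheap
            scene = synthetic.render_plate(
                [self.library[j % len(self.library)]],
                [float(rng.uniform(0.4, 1.0))], self.geometry, noise_sd=0.0,
                seed=int(rng.integers(2 ** 31)))
            images.append((scene.rgb, scene.truth_food_mask))
        hp = AutoencoderHyperparams(
            lr=cfg.lr, batch_size=cfg.batch_size, tol=cfg.tol, patience=cfg.patience,
            max_epochs=cfg.max_epochs, seed=self._seeds[2],
            train_shape=(cfg.train_height, cfg.train_width))
        self.extractor = train_autoencoder(images, hp)
        return self.extractor

    def _mixed_plates(self, n, rng):
        """Sample n plates across all scenarios (for segmenter train/test)."""
        out = []
        for _ in range(n):
            sc = self.scenarios[int(rng.integers(len(self.scenarios)))]
            out.append(sc.render(int(rng.integers(sc.n_plates))))
        return out

    def train_segmenter(self):
        """Train the food/no-food labeller.

        Training plates are sampled from the meal scenarios (the evaluation
        distribution) plus one single-food plate per library item: a colour
        that never appears in training goes unlearned without moving the
        validation loss, so coverage of every hue is guaranteed explicitly.
        """
        cfg = self.config.segmenter
        rng = np.random.default_rng([self._seeds[3], 52])
        train_fac = self.factor * cfg.train_factor
        scenes = self._mixed_plates(cfg.n_train, rng)
        for spec in self.library:  # one plate per food: full colour coverage
            scenes.append(synthetic.render_plate(
                [spec], [float(rng.uniform(0.3, 1.0))], self.geometry,
                self.config.noise_sd, seed=int(rng.integers(2 ** 31))))
        samples = []
        for scene in scenes:
            rgb_w = _working(scene.rgb, train_fac)
            mask_w = _working(scene.truth_food_mask, train_fac, labels=True)
            samples.append((rgb_w, mask_w))
        hp = seg_mod.SegmenterHyperparams(
            lr=cfg.lr, batch_size=cfg.batch_size, tol=cfg.tol, patience=cfg.patience,
            max_epochs=cfg.max_epochs, seed=self._seeds[4])
        self.segmenter = seg_mod.train_segmenter(samples, hp)
        return self.segmenter

    def heldout_segmentation_iou(self):
        """Mean IOU of the depth-refined segmenter on held-out mixed plates.

        The segmentation contract includes depth refinement (the binary
        labeller plus the calibrated-height threshold), so the held-out score
        is computed on the refined capture-resolution mask.
        """
        cfg = self.config.segmenter
        rng = np.random.default_rng([self._seeds[5], 53])
        rows = []
        for scene in self._mixed_plates(cfg.n_test, rng):
            mean_depth, _ = imaging.average_depth_frames(scene.depth_stack)
            geom = _detect_geometry(scene.rgb, self.geometry)
            _, mask_w, _ = self._estimate_mask(scene)
            food_full = upsample_nearest(mask_w.mask, self.factor)
            surface = imaging.estimate_plate_surface_depth(
                mean_depth, geom, food_mask=food_full)
            geom = dataclasses.replace(geom, plate_surface_depth=surface)
            height_map = imaging.to_height_map(mean_depth, geom)
            refined = seg_mod.refine_with_depth(
                seg_mod.FoodMask(food_full, source="model"), height_map,
                self.config.min_height_mm)
            rows.append({"iou": seg_mod.iou(refined.mask, scene.truth_food_mask)})
        return float(np.mean([r["iou"] for r in rows])), rows

    def train_heads(self):
        cfg = self.config.head
        for i, sc in enumerate(self.scenarios):
            refs = []
            for scene in sc.reference_plates():
                rgb_w = _working(scene.rgb, self.factor)
                lab_w = _working(scene.truth_class_map, self.factor, labels=True)
                refs.append((rgb_w, lab_w))
            aug = meal_mod.augment_references(refs, n_augment=cfg.n_augment,
                                              seed=self._seeds[30 + i % 30])
            hp = meal_mod.HeadHyperparams(
                lr=cfg.lr, batch_size=cfg.batch_size, tol=cfg.tol,
                patience=cfg.patience, max_epochs=cfg.max_epochs,
                seed=self._seeds[30 + i % 30])
            self.heads[sc.meal_id] = meal_mod.train_head(
                self.extractor, aug, sc.class_ids, hp)
        return self.heads

    # ---- inference -----------------------------------------------------
    def _estimate_mask(self, scene, height_map=None):
        """Working-res food mask + capture-res depth-refined mask."""
        cfg = self.config
        rgb_w = _working(scene.rgb, self.factor)
        if cfg.use_truth_masks:
            mask_w = seg_mod.FoodMask(
                _working(scene.truth_food_mask, self.factor, labels=True),
                source="ground_truth")
        else:
            mask_w = seg_mod.segment(self.segmenter, rgb_w)
        mask_full = seg_mod.FoodMask(
            upsample_nearest(mask_w.mask, self.factor), source=mask_w.source)
        if height_map is not None:
            mask_full = seg_mod.refine_with_depth(mask_full, height_map,
                                                  cfg.min_height_mm)
        return rgb_w, mask_w, mask_full

    def prepare_reference(self, sc: MealScenario):
        """Process a meal's full-portion references once: estimate the plate
        surface depth and the per-class full volumes."""
        refs = sc.reference_plates()
        state = {"full_volumes": {}, "per_item_full": {}, "surface": None}
        surfaces = []
        for scene in refs:
            mean_depth, _ = imaging.average_depth_frames(scene.depth_stack)
            geom = _detect_geometry(scene.rgb, self.geometry)
            _, mask_w, _ = self._estimate_mask(scene)
            food_full = upsample_nearest(mask_w.mask, self.factor)
            surfaces.append(imaging.estimate_plate_surface_depth(
                mean_depth, geom, food_mask=food_full))
        state["surface"] = float(np.mean(surfaces))
        for j, scene in enumerate(refs):
            est = self._plate_estimate(scene, sc, state["surface"])
            for cid, v in est.volumes.items():
                state["full_volumes"][cid] = state["full_volumes"].get(cid, 0.0) + v
            if sc.style == "single":
                state["per_item_full"][sc.items[j].class_id] = dict(est.volumes)
        self.reference_state[sc.meal_id] = state
        return state

    def _plate_estimate(self, scene, sc: MealScenario, surface_depth):
        """Full estimation path for one plate -> per-class VolumeEstimate."""
        cfg = self.config
        mean_depth, _ = imaging.average_depth_frames(scene.depth_stack)
        geom = _detect_geometry(scene.rgb, self.geometry)
        geom = dataclasses.replace(geom, plate_surface_depth=surface_depth)
        height_map = imaging.to_height_map(mean_depth, geom)
        rgb_w, mask_w, mask_full = self._estimate_mask(scene, height_map)
        if cfg.use_truth_classes:
            labels_full = np.where(mask_full.mask, scene.truth_class_map, 0)
        else:
            head = self.heads[sc.meal_id]
            feats = extract_features(self.extractor, rgb_w, mask_w)
            cmap = meal_mod.classify(head, feats, mask_w)
            labels_full = upsample_nearest(cmap.labels, self.factor)
            labels_full = np.where(mask_full.mask, labels_full, 0)
        return vol_mod.plate_volumes(height_map, labels_full, geom,
                                     sc.class_ids, food_mask=mask_full)

    def classification_accuracy(self, scene, sc: MealScenario):
        """Pixel counts (correct, total) with ground-truth masks, working res."""
        rgb_w = _working(scene.rgb, self.factor)
        truth_w = _working(scene.truth_class_map, self.factor, labels=True)
        mask_w = truth_w > 0
        if not mask_w.any():
            return 0, 0
        feats = extract_features(self.extractor, rgb_w, mask_w)
        cmap = meal_mod.classify(self.heads[sc.meal_id], feats, mask_w)
        correct = int((cmap.labels[mask_w] == truth_w[mask_w]).sum())
        return correct, int(mask_w.sum())


def run_validation_study(config: RunConfig) -> StudyResults:
    """Train the full system and score it on held-out synthetic plates."""
    system = TrainedSystem(config)
    system.train_extractor()
    if not config.use_truth_masks:
        system.train_segmenter()
        seg_iou, seg_rows = system.heldout_segmentation_iou()
    else:
        seg_iou, seg_rows = None, []
    if not config.use_truth_classes:
        system.train_heads()

    rng_eval = np.random.default_rng([system._seeds[20], 61])
    per_meal = []
    records = []
    plate_nutrients = []  # (volume_path NutrientVector, mass_path NutrientVector)
    full_perm_counts = None

    for i, sc in enumerate(system.scenarios):
        state = system.prepare_reference(sc)
        portions = {s.class_id: nutr.portion_record_for(s) for s in sc.items}
        full_perm = (i == config.full_permutation_scenario and sc.style == "multi")
        if full_perm:
            plate_ids = np.arange(sc.n_plates)
        else:
            k = min(config.eval_plates_per_meal, sc.n_plates)
            plate_ids = np.sort(rng_eval.choice(sc.n_plates, size=k, replace=False))
        correct = total = 0
        for pid in plate_ids:
            scene = sc.render(int(pid))
            c, t = (system.classification_accuracy(scene, sc)
                    if not config.use_truth_classes else (0, 0))
            correct += c
            total += t

            est = system._plate_estimate(scene, sc, state["surface"])
            if sc.style == "multi":
                full_vols = dict(state["full_volumes"])
                truth_full = sum(sc.truth_full_volumes().values())
            else:
                # a single-item plate is differenced against its own item's
                # reference plate, not the whole menu's references
                item_idx = sc.plates[pid][0]
                cid_here = sc.items[item_idx].class_id
                full_vols = dict.fromkeys(sc.class_ids, 0.0)
                full_vols.update(state["per_item_full"][cid_here])
                truth_full = sc.items[item_idx].full_portion_volume_ml
            full_vols.pop(vol_mod.RESIDUAL_CLASS, None)
            est.volumes.pop(vol_mod.RESIDUAL_CLASS, None)
            rec = vol_mod.intake(vol_mod.VolumeEstimate(full_vols), est)
            rec.meal_id = sc.meal_id
            rec.plate_id = f"{sc.meal_id}:{pid}"
            rec.truth_leftover_ml = float(sum(scene.truth_volumes.values()))
            rec.truth_full_ml = float(truth_full)
            rec.truth_intake_ml = rec.truth_full_ml - rec.truth_leftover_ml
            records.append(rec)

            vol_vecs, mass_vecs = [], []
            for spec in sc.items:
                cid = spec.class_id
                if sc.style == "single" and cid != sc.items[sc.plates[pid][0]].class_id:
                    continue
                # relative consumption against the classified full reference
                # portion; shared under/over-segmentation cancels in the ratio
                it = rec.item(cid)
                est_frac = it.fraction if it.fraction is not None else 0.0
                true_frac = 1.0 - scene.truth_fractions.get(cid, 1.0)
                vol_vecs.append(nutr.item_nutrient_intake(est_frac, portions[cid]))
                mass_vecs.append(nutr.item_nutrient_intake(true_frac, portions[cid]))
            plate_nutrients.append((nutr.plate_nutrient_totals(vol_vecs),
                                    nutr.plate_nutrient_totals(mass_vecs)))
        top1 = 100.0 * correct / total if total else float("nan")
        per_meal.append({"meal_id": sc.meal_id, "n_classes": len(sc.items),
                         "n_plates": len(plate_ids), "top1_pct": top1})
        if full_perm:
            full_perm_counts = (correct, total)

    mean_top1 = float(np.mean([r["top1_pct"] for r in per_meal])) \
        if not config.use_truth_classes else float("nan")
    full_perm_top1 = (100.0 * full_perm_counts[0] / full_perm_counts[1]
                      if full_perm_counts and full_perm_counts[1] else None)

    metrics = vol_mod.intake_error_metrics(records)

    nutrient_results, nutrient_pairs = {}, {}
    for key in nutr.NUTRIENT_KEYS:
        vol_path = np.array([p[0].values[key] for p in plate_nutrients], dtype=float)
        mass_path = np.array([p[1].values[key] for p in plate_nutrients], dtype=float)
        fit = stats_mod.linear_fit(mass_path, vol_path)
        agr = stats_mod.bland_altman(vol_path, mass_path)
        nutrient_results[key] = (fit, agr)
        nutrient_pairs[key] = (vol_path, mass_path)

    results = StudyResults(
        per_meal=per_meal,
        mean_top1_pct=mean_top1,
        full_perm_top1_pct=full_perm_top1,
        seg_mean_iou=seg_iou,
        intake_metrics=metrics,
        nutrient_results=nutrient_results,
        nutrient_pairs=nutrient_pairs,
        min_r2=float(min(f.r2 for f, _ in nutrient_results.values())),
        max_abs_bias=float(max(abs(a.bias) for _, a in nutrient_results.values())),
        all_zero_within_loa=bool(all(a.zero_within_loa
                                     for _, a in nutrient_results.values())),
        n_plates=len(records),
        seed=config.seed,
        extractor_n_params=system.extractor.n_params,
        segmentation_rows=seg_rows,
        intake_records=records,
    )
    if config.out_dir:
        write_report(results, config)
    return results


def write_report(results: StudyResults, config: RunConfig):
    import json
    from pathlib import Path

    out = Path(config.out_dir)
    summary = stats_mod.build_report(
        out,
        segmentation=results.segmentation_rows or None,
        classification=results.per_meal,
        intake_metrics=results.intake_metrics,
        nutrient_results=results.nutrient_results,
        nutrient_pairs=results.nutrient_pairs,
        n=results.n_plates,
        seed=results.seed,
        plots=config.plots,
    )
    if results.intake_records:
        vol_mod.intake_report_frame(results.intake_records).to_csv(
            out / "intake_records.csv", index=False)
    (out / "config.json").write_text(config.model_dump_json(indent=1))
    return summary


def run_pipeline(config: RunConfig) -> StudyResults:
    """Alias used by the CLI: full study + report when out_dir is set."""
    return run_validation_study(config)


def acceptance_config(seed: int) -> RunConfig:
    """The canonical desk-scale validation-study configuration.

    Capture geometry is 240x320 (plate radius 110 px, 4/3 mm^2/px — the same
    physical plate as the 480x640 default, at half resolution), networks run
    at 120x160, the feature extractor trains on 600 masked single-food plates
    at 48x64, the segmenter on 60 plates with 40 held out, and each of the
    12 meal scenarios (3-15 classes) is scored on a sample of its intake
    series, with one 3-class meal scored on all 125 permutation plates.
    """
    return RunConfig(
        seed=seed,
        geometry=GeometryConfig(image_height=240, image_width=320,
                                plate_radius=110.0, pixel_area=4.0 / 3.0),
        working_factor=2,
        library_size=76,
        scenario_class_counts=list(DEFAULT_SCENARIO_CLASS_COUNTS),
        full_permutation_scenario=2,
        eval_plates_per_meal=10,
    )
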