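# platevision

Automated food-intake tracking from overhead RGB-D plate images: pixel-wise
food classification, differential-volume intake estimation, and per-item
linking to a 13-nutrient panel, with the full accuracy/agreement validation
suite and a built-in synthetic plate-scene generator so every stage is
testable end to end without any external imagery.

## The problem

In long-term care, food intake is charted by eye in 25% increments, often
hours after the meal — subjective, coarse, and unreliable for catching
malnutrition. An overhead depth camera photographing each plate before and
after the meal can replace that with objective, per-item measurements:

1. **Where is food?** A small encoder–decoder network labels each pixel
   food / no-food; the mask is refined with calibrated depth (pixels lower
   than a minimum height above the plate plane are dropped).
2. **Which foods?** A convolutional autoencoder, trained once on masked food
   imagery with food-pixel-only MSE loss, is spliced before its final 1×1
   convolution block to expose a full-resolution 16-channel latent feature
   map. For each meal with `n_c` menu items, `n_c` 1×1 convolution kernels
   (17·`n_c` parameters) are trained on 300 augmented copies of a single
   labelled full-portion reference per item — so a new menu costs one
   reference image, not a retrained network.
3. **How much was eaten?** Depth frames (10 per plate) are averaged,
   converted to heights above the plate plane, and integrated per class:
   V_c = Σ h·ΔA. Intake is the differential volume between the classified
   full-portion and leftover plates; relative consumption is the ratio
   intake / full reference volume.
4. **Which nutrients?** Each item's consumed fraction scales its
   full-portion nutrient vector (calories, carbohydrates, fats, fiber,
   protein, calcium, iron, sodium, vitamins B6/C/D/K, zinc); plate totals
   are item sums. %DV-style nutrition labels convert to absolute amounts
   through an editable daily-reference table.

The validation layer reports segmentation IOU, pixel-wise top-1 accuracy,
the bulk intake error family (signed/absolute food-volume and intake error,
3D % intake error), and — per nutrient — OLS goodness of fit (r², RMSE) and
Bland–Altman agreement (bias µ, limits of agreement µ ± 1.96·σ_d) between
volume-path estimates and the weighed-mass gold standard.

Because the networks run on a small CPU-only numpy conv-net core, everything
trains and runs offline on one machine — no GPU, no network access.

## Worked example

```python
from platevision.pipeline import GeometryConfig, RunConfig, run_validation_study

config = RunConfig(
    seed=11,
    geometry=GeometryConfig(image_height=240, image_width=320,
                            plate_radius=110.0, pixel_area=4.0 / 3.0),
    working_factor=2,          # networks run at 120x160
    library_size=12,           # synthetic food library
    scenario_class_counts=[3, 5],
    full_permutation_scenario=-1,
    eval_plates_per_meal=6,
    extractor={"n_images": 150, "max_epochs": 120},
    segmenter={"n_train": 30, "n_test": 10},
    head={"n_augment": 100},
)
results = run_validation_study(config)
for row in results.per_meal:
    print(f"{row['meal_id']}: top-1 {row['top1_pct']:.1f}% over {row['n_plates']} plates")
print(f"segmentation IOU (held out): {results.seg_mean_iou:.3f}")
mean_err, sd_err = results.intake_metrics["absolute_intake_error_ml"]
print(f"bulk intake |error|: {mean_err:.1f} (SD {sd_err:.1f}) mL")
fit, agr = results.nutrient_results["calories"]
print(f"calories, volume vs mass: r2={fit.r2:.3f}, bias={agr.bias:+.2f} kcal, "
      f"LoA [{agr.loa_lower:+.1f}, {agr.loa_upper:+.1f}]")
```

prints (about 3 minutes on one CPU):

```
meal_01_3cls: top-1 100.0% over 6 plates
meal_02_5cls: top-1 100.0% over 6 plates
segmentation IOU (held out): 0.947
bulk intake |error|: 2.0 (SD 5.5) mL
calories, volume vs mass: r2=0.994, bias=-2.34 kcal, LoA [-20.1, +15.4]
```

Reading the numbers: every food pixel of the two test meals was assigned the
right menu item; the trained segmenter overlaps the true food masks by ~95%;
estimated consumed volume is within a few mL of ground truth per plate; and
calorie intake inferred from volume tracks the weighed-mass path with r²
0.99 and a bias of about −2 kcal on these small, clean synthetic plates
(the full 12-scenario study in `scripts/acceptance.py` drives these numbers
much tighter).

A command-line interface wraps the same pipeline
(`platevision simulate | train-extractor | define-meal | run | report`);
`platevision run --seed 1 --out report/` writes the CSV tables, JSON summary
and optional regression/agreement figures.

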