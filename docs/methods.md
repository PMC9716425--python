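# Methods

This note records the models, parameters, and design choices behind
platevision, and what its synthetic validation study does and does not
demonstrate.

## Pipeline model

A plate observation is an RGB image plus a stack of 10 depth frames from a
fixed overhead camera. Processing per plate:

1. **Depth averaging.** The 10 frames are averaged per pixel; any pixel with
   a non-finite reading in any frame is flagged invalid (never zeroed).
2. **Plate localization.** The plate is found in RGB as the largest bright
   connected region (Otsu threshold, holes filled); its centroid and
   equivalent-area radius define the analysis circle. Calibration
   (mm/depth-unit, mm²/pixel) is supplied by the rig, not estimated.
3. **Plate-plane reference.** The bare-plate surface depth is the modal
   depth inside the plate circle, excluding the estimated food mask, on the
   meal's full-portion reference plate(s); the estimate is reused for every
   plate of that meal. The mode is refined to sub-bin accuracy by averaging
   readings within ±1.5 bins of the modal 1-unit bin.
4. **Heights.** height = (surface_depth − depth) · depth_scale, in mm.
   Negative heights inside the plate are physically meaningless depth noise
   and are clamped to 0 (counted in diagnostics). The plate plane is treated
   as orthographic: constant pixel area.
5. **Segmentation.** A 3-level encoder–decoder (8→16→8 channels, ~3k
   parameters) emits a per-pixel food logit; probability 0.5 is the mask
   threshold. The mask is then depth-refined: food pixels below
   `min_height_mm` (default 1 mm — suppresses plate-plane noise; the value
   is this package's choice) or outside the plate circle are dropped.
   Refinement is idempotent and only removes pixels. The segmenter is a
   pluggable stand-in honouring the same contract as a full-scale
   pretrained food-segmentation network; ground-truth masks can be
   substituted anywhere (`source="ground_truth"`) to decouple error sources.
6. **Feature extraction.** A convolutional autoencoder (3→8→16→16 latent
   channels, 3×3 kernels, sigmoid 1×1 decoder head; 3,763 parameters)
   reconstructs masked food imagery (background zeroed, colours in [0,1]).
   Loss is MSE over food pixels only, so background content cannot influence
   training — exactly, because the input itself is masked. After training it
   is spliced before the final 1×1 block: the 16-channel full-resolution
   ReLU activation map is the frozen latent feature extractor.
   The network keeps full spatial resolution throughout (no down/upsampling):
   the code is per-pixel and overcomplete rather than spatially
   bottlenecked, which preserves the edge fidelity the 1×1 heads depend on.
   The reference-scale system this emulates used an ~84k-parameter
   autoencoder; the synthetic palette needs far less capacity, and the
   smaller net keeps CPU training inside desk-scale budgets.
7. **Per-meal classification.** For a meal of n_c items, the head is n_c
   1×1 kernels over the 16 latent channels (16 weights + 1 bias per class;
   zero-initialised, which makes output channels exactly equivariant to item
   order). Training data are 300 augmented instances generated from the
   meal's full-portion reference plate(s): random horizontal/vertical flips
   (p=0.5 each), rotations uniform in [−180°, 180°] (bilinear for RGB,
   nearest for labels; swept-in corners are background and excluded from the
   loss), and contrast scaling uniform in [0.8, 1.2] about mid-grey. The
   ranges are this package's choice; the transform family and the count of
   300 follow the published protocol. Ties in the arg-max break to the
   lowest class index.
8. **Volumes and intake.** V_c = Σ_{pixels labelled c} h·ΔA/1000 (mL),
   computed at capture resolution with the working-resolution label map
   upsampled nearest-neighbour. Intake per class is V_full − V_leftover
   between the classified full-portion reference and the leftover plate
   (each image uses its own classification; no cross-image reconciliation).
   Relative consumption is intake/V_full — a ratio in which shared
   systematic segmentation error largely cancels. Fractions are never
   clipped; values outside [0,1] are flagged, because signed errors are
   reported downstream. Food-mask pixels left unlabelled (possible only with
   external masks) go to a separate residual bucket.
9. **Nutrient linking.** Item intake vector = fraction × full-portion
   nutrient vector; plate totals are elementwise sums. Missing nutrient
   values are explicit `None`: excluded from totals, flagged
   `incomplete:<nutrient>`, never imputed. Density (mass/volume of the full
   plate) is needed only to convert the weighed-mass gold standard for
   validation, not for the system to operate. %DV values convert through a
   daily-reference table shipped as an editable CSV (DRI-era >70 y,
   sex-averaged amounts; macronutrients from the 2000-kcal label
   convention) — documented stand-ins, not an authoritative table.

## Training discipline

All three trainable stages share one loop: 70/30 train/validation split,
Adam, mini-batches, and early stopping once the validation loss has failed
to improve on its best value by at least `tol` for `patience` consecutive
epochs (`best_epoch` marks the last ≥tol improvement, so the stop epoch
trails it by at least `patience`). Defaults:

| stage      | lr     | batch | tol    | patience | loss                        |
|------------|--------|-------|--------|----------|-----------------------------|
| autoencoder| 1e-4   | 32    | 1e-4   | 5        | food-masked MSE             |
| segmenter  | 5e-3   | 8     | 1e-4   | 5        | BCE (all pixels)            |
| meal head  | 0.1    | 32    | 1e-5   | 5        | food-masked cross-entropy   |

Autoencoder and head values follow the published recipe. The segmenter's
early-stop constants reuse the autoencoder's; its learning rate and batch
size are this package's own (no value is prescribed), chosen so the small
net converges within a CPU budget — note that with few batches per epoch the
per-epoch improvement criterion fires early, so the segmenter uses smaller
batches and the autoencoder a training set large enough (hundreds of
images) for the criterion to engage only near convergence.

Desk-scale training choices, all recorded here as the package's own:

- The head trains on a fixed-size random subsample of food pixels per
  augmented image (1,024 by default) — a 1×1 head is per-pixel softmax
  regression, so the subsample is an unbiased surrogate for the full pixel
  set.
- The segmenter trains at half the working resolution and infers at working
  resolution — its food/no-food decision is colour-driven and the kernels
  transfer across scale.
- The segmenter's training set is the configured scenario-sampled plates
  plus one single-food plate per library item: a colour family absent from
  training is simply never learned, and the validation loss gives no signal
  about it, so colour coverage is guaranteed explicitly rather than left to
  sampling luck.
- The segmenter retrains from a fresh initialisation (up to 3 attempts,
  best validation kept) when validation BCE plateaus above 0.05: a
  ~1.5k-parameter net occasionally sticks in a poor basin, and the early
  stopping criterion would otherwise accept the plateau.

## Synthetic scene generator

The generator emulates the statistical and geometric structure of plated
long-term-care meals under an overhead RGB-D rig:

- **Geometry.** Default 480×640 capture grid, plate radius 220 px,
  1/3 mm²/pixel, 0.5 mm/depth-unit, plate surface at 1000 depth units
  (~25 cm plate at ~50 cm range). All defaults overridable.
- **Foods.** A hue-ordered library of distinguishable items: base colour
  (evenly spaced hues, varied saturation/value), per-pixel colour jitter,
  correlated speckle texture, height profile ∈ {slab, dome, granular
  (slab + correlated roughness, emulating low-density foods)}, peak height
  12–35 mm, density 0.3–1.1 g/mL, full-portion volume 50–250 mL, and a
  13-nutrient vector drawn from serving-size-plausible ranges.
- **Plates.** Items are non-overlapping discs placed by rejection sampling
  (largest first, fixed retry cap, restart on failure). Intake removal
  shrinks the footprint (radius ∝ √fraction) at fixed height profile — the
  way a plate is physically re-plated with less food — and the rendered
  height field is rescaled so the integrated volume equals
  fraction × full-portion volume exactly, removing quadrature error from
  the ground truth.
- **Depth.** 10 frames of noiseless depth + i.i.d. Gaussian noise per pixel
  per frame, SD 3 depth units (1.5 mm) by default; the reference rig's
  noise magnitude is not published, so this is a plausible consumer
  depth-camera figure at half-metre range.
- **Series.** 3-item meals: every permutation of the 25% fraction grid
  (5³ = 125 plates). Larger menus: one item per plate, each imaged as a
  progressive-removal series (1.0 → 0.75 → 0.5 → 0.25 → 0.0), matching how
  modified-texture samples are imaged singly.
- **Occlusion.** `inject_occlusion` tilts/stacks a rigid slab so part of its
  footprint overhangs air: apparent (depth-visible) surface rises, true
  volume is unchanged — the overhead-imaging artifact that produces volume
  error at perfect segmentation.

What the generator does **not** emulate: photorealistic appearance, mixed
or overlapping foods, specular sauces, translucent/fluid items, perspective
distortion, depth shadows or material-dependent depth artifacts, plate
pattern/rim relief. Passing the synthetic study therefore demonstrates that
the pipeline's machinery is correct and self-consistent under known ground
truth — not that these accuracy levels transfer to real kitchen imagery,
where colour separability and depth quality are far less forgiving.

## Validation study (acceptance configuration)

The canonical study (`platevision.pipeline.acceptance_config`) uses a
240×320 capture grid (plate radius 110 px, 4/3 mm²/px — the same physical
plate at half resolution), networks at 120×160, a 76-food library, and 12
meal scenarios with class counts 3,3,3,5,5,9,10,10,12,12,15,15. The
autoencoder trains on 600 masked single-food plates reduced to 48×64; the
segmenter on 60 mixed plates plus the per-food coverage sweep, with 40
held-out mixed plates scored on the depth-refined mask (the segmentation
contract's output); each meal head on 300 augmented references. One 3-class meal is scored on its full 125-plate
permutation series; every other meal on 10 plates sampled from its series.
Bulk intake error pools all evaluated plates; the nutrient layer compares
volume-path and mass-path intake per plate across all 13 nutrients (OLS of
volume on mass, Bland–Altman volume − mass). These sizes are the package's
chosen desk scale: large enough for every training criterion to engage,
small enough to run in ~10 minutes on one CPU.

## Numerical choices and degenerate inputs

- Colour is processed in [0,1]; the decoder ends in a sigmoid, so
  reconstructions are range-valid by construction.
- IOU of two empty masks is defined as 1.0 (perfect agreement on "no
  food"); top-1 accuracy on an empty mask is NaN with a warning.
- Bland–Altman uses the sample SD (n−1) and the 1.96 normal multiplier;
  µ always denotes the bias (mean difference) and σ_d the SD of
  differences. Regression is unweighted OLS of volume-path on mass-path
  with a free intercept; axis assignment is configurable.
- Volumes are reported at 0.1 mL display resolution; internal arithmetic is
  full double precision. Metric-layer arithmetic (IOU counts, OLS,
  Bland–Altman, intake errors) is tested against independent brute-force
  implementations at 1e-9.
- Scenes serialize as PNG (16-bit for depth, 1/16 depth-unit quantization;
  label maps as 16-bit label PNGs) plus JSON calibration/truth and a CSV
  manifest per dataset. Model checkpoints are `.npz` weight archives with a
  JSON sidecar (hyperparameters, seed, per-epoch losses, parameter count).
- Every stochastic operation draws its seed deterministically from the run
  seed; identical configurations reproduce bit-identical scenes and
  byte-identical report tables.

## Known limitations

- The latent code is overcomplete (16 channels ≥ 3 input channels) and the
  autoencoder has no spatial bottleneck; it regularises toward food-colour
  structure rather than compressing. A spatially bottlenecked variant would
  be closer to classic autoencoder practice but degrades per-pixel edge
  fidelity at these resolutions.
- Per-meal heads assume menu colours are separable in the latent space;
  visually near-identical foods on one menu will confuse a 17-parameter
  class model by design.
- The occlusion artifact is modelled (and measured) but not corrected;
  overhang inflates estimated volume exactly as it does for a real overhead
  camera.
- Fluid intake, mixed dishes, and mass estimation for foods without density
  records are out of scope.
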