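"""Food / no-food pixel labelling with depth refinement.

A small encoder-decoder binary labeller stands in for a full-scale
pretrained food segmentation network: it honours the same contract (RGB in,
pixel-level food mask out, refined by calibrated depth) behind a pluggable
interface, so a larger network could be dropped in unchanged. Ground-truth
masks can be substituted at any pipeline point (``source="ground_truth"``)
to decouple segmentation error from downstream stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import DegenerateDataError
from .imaging import HeightMap

DEFAULT_MIN_HEIGHT_MM = 1.0  # suppresses plate-plane depth noise


@dataclass
class FoodMask:
    mask: np.ndarray  # (H, W) bool
    source: str = "model"  # model | ground_truth | manual


@dataclass
class SegmenterHyperparams:
    """Early-stop constants follow the feature extractor's training recipe;
    the learning rate is this package's own default (none is prescribed)."""

    lr: float = 5e-3
    batch_size: int = 32
    tol: float = 1e-4
    patience: int = 5
    max_epochs: int = 200
    val_frac: float = 0.3
    seed: int = 0
    # the small net occasionally plateaus from a bad init; retrain with a
    # fresh init (up to `restarts` attempts) until validation BCE reaches
    # `target_val_loss`, keeping the best run
    restarts: int = 3
    target_val_loss: float = 0.05


@dataclass
class SegmenterModel:
    net: nn.Sequential
    threshold: float = 0.5
    training_log: nn.TrainingLog | None = None
    hyperparams: SegmenterHyperparams = field(default_factory=SegmenterHyperparams)

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *[p for p, _ in self.net.params()])
        sidecar = {
            "threshold": self.threshold,
            "hyperparams": vars(self.hyperparams),
            "training_log": self.training_log.to_dict() if self.training_log else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path):
        path = Path(path)
        model = cls(net=_build_net(0))
        with np.load(path.with_suffix(".npz")) as data:
            model.net.load_state([data[k] for k in data.files])
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model.threshold = sidecar["threshold"]
        model.hyperparams = SegmenterHyperparams(**sidecar["hyperparams"])
        return model


def _build_net(seed) -> nn.Sequential:
    """3-level encoder-decoder: full res -> half res -> full res, 1 logit/px."""
    rng = np.random.default_rng([seed, 11])
    return nn.Sequential([
        nn.Conv2d(3, 8, 3, rng=rng),
        nn.ReLU(),
        nn.Conv2d(8, 16, 3, stride=2, rng=rng),
        nn.ReLU(),
        nn.Upsample2x(),
        nn.Conv2d(16, 8, 3, rng=rng),
        nn.ReLU(),
        nn.Conv2d(8, 1, 1, rng=rng),
    ])


def train_segmenter(samples, hyperparams: SegmenterHyperparams | None = None):
    """Train the binary food labeller.

    samples: list of (rgb, truth_food_mask) pairs at the training resolution
    (rgb uint8 or [0,1] float; H, W even). Training stops once validation
    loss improvement stays below `tol` for `patience` consecutive epochs.
    """
    hp = hyperparams or SegmenterHyperparams()
    if len(samples) < 2:
        raise ValueError("need at least 2 scenes to train")
    inputs = []
    any_food, any_bg = False, False
    for rgb, mask in samples:
        x = _to_unit_rgb(rgb)
        m = np.asarray(mask, dtype=bool)
        any_food |= bool(m.any())
        any_bg |= bool((~m).any())
        inputs.append((x, m))
    if not (any_food and any_bg):
        raise DegenerateDataError("training masks contain a single class")

    def loss_fn(out, ids, xs, rest):
        target = np.stack([r[0] for r in rest])
        return nn.bce_with_logits(out, target)

    best = None
    for attempt in range(max(1, hp.restarts)):
        attempt_seed = hp.seed + 101 * attempt
        net = _build_net(attempt_seed)
        log = nn.fit(net, inputs, loss_fn, lr=hp.lr, batch_size=hp.batch_size,
                     tol=hp.tol, patience=hp.patience, max_epochs=hp.max_epochs,
                     seed=attempt_seed, val_frac=hp.val_frac)
        val = min(log.val_loss)
        if best is None or val < best[0]:
            best = (val, net, log)
        if val <= hp.target_val_loss:
            break
    _, net, log = best
    return SegmenterModel(net=net, training_log=log, hyperparams=hp)


def _to_unit_rgb(rgb):
    x = np.asarray(rgb, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    return x


def segment(model: SegmenterModel, rgb) -> FoodMask:
    """Deterministic inference: per-pixel food probability thresholded at 0.5.

    The image's height and width must be even (the encoder halves them).
    """
    x = _to_unit_rgb(rgb)
    if x.ndim != 3 or x.shape[2] != 3 or x.shape[0] % 2 or x.shape[1] % 2:
        raise ValueError(f"incompatible image shape {x.shape}")
    logits = model.net.forward(x[None], train=False)[0, :, :, 0]
    # threshold 0.5 on probability == 0 on the logit
    thr_logit = np.log(model.threshold / (1.0 - model.threshold))
    return FoodMask(mask=logits > thr_logit, source="model")


def refine_with_depth(mask: FoodMask, heights: HeightMap,
                      min_height: float = DEFAULT_MIN_HEIGHT_MM) -> FoodMask:
    """Drop food pixels below `min_height` mm or outside the plate interior.

    Idempotent and monotone: pixels are only ever removed.
    """
    if mask.mask.shape != heights.heights.shape:
        raise ValueError("mask and height map grids are not congruent")
    keep = mask.mask & heights.valid_mask
    with np.errstate(invalid="ignore"):
        keep &= np.nan_to_num(heights.heights, nan=-np.inf) >= min_height
    if min_height <= 0:
        keep = mask.mask & heights.valid_mask  # no-op threshold inside plate
    return FoodMask(mask=keep, source=mask.source)


def iou(a, b) -> float:
    """Intersection over union of two masks; 1.0 when both are empty."""
    ma = a.mask if isinstance(a, FoodMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, FoodMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("mask grids are not congruent")
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)
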