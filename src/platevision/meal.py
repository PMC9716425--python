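"""Per-meal classification heads on frozen latent features.

Each meal's menu lists n_c items; the classifier for that meal is n_c 1x1
convolution kernels (16 weights + bias per class) applied to the frozen
16-channel latent feature map. It is trained from the meal's full-portion
reference plates: 300 augmented instances (random flips, rotations in
[-180, 180] degrees, contrast scaling in [0.8, 1.2]), categorical
cross-entropy over food pixels only, Adam at learning rate 0.1, batch 32,
early stopping at <1e-5 validation-loss change with 5-epoch patience.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .autoencoder import AutoencoderModel, extract_features
from .exceptions import MissingClassError
from .segmentation import FoodMask


@dataclass
class MealSpec:
    """A meal's menu: items, one full-portion reference scene per item (or a
    single multi-item reference plate), and the nutrient table handle."""

    meal_id: str
    items: list  # FoodSpecs
    reference_scenes: list  # PlateScenes (full portions)
    nutrient_table: object = None

    def __post_init__(self):
        if len(self.items) < 1:
            raise ValueError("a meal needs at least one item")
        ids = [s.class_id for s in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("class_ids must be unique within a meal")

    @property
    def n_classes(self):
        return len(self.items)


@dataclass
class ClassMap:
    """Per-pixel class decision: labels (0 = background) + normalized scores.

    `class_ids[j]` is the class id of score channel j; labels hold class ids
    (argmax over channels on food pixels, ties to the lowest class index).
    """

    labels: np.ndarray  # (H, W) int16
    scores: np.ndarray  # (H, W, n_c) float32, rows sum to 1
    class_ids: tuple

    def save(self, path):
        import imageio.v3 as iio
        import pandas as pd

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path / "labels.png", self.labels.astype(np.uint16))
        rows = []
        for j, cid in enumerate(self.class_ids):
            sel = self.labels == cid
            rows.append({
                "class_id": cid,
                "n_pixels": int(sel.sum()),
                "mean_score": float(self.scores[..., j][sel].mean()) if sel.any() else np.nan,
            })
        pd.DataFrame(rows).to_csv(path / "class_scores.csv", index=False)


def apply_transform(rgb, label_map, hflip, vflip, angle_deg, contrast):
    """One augmentation instance; the label map transforms congruently.

    RGB uses bilinear resampling, labels nearest-neighbour; rotation keeps
    the frame (corners swept in are background, excluded from any masked
    loss). Contrast scales colour about mid-grey in [0, 1] units.
    """
    x = np.asarray(rgb, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    lab = np.asarray(label_map)
    if hflip:
        x, lab = x[:, ::-1], lab[:, ::-1]
    if vflip:
        x, lab = x[::-1], lab[::-1]
    if angle_deg % 360 != 0:
        x = ndimage.rotate(x, angle_deg, axes=(1, 0), reshape=False, order=1,
                           mode="constant", cval=0.0)
        lab = ndimage.rotate(lab, angle_deg, axes=(1, 0), reshape=False, order=0,
                             mode="constant", cval=0)
    x = np.clip(0.5 + contrast * (x - 0.5), 0.0, 1.0)
    return np.ascontiguousarray(x), np.ascontiguousarray(lab)


def augment_references(references, n_augment=300, seed=0):
    """Generate `n_augment` augmented (rgb, label_map) training instances.

    references: list of (rgb, label_map) full-portion pairs. Deterministic
    given seed; each instance picks a reference uniformly and applies a
    random flip/rotation/contrast transform.
    """
    if len(references) < 1:
        raise ValueError("need at least one reference")
    if n_augment < 1:
        raise ValueError("n_augment must be >= 1")
    rng = np.random.default_rng([seed, 31])
    out = []
    for _ in range(n_augment):
        rgb, lab = references[rng.integers(len(references))]
        out.append(apply_transform(
            rgb, lab,
            hflip=bool(rng.uniform() < 0.5),
            vflip=bool(rng.uniform() < 0.5),
            angle_deg=float(rng.uniform(-180.0, 180.0)),
            contrast=float(rng.uniform(0.8, 1.2)),
        ))
    return out


@dataclass
class HeadHyperparams:
    lr: float = 0.1
    batch_size: int = 32
    tol: float = 1e-5
    patience: int = 5
    max_epochs: int = 200
    val_frac: float = 0.3
    seed: int = 0
    # a 1x1 head is a per-pixel softmax regression, so each augmented image
    # contributes a fixed-size random subsample of its food pixels to the
    # loss instead of every pixel; 0 disables subsampling
    pixel_sample: int = 1024


@dataclass
class MealHead:
    """n_c 1x1 kernels over the 16 latent channels (17 parameters/class)."""

    net: nn.Sequential
    class_ids: tuple
    training_log: nn.TrainingLog | None = None
    hyperparams: HeadHyperparams = field(default_factory=HeadHyperparams)

    @property
    def n_classes(self):
        return len(self.class_ids)

    @property
    def n_params(self):
        return self.net.n_params

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *[p for p, _ in self.net.params()])
        sidecar = {
            "class_ids": list(self.class_ids),
            "hyperparams": vars(self.hyperparams),
            "training_log": self.training_log.to_dict() if self.training_log else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _build_head(n_classes, latent_channels=16) -> nn.Sequential:
    conv = nn.Conv2d(latent_channels, n_classes, 1)
    conv.W[...] = 0.0  # symmetric start: head output is order-equivariant
    return nn.Sequential([conv])


def train_head(extractor: AutoencoderModel, samples, class_ids,
               hyperparams: HeadHyperparams | None = None) -> MealHead:
    """Train a meal head on augmented (rgb, label_map) instances.

    Label maps contain the meal's class ids (0 = background); the loss is
    computed over food pixels only. The feature extractor's weights are
    checksummed before and after: head training never touches them.
    """
    hp = hyperparams or HeadHyperparams()
    class_ids = tuple(class_ids)
    id_to_idx = {cid: j for j, cid in enumerate(class_ids)}
    seen = set()
    before = extractor.checksum()

    rng = np.random.default_rng([hp.seed, 32])
    inputs = []
    for rgb, lab in samples:
        lab = np.asarray(lab)
        mask = lab > 0
        if not mask.any():
            continue
        feats = extract_features(extractor, rgb, mask)
        idx = np.zeros(lab.shape, dtype=np.int64)
        for cid, j in id_to_idx.items():
            sel = lab == cid
            idx[sel] = j
            if sel.any():
                seen.add(cid)
        unknown = np.setdiff1d(np.unique(lab), [0] + list(class_ids))
        if unknown.size:
            raise ValueError(f"label map contains ids {unknown} not in the meal")
        if hp.pixel_sample:
            flat_feats = feats.reshape(-1, feats.shape[-1])
            food = np.flatnonzero(mask.ravel())
            pick = rng.choice(food, size=hp.pixel_sample, replace=True)
            feats_s = flat_feats[pick][:, None, :]  # (P, 1, 16)
            idx_s = idx.ravel()[pick][:, None]
            mask_s = np.ones(idx_s.shape, dtype=bool)
            inputs.append((feats_s.astype(np.float32), idx_s, mask_s))
        else:
            inputs.append((feats.astype(np.float32), idx, mask))

    absent = [cid for cid in class_ids if cid not in seen]
    if absent:
        raise MissingClassError(f"classes {absent} appear in no label map")

    head_net = _build_head(len(class_ids), extractor.latent_channels)

    def loss_fn(out, ids, xs, rest):
        labels = np.stack([r[0] for r in rest])
        masks = np.stack([r[1] for r in rest])
        return nn.masked_softmax_ce(out, labels, masks)

    log = nn.fit(head_net, inputs, loss_fn, lr=hp.lr, batch_size=hp.batch_size,
                 tol=hp.tol, patience=hp.patience, max_epochs=hp.max_epochs,
                 seed=hp.seed, val_frac=hp.val_frac)
    after = extractor.checksum()
    if before != after:
        raise RuntimeError("feature extractor weights changed during head training")
    return MealHead(net=head_net, class_ids=class_ids, training_log=log,
                    hyperparams=hp)


def classify(head: MealHead, features, mask: FoodMask | np.ndarray) -> ClassMap:
    """Label food pixels from latent features; deterministic.

    Scores (softmax) are computed for every pixel; labels are assigned only
    on mask pixels, 0 elsewhere; argmax ties break to the lowest class index.
    """
    features = np.asarray(features)
    if features.shape[-1] != head.net.layers[0].in_ch:
        raise ValueError("feature channels do not match the head")
    m = mask.mask if isinstance(mask, FoodMask) else np.asarray(mask, dtype=bool)
    if m.shape != features.shape[:2]:
        raise ValueError("mask and feature grids are not congruent")
    logits = head.net.forward(features[None].astype(np.float32), train=False)[0]
    scores = nn.softmax(logits).astype(np.float32)
    ids = np.asarray(head.class_ids, dtype=np.int16)
    labels = np.where(m, ids[np.argmax(scores, axis=-1)], 0).astype(np.int16)
    return ClassMap(labels=labels, scores=scores, class_ids=head.class_ids)


def top1_accuracy(predicted: ClassMap, truth, mask: FoodMask | np.ndarray) -> float:
    """Percentage of mask pixels whose predicted label equals truth."""
    m = mask.mask if isinstance(mask, FoodMask) else np.asarray(mask, dtype=bool)
    truth = np.asarray(truth)
    pred = predicted.labels if isinstance(predicted, ClassMap) else np.asarray(predicted)
    if not (m.shape == truth.shape == pred.shape):
        raise ValueError("grids are not congruent")
    n = m.sum()
    if n == 0:
        warnings.warn("top-1 accuracy undefined on an empty mask", stacklevel=2)
        return float("nan")
    return float(100.0 * (pred[m] == truth[m]).sum() / n)
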