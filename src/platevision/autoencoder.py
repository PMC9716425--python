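"""Convolutional autoencoder food-feature extractor.

The autoencoder reconstructs masked food imagery (background zeroed) and is
trained with mean squared error computed over food pixels only, Adam at
learning rate 1e-4, batch size 32, a 70/30 train/validation split, and early
stopping once validation improvement stays below 1e-4 for 5 epochs. After
training it is spliced before the final 1x1 convolution block, exposing a
full-resolution 16-channel latent feature map; those frozen features feed
the per-meal classification heads.

The network keeps full spatial resolution throughout (3 -> 8 -> 16 -> 16
latent channels -> 1x1 -> 3): the code is per-pixel and overcomplete rather
than spatially bottlenecked, which preserves the edge fidelity the 1x1
classification heads rely on. Colour is scaled to [0, 1]; the decoder ends
in a sigmoid so reconstructions stay in range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import DegenerateDataError
from .resolution import block_mean, center_sample

LATENT_CHANNELS = 16


@dataclass
class AutoencoderHyperparams:
    lr: float = 1e-4
    batch_size: int = 32
    tol: float = 1e-4
    patience: int = 5
    max_epochs: int = 150
    val_frac: float = 0.3
    seed: int = 0
    train_shape: tuple = (120, 160)  # working resolution (H, W)


def _build_net(seed) -> nn.Sequential:
    rng = np.random.default_rng([seed, 21])
    return nn.Sequential([
        nn.Conv2d(3, 8, 3, rng=rng),
        nn.ReLU(),
        nn.Conv2d(8, 16, 3, rng=rng),
        nn.ReLU(),
        nn.Conv2d(16, LATENT_CHANNELS, 3, rng=rng),
        nn.ReLU(),  # <- splice point: full-resolution 16-channel latent
        nn.Conv2d(LATENT_CHANNELS, 3, 1, rng=rng),
        nn.Sigmoid(),
    ])


_SPLICE_LAYER_INDEX = 6  # layers [0:6] end at the 16-channel ReLU


@dataclass
class AutoencoderModel:
    net: nn.Sequential
    splice_index: int = _SPLICE_LAYER_INDEX
    latent_channels: int = LATENT_CHANNELS
    training_log: nn.TrainingLog | None = None
    hyperparams: AutoencoderHyperparams = field(default_factory=AutoencoderHyperparams)

    @property
    def n_params(self) -> int:
        """Total trainable parameter count (platform-independent)."""
        return self.net.n_params

    def checksum(self) -> str:
        return self.net.checksum()

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *[p for p, _ in self.net.params()])
        hp = vars(self.hyperparams).copy()
        hp["train_shape"] = list(hp["train_shape"])
        sidecar = {
            "splice_index": self.splice_index,
            "latent_channels": self.latent_channels,
            "n_params": self.n_params,
            "hyperparams": hp,
            "training_log": self.training_log.to_dict() if self.training_log else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path):
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        hp = sidecar["hyperparams"]
        hp["train_shape"] = tuple(hp["train_shape"])
        model = cls(net=_build_net(0), splice_index=sidecar["splice_index"],
                    hyperparams=AutoencoderHyperparams(**hp))
        with np.load(path.with_suffix(".npz")) as data:
            model.net.load_state([data[k] for k in data.files])
        return model


def masked_unit_rgb(rgb, mask) -> np.ndarray:
    """RGB scaled to [0, 1] with non-food pixels zeroed (the network input)."""
    x = np.asarray(rgb, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    return x * np.asarray(mask, dtype=np.float32)[..., None]


def _fit_to_shape(rgb, mask, shape):
    """Reduce a capture-resolution pair to the training shape (integer factor)."""
    h, w = np.asarray(mask).shape
    if (h, w) == tuple(shape):
        return np.asarray(rgb), np.asarray(mask, dtype=bool)
    if h % shape[0] or w % shape[1] or h // shape[0] != w // shape[1]:
        raise ValueError(f"cannot reduce {(h, w)} to {tuple(shape)} by an integer factor")
    k = h // shape[0]
    return block_mean(rgb, k), center_sample(np.asarray(mask, dtype=bool), k)


def train_autoencoder(images, hyperparams: AutoencoderHyperparams | None = None):
    """Train the feature extractor on (rgb, FoodMask-or-bool-mask) pairs.

    Loss is mean squared reconstruction error over food pixels only, using
    the supplied masks; inputs are masked, so content confined to non-food
    pixels cannot influence training.
    """
    from .segmentation import FoodMask

    hp = hyperparams or AutoencoderHyperparams()
    if len(images) < 2:
        raise ValueError("need at least 2 images to train")
    inputs = []
    for rgb, mask in images:
        m = mask.mask if isinstance(mask, FoodMask) else mask
        rgb_s, m_s = _fit_to_shape(rgb, m, hp.train_shape)
        if not m_s.any():
            continue
        x = masked_unit_rgb(rgb_s, m_s)
        inputs.append((x, m_s))
    if len(inputs) < 2:
        raise DegenerateDataError("fewer than 2 images have non-empty food masks")

    net = _build_net(hp.seed)

    def loss_fn(out, ids, xs, rest):
        masks = np.stack([r[0] for r in rest])
        return nn.masked_mse(out, xs, masks)

    log = nn.fit(net, inputs, loss_fn, lr=hp.lr, batch_size=hp.batch_size,
                 tol=hp.tol, patience=hp.patience, max_epochs=hp.max_epochs,
                 seed=hp.seed, val_frac=hp.val_frac)
    return AutoencoderModel(net=net, training_log=log, hyperparams=hp)


def extract_features(model: AutoencoderModel, rgb, mask=None) -> np.ndarray:
    """Frozen forward pass to the splice point: (H, W, 16) latent features.

    `mask` (food/no-food) is applied to the input when given, matching the
    masked-input training regime. Pure function of (weights, image, mask).
    """
    from .segmentation import FoodMask

    if model.training_log is None and not any(p.any() for p, _ in model.net.params()):
        raise RuntimeError("model is untrained")
    if mask is None:
        mask = np.ones(np.asarray(rgb).shape[:2], dtype=bool)
    m = mask.mask if isinstance(mask, FoodMask) else mask
    x = masked_unit_rgb(rgb, m)
    return model.net.forward_to(x[None], model.splice_index)[0]


def reconstruct(model: AutoencoderModel, rgb, mask=None) -> np.ndarray:
    """Full forward pass: (H, W, 3) reconstruction in [0, 1]."""
    from .segmentation import FoodMask

    if mask is None:
        mask = np.ones(np.asarray(rgb).shape[:2], dtype=bool)
    m = mask.mask if isinstance(mask, FoodMask) else mask
    x = masked_unit_rgb(rgb, m)
    return model.net.forward(x[None], train=False)[0]


def masked_reconstruction_mse(model, rgb, mask) -> float:
    """Masked MSE of a reconstruction (validation-style diagnostic)."""
    from .segmentation import FoodMask

    m = mask.mask if isinstance(mask, FoodMask) else np.asarray(mask, dtype=bool)
    x = masked_unit_rgb(rgb, m)
    out = model.net.forward(x[None], train=False)
    loss, _ = nn.masked_mse(out, x[None], m[None])
    return loss
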