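"""Shared fixtures: a tiny capture geometry and small trained models.

Everything is generated programmatically at test time; training fixtures use
desk-scale image counts and (where the hyperparameter is this package's own
choice rather than part of the training recipe under test) raised learning
rates so the whole suite stays CPU-friendly.
"""

import numpy as np
import pytest

from platevision import synthetic
from platevision.autoencoder import AutoencoderHyperparams, train_autoencoder

TINY_SEED = 7


@pytest.fixture(scope="session")
def tiny_geometry():
    # 120x160 capture grid, same physical plate as the full-size default
    return synthetic.PlateGeometry(
        image_height=120, image_width=160, plate_center=(60.0, 80.0),
        plate_radius=55.0, plate_surface_depth=1000.0, depth_scale=0.5,
        pixel_area=16.0 / 3.0)


@pytest.fixture(scope="session")
def tiny_library():
    return synthetic.generate_food_library(8, seed=TINY_SEED)


@pytest.fixture(scope="session")
def tiny_meal(tiny_library, tiny_geometry):
    meal = synthetic.scale_meal_to_plate(
        [tiny_library[0], tiny_library[3], tiny_library[6]], tiny_geometry)
    return meal


@pytest.fixture(scope="session")
def tiny_scene(tiny_meal, tiny_geometry):
    return synthetic.render_plate(tiny_meal, [1.0, 0.5, 0.25], tiny_geometry,
                                  noise_sd=3.0, seed=TINY_SEED)


@pytest.fixture(scope="session")
def tiny_noiseless_scene(tiny_meal, tiny_geometry):
    return synthetic.render_plate(tiny_meal, [1.0, 0.5, 0.25], tiny_geometry,
                                  noise_sd=0.0, seed=TINY_SEED)


@pytest.fixture(scope="session")
def tiny_extractor(tiny_library, tiny_geometry):
    """A genuinely converged (desk-scale) feature extractor.

    Trained at 24x32 on masked single-food plates. The learning rate is
    raised above the deployment default so convergence fits the test budget;
    the loss definition, split and early-stopping discipline are the ones
    under test.
    """
    rng = np.random.default_rng(11)
    images = []
    for i in range(48):
        spec = tiny_library[i % len(tiny_library)]
        scene = synthetic.render_plate([spec], [float(rng.uniform(0.4, 1.0))],
                                       tiny_geometry, noise_sd=0.0,
                                       seed=int(rng.integers(2 ** 31)))
        images.append((scene.rgb, scene.truth_food_mask))
    hp = AutoencoderHyperparams(lr=1e-3, batch_size=8, tol=1e-4, patience=5,
                                max_epochs=250, seed=5, train_shape=(24, 32))
    return train_autoencoder(images, hp)
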