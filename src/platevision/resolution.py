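"""Integer-factor resolution changes between capture and network grids.

The networks run at a reduced "working" resolution; capture-resolution
images are reduced by block averaging (RGB) or block-center sampling
(label/mask grids), and label maps come back up by nearest-neighbour
replication, so a working pixel corresponds exactly to a k x k capture block.
"""

from __future__ import annotations

import numpy as np


def block_mean(img, k: int):
    """Mean-pool an (H, W[, C]) array by integer factor k (H, W divisible)."""
    if k == 1:
        return np.asarray(img, dtype=float)
    img = np.asarray(img, dtype=float)
    h, w = img.shape[:2]
    if h % k or w % k:
        raise ValueError(f"image shape {img.shape[:2]} not divisible by {k}")
    shape = (h // k, k, w // k, k) + img.shape[2:]
    return img.reshape(shape).mean(axis=(1, 3))


def center_sample(arr, k: int):
    """Sample the centre pixel of each k x k block (labels, masks)."""
    if k == 1:
        return np.asarray(arr)
    arr = np.asarray(arr)
    return arr[k // 2::k, k // 2::k]


def upsample_nearest(arr, k: int):
    """Replicate each pixel into a k x k block."""
    if k == 1:
        return np.asarray(arr)
    return np.asarray(arr).repeat(k, axis=0).repeat(k, axis=1)
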