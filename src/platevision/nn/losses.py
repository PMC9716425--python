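"""Pixel losses. Every loss returns (scalar, grad wrt the network output).

The masked variants average over masked pixels only, so any change confined
to unmasked pixels leaves the loss value exactly unchanged — the pipeline
relies on this to keep background content out of training.
"""

from __future__ import annotations

import numpy as np


def masked_mse(pred, target, mask):
    """Mean squared error over mask pixels (all channels).

    pred/target: (N,H,W,C); mask: (N,H,W) bool.
    """
    m = mask[..., None]
    n = mask.sum() * pred.shape[-1]
    if n == 0:
        raise ValueError("empty mask: no pixels contribute to the loss")
    diff = np.where(m, pred - target, 0.0)
    loss = float((diff.astype(np.float64) ** 2).sum() / n)
    grad = (2.0 / n) * diff
    return loss, grad.astype(pred.dtype)


def softmax(logits, axis=-1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax_ce(logits, labels, mask):
    """Categorical cross-entropy over mask pixels.

    logits: (N,H,W,K); labels: (N,H,W) ints in 0..K-1 (ignored off-mask).
    """
    n = mask.sum()
    if n == 0:
        raise ValueError("empty mask: no pixels contribute to the loss")
    p = softmax(logits)
    idx = np.where(mask, labels, 0)
    picked = np.take_along_axis(p, idx[..., None], axis=-1)[..., 0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-(np.log(np.maximum(picked, eps), where=mask, out=np.zeros_like(picked, dtype=np.float64)).sum()) / n)
    grad = p.copy()
    np.put_along_axis(grad, idx[..., None], picked[..., None] - 1.0, axis=-1)
    grad *= mask[..., None] / n
    return loss, grad.astype(logits.dtype)


def bce_with_logits(logits, target, mask=None):
    """Binary cross-entropy on logits (numerically stable).

    logits: (N,H,W,1); target: (N,H,W) in {0,1}; optional pixel mask.
    """
    z = logits[..., 0]
    t = target.astype(z.dtype)
    # log(1+exp(-|z|)) formulation
    loss_px = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    if mask is None:
        n = z.size
        loss = float(loss_px.astype(np.float64).sum() / n)
        grad = ((p - t) / n)[..., None]
    else:
        n = mask.sum()
        if n == 0:
            raise ValueError("empty mask: no pixels contribute to the loss")
        loss = float(loss_px.astype(np.float64)[mask].sum() / n)
        grad = (np.where(mask, p - t, 0.0) / n)[..., None]
    return loss, grad.astype(logits.dtype)
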