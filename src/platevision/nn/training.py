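"""Shared training loop: 70/30 split, mini-batches, early stopping.

Early stopping follows the discipline used throughout the pipeline: training
halts once the validation loss has failed to improve on its best value by at
least `tol` for `patience` consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EarlyStopper:
    """Stop when best-validation improvement < tol for `patience` epochs."""

    def __init__(self, tol, patience):
        self.tol = float(tol)
        self.patience = int(patience)
        self.best = np.inf
        self.best_epoch = 0
        self.streak = 0
        self.epoch = 0

    def update(self, val_loss):
        """Record one epoch's validation loss; return True to stop.

        `best_epoch` marks the last epoch with a significant (>= tol)
        improvement, so the stop epoch always trails it by >= patience.
        """
        self.epoch += 1
        if self.best - val_loss < self.tol:
            self.streak += 1
        else:
            self.streak = 0
            self.best_epoch = self.epoch
        self.best = min(self.best, val_loss)
        return self.streak >= self.patience


@dataclass
class TrainingLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_dict(self):
        return {
            "train_loss": [float(v) for v in self.train_loss],
            "val_loss": [float(v) for v in self.val_loss],
            "stopped_epoch": self.stopped_epoch,
            "best_epoch": self.best_epoch,
        }


def train_val_split(n, val_frac, rng):
    """Shuffled index split; validation gets round(n*val_frac) items (>=1)."""
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * val_frac))) if n > 1 else 0
    return idx[n_val:], idx[:n_val]


def fit(model, inputs, loss_fn, lr, batch_size, tol, patience, max_epochs,
        seed, val_frac=0.3):
    """Train `model` on a list of per-image samples.

    inputs: list of sample tuples; loss_fn(model_output, sample) -> (loss, grad).
    Samples are stacked along axis 0 per batch, so every sample must share its
    spatial shape. Returns a TrainingLog.
    """
    rng = np.random.default_rng(seed)
    n = len(inputs)
    if n < 2:
        raise ValueError("need at least 2 samples for a train/validation split")
    tr_idx, va_idx = train_val_split(n, val_frac, rng)
    from .optim import Adam

    opt = Adam(model.params(), lr=lr)
    stopper = EarlyStopper(tol, patience)
    log = TrainingLog()

    def batch_arrays(indices):
        xs = np.stack([inputs[i][0] for i in indices])
        rest = [tuple(inputs[i][1:]) for i in indices]
        return xs, rest

    def eval_loss(indices):
        tot, cnt = 0.0, 0
        for start in range(0, len(indices), batch_size):
            ids = indices[start:start + batch_size]
            xs, rest = batch_arrays(ids)
            out = model.forward(xs, train=False)
            loss, _ = loss_fn(out, ids, xs, rest)
            tot += loss * len(ids)
            cnt += len(ids)
        return tot / cnt

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(tr_idx))
        ep_loss, ep_n = 0.0, 0
        for start in range(0, len(order), batch_size):
            ids = tr_idx[order[start:start + batch_size]]
            xs, rest = batch_arrays(ids)
            out = model.forward(xs, train=True)
            loss, grad = loss_fn(out, ids, xs, rest)
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(ids)
            ep_n += len(ids)
        val = eval_loss(va_idx)
        log.train_loss.append(ep_loss / ep_n)
        log.val_loss.append(val)
        if stopper.update(val):
            break
    log.stopped_epoch = len(log.val_loss)
    log.best_epoch = stopper.best_epoch
    return log
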