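"""Training and evaluation orchestration.

The training loop follows the published recipe: Adam, the compound
Dice + 0.5*BCE objective, a polynomial learning-rate schedule
``lr0 * (1 - iter/max_iter)^power`` stepped per iteration (initial rate
1e-3, power 0.9), weight decay 5e-4, batch size 8, with online geometric
and photometric augmentation of the training stream.  The best checkpoint
is selected by validation IoU.  All randomness (weight init, shuffling,
augmentation) derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import build_variant, load_checkpoint, model_fingerprint, save_checkpoint
from .objectives import dice_bce_loss, evaluate_predictions
from .optim import Adam
from .synthetic_data import SegSample, augment
from .tensor import Tensor


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    optimizer: str = "adam"
    lr0: float = 1e-3
    lr_power: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0
    device: str = "cpu"
    variant: str = "lcmunet"
    augment: bool = True
    val_frac: float = 0.125    # of the training pool, when no val set given
    val_every: int = 1         # epochs between validation passes

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size and lr0 must be positive")
        if not (0.0 < self.lr_power <= 1.0):
            raise ValueError("lr_power must lie in (0, 1]")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)            # per epoch
    lr: list[float] = field(default_factory=list)              # per iteration
    val_iou: list[float] = field(default_factory=list)         # per epoch
    best_epoch: int = -1
    best_val_iou: float = -1.0


def poly_lr(iteration: int, max_iter: int, lr0: float, power: float) -> float:
    """Polynomial decay: lr0 * (1 - iter/max_iter)**power."""
    if not 0 <= iteration <= max_iter:
        raise ValueError("iteration must lie in [0, max_iter]")
    return lr0 * (1.0 - iteration / max_iter) ** power


def _batch(samples: list[SegSample]):
    x = np.stack([s.image for s in samples])
    y = np.stack([s.mask for s in samples])
    return Tensor(x), y


def predict(model, samples: list[SegSample], batch_size: int = 8):
    """Forward probability maps for a sample list, in evaluation mode."""
    model.eval()
    preds = []
    for i in range(0, len(samples), batch_size):
        x, _ = _batch(samples[i:i + batch_size])
        out = model(x)
        preds.extend(out.data[j] for j in range(out.shape[0]))
    return preds


def train(cfg: TrainConfig, train_samples: list[SegSample],
          val_samples: list[SegSample] | None = None):
    """Run the training loop; returns (checkpoint_state, TrainHistory).

    ``checkpoint_state`` is a dict with the best weights, variant name and
    fingerprint; pass it to :func:`save` / :func:`evaluate`.
    """
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    if val_samples is None:
        n_val = max(1, int(round(cfg.val_frac * len(train_samples)))) \
            if len(train_samples) >= 8 else 0
        val_samples = train_samples[-n_val:] if n_val else train_samples
        train_samples = train_samples[:-n_val] if n_val else train_samples

    model = build_variant(cfg.variant, seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    steps_per_epoch = max(1, int(np.ceil(len(train_samples) / cfg.batch_size)))
    max_iter = cfg.epochs * steps_per_epoch
    history = TrainHistory()
    best_state = None
    iteration = 0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [train_samples[i] for i in idx]
            if cfg.augment:
                batch = [augment(s, int(rng.integers(2 ** 31))) for s in batch]
            lr = poly_lr(iteration, max_iter, cfg.lr0, cfg.lr_power)
            history.lr.append(lr)
            opt.lr = lr
            x, y = _batch(batch)
            pred = model(x)
            loss = dice_bce_loss(pred, y)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss {loss.item()} at iteration {iteration}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            iteration += 1
        history.loss.append(float(np.mean(epoch_losses)))
        if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
            preds = predict(model, val_samples, cfg.batch_size)
            val = evaluate_predictions(preds, [s.mask for s in val_samples])
            history.val_iou.append(val.iou)
            if val.iou > history.best_val_iou:
                history.best_val_iou = val.iou
                history.best_epoch = epoch
                best_state = model.state_dict()

    checkpoint = {
        "variant": cfg.variant,
        "fingerprint": model_fingerprint(model),
        "state": best_state,
        "config": cfg.__dict__.copy(),
    }
    return checkpoint, history


def save(checkpoint: dict, path) -> None:
    model = build_variant(checkpoint["variant"])
    model.load_state_dict(checkpoint["state"])
    save_checkpoint(model, path, variant=checkpoint["variant"],
                    meta={"config": {k: v for k, v in checkpoint["config"].items()
                                     if isinstance(v, (int, float, str, bool))}})


def _materialise(checkpoint) -> object:
    """Accept either an in-memory checkpoint dict or an .npz path."""
    if isinstance(checkpoint, dict):
        model = build_variant(checkpoint["variant"])
        if model_fingerprint(model) != checkpoint["fingerprint"]:
            from .network import FingerprintMismatch
            raise FingerprintMismatch("checkpoint does not match built variant")
        model.load_state_dict(checkpoint["state"])
        return model
    model, _ = load_checkpoint(checkpoint)
    return model


def evaluate(checkpoint, test_samples: list[SegSample], *,
             per_image: bool = False, batch_size: int = 8):
    """Evaluate a checkpoint on unaugmented samples (global aggregation)."""
    if not test_samples:
        raise ValueError("cannot evaluate an empty test set")
    model = _materialise(checkpoint)
    preds = predict(model, test_samples, batch_size)
    targets = [s.mask for s in test_samples]
    return evaluate_predictions(preds, targets, per_image=per_image)
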