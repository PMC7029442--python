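"""SGD training loop with the poly learning-rate schedule.

Optimisation follows the published recipe: mini-batch SGD (batch 8) with
momentum 0.9 and weight decay 1e-4, base learning rate 2e-3 decayed as
lr = base_lr * (1 - iter/max_iter)^power with power 0.9, for max_iter
epochs.  Batch order, initialisation and therefore the full run are
reproducible for a fixed seed; the per-epoch shuffle is derived from
(seed, epoch) so a resumed run continues identically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .evaluate import dice_from_masks
from .network import BSCN
from .supervision import LossConfig, build_targets, total_loss

__all__ = ["TrainConfig", "TrainingDiverged", "poly_lr", "train",
           "save_training_state", "load_training_state"]

log = logging.getLogger("bscn.trainer")


@dataclass
class TrainConfig:
    batch_size: int = 8
    base_lr: float = 2e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    power: float = 0.9
    max_iter: int = 150          # epochs by default; see `schedule`
    seed: int = 0
    device: str = "cpu"
    checkpoint_path: str | None = None
    log_path: str | None = None
    val_every: int = 10
    schedule: str = "per_epoch"  # or "per_update"

    def __post_init__(self):
        if min(self.batch_size, self.max_iter) <= 0 or self.base_lr <= 0:
            raise ValueError("batch_size, max_iter and base_lr must be positive")
        if not (0 < self.power <= 1):
            raise ValueError("power must be in (0, 1]")
        if self.schedule not in ("per_epoch", "per_update"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


class TrainingDiverged(RuntimeError):
    """Raised when the loss goes non-finite; carries the term breakdown."""

    def __init__(self, epoch, breakdown):
        bad = {k: v for k, v in breakdown.items() if not np.isfinite(v)}
        super().__init__(
            f"non-finite loss at epoch {epoch}; offending terms: {bad or breakdown}"
        )
        self.breakdown = breakdown


def poly_lr(iteration, max_iter, base_lr=2e-3, power=0.9):
    """Polynomial decay: base_lr * (1 - iter/max_iter)^power."""
    if iteration > max_iter:
        warnings.warn("poly_lr: iteration beyond max_iter; clamping lr to 0")
        return 0.0
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return float(base_lr * (1.0 - iteration / max_iter) ** power)


def _epoch_rng(seed, epoch):
    return np.random.default_rng((seed * 1_000_003 + epoch) % (2**31 - 1))


def _as_splits(splits):
    """Accept {'train': (X, Y), 'val': (Xv, Yv)?} with NCHW images."""
    X, Y = splits["train"]
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y)
    if X.ndim != 4 or Y.ndim != 3 or X.shape[0] != Y.shape[0]:
        raise ValueError("train split must be (images [N,3,H,W], labels [N,H,W])")
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    val = splits.get("val")
    if val is not None:
        val = (np.asarray(val[0], dtype=np.float32), np.asarray(val[1]))
    return (X, Y), val


def _validation_dice(model, Xv, Yv, batch_size, threshold=0.5):
    preds = []
    for s in range(0, Xv.shape[0], batch_size):
        out = model.forward(Xv[s : s + batch_size])
        preds.append(out.fused.data[:, 0])
    pred = np.concatenate(preds, axis=0) >= threshold
    return dice_from_masks(Yv > 0, pred)


def train(model: BSCN, splits, loss_cfg: LossConfig, train_cfg: TrainConfig,
          start_epoch=0, optimizer=None, stop_epoch=None):
    """Train in place; returns (model, history dict).

    ``stop_epoch`` interrupts the run early without changing the learning
    rate schedule (which is governed by max_iter), so a snapshot taken there
    and resumed continues identically to an uninterrupted run.
    """
    (X, Y), val = _as_splits(splits)
    n = X.shape[0]
    opt = optimizer or nn.SGD(
        model.parameters(), lr=train_cfg.base_lr,
        momentum=train_cfg.momentum, weight_decay=train_cfg.weight_decay,
    )
    history = {"epoch": [], "lr": [], "loss": [], "side": [], "fuse": [],
               "val_epoch": [], "val_dice": []}
    best = {"dice": -1.0, "state": None, "epoch": None}
    n_updates = start_epoch * -(-n // train_cfg.batch_size)
    last_epoch = train_cfg.max_iter if stop_epoch is None else stop_epoch
    for epoch in range(start_epoch, last_epoch):
        order = _epoch_rng(train_cfg.seed, epoch).permutation(n)
        if train_cfg.schedule == "per_epoch":
            opt.lr = poly_lr(epoch, train_cfg.max_iter, train_cfg.base_lr,
                             train_cfg.power)
        epoch_loss = epoch_side = epoch_fuse = 0.0
        n_batches = 0
        for s in range(0, n, train_cfg.batch_size):
            idx = order[s : s + train_cfg.batch_size]
            if train_cfg.schedule == "per_update":
                opt.lr = poly_lr(min(n_updates, train_cfg.max_iter),
                                 train_cfg.max_iter, train_cfg.base_lr,
                                 train_cfg.power)
            out = model.forward(X[idx])
            Yb = Y[idx][:, None].astype(np.float64)
            pairs = build_targets(Yb, out.side_l2h, out.side_h2l)
            loss, breakdown = total_loss(out, pairs, Yb, loss_cfg)
            if not np.isfinite(breakdown["total"]):
                raise TrainingDiverged(epoch, breakdown)
            opt.zero_grad()
            loss.backward()
            opt.step()
            n_updates += 1
            n_batches += 1
            epoch_loss += breakdown["total"]
            epoch_side += breakdown["side"]
            epoch_fuse += breakdown["fuse"]
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["loss"].append(epoch_loss / n_batches)
        history["side"].append(epoch_side / n_batches)
        history["fuse"].append(epoch_fuse / n_batches)
        validate_now = val is not None and (
            (epoch + 1) % train_cfg.val_every == 0
            or epoch == train_cfg.max_iter - 1
        )
        if validate_now:
            dice = _validation_dice(model, val[0], val[1], train_cfg.batch_size)
            history["val_epoch"].append(epoch)
            history["val_dice"].append(dice)
            if dice > best["dice"]:
                best.update(dice=dice, state=model.state_dict(), epoch=epoch)
                if train_cfg.checkpoint_path:
                    save_training_state(
                        train_cfg.checkpoint_path, model, opt, epoch,
                        extra={"best_val_dice": dice},
                    )
            log.info("epoch %d lr %.2e loss %.4f val_dice %.4f",
                     epoch, opt.lr, history["loss"][-1], dice)
        else:
            log.info("epoch %d lr %.2e loss %.4f",
                     epoch, opt.lr, history["loss"][-1])
    history["best_val_dice"] = best["dice"] if best["state"] else None
    history["best_epoch"] = best["epoch"]
    if val is None and train_cfg.checkpoint_path:
        save_training_state(train_cfg.checkpoint_path, model, opt,
                            train_cfg.max_iter - 1)
    return model, history


# --------------------------------------------------------- resume support


def save_training_state(path, model, opt, epoch, extra=None):
    """Full training snapshot: weights, config, momentum buffers, epoch."""
    from dataclasses import asdict

    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    for i, v in enumerate(opt.state()):
        payload[f"vel:{i}"] = v
    meta = {"epoch": int(epoch), "config": asdict(model.cfg)}
    if extra:
        meta["extra"] = extra
    payload["meta_json"] = np.bytes_(json.dumps(meta).encode())
    np.savez(path, **payload)


def load_training_state(path, train_cfg: TrainConfig):
    """Rebuild (model, optimizer, next_epoch) from a snapshot."""
    from .network import NetworkConfig

    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["meta_json"]).decode())
    cfg = meta["config"]
    for k in ("convs_per_block", "channels_per_block"):
        cfg[k] = tuple(cfg[k])
    model = BSCN(NetworkConfig(**cfg))
    model.load_state_dict(
        {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    )
    opt = nn.SGD(model.parameters(), lr=train_cfg.base_lr,
                 momentum=train_cfg.momentum,
                 weight_decay=train_cfg.weight_decay)
    vel_keys = sorted(
        (k for k in data.files if k.startswith("vel:")),
        key=lambda k: int(k.split(":")[1]),
    )
    opt.load_state([data[k] for k in vel_keys])
    return model, opt, meta["epoch"] + 1
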