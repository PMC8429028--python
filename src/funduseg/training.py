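"""Training protocol: BCE+Dice loss, Adam, plateau LR schedule, early stop.

The monitored quantity is the training loss.  When it fails to improve
for ``lr_patience`` consecutive epochs the learning rate is multiplied by
``lr_factor`` (default x0.1 after 5 epochs); when it fails to improve for
``early_stop_patience`` epochs (default 15) training stops.  Both are
pure functions of the loss sequence and are unit-testable without a
network.  Datasets are split train:test = 2:1 at the image level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_masks import FundusImage, LesionMaskSet
from .model import EADNet
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "bce_dice_loss",
    "split_dataset",
    "PlateauScheduler",
    "EarlyStopping",
    "train",
    "to_sample",
]

_EPS = 1e-7


@dataclass
class TrainConfig:
    batch_size: int = 2
    dropout: float = 0.5
    learning_rate: float = 1e-4
    lr_factor: float = 0.1
    lr_patience: int = 5
    early_stop_patience: int = 15
    split_ratio: tuple[int, int] = (2, 1)
    seed: int = 0
    max_epochs: int = 300

    def __post_init__(self):
        if self.lr_patience >= self.early_stop_patience:
            raise ValueError("lr_patience must be smaller than early_stop_patience")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""


def bce_dice_loss(pred, target) -> float:
    """Binary cross-entropy plus (1 - Dice), as a plain number.

    Works on numpy arrays of any matching shape; the Dice term is
    averaged over the leading class axis if present, with an epsilon
    smoothing so empty masks are well defined.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pc = np.clip(p, _EPS, 1 - _EPS)
    bce = -np.mean(t * np.log(pc) + (1 - t) * np.log(1 - pc))
    if p.ndim >= 3:
        axes = tuple(range(p.ndim - 2, p.ndim))
        inter = (p * t).sum(axis=axes)
        dice = (2 * inter + _EPS) / (p.sum(axis=axes) + t.sum(axis=axes) + _EPS)
        dice = float(dice.mean())
    else:
        dice = float((2 * (p * t).sum() + _EPS) / (p.sum() + t.sum() + _EPS))
    return float(bce + (1 - dice))


def _bce_dice_loss_graph(pred: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable BCE+Dice on the tape; ``pred`` is (B, C, H, W)."""
    t = Tensor(target)
    one = Tensor(1.0)
    pc_log = (pred + _EPS).log()
    pq_log = (one - pred + _EPS).log()
    bce = -(t * pc_log + (one - t) * pq_log).mean()
    inter = (pred * t).sum(axis=3).sum(axis=2)
    denom = pred.sum(axis=3).sum(axis=2) + t.sum(axis=3).sum(axis=2)
    dice = ((inter * 2.0 + _EPS) / (denom + _EPS)).mean().mean()
    return bce + (one - dice)


def split_dataset(items: list, ratio: tuple[int, int] = (2, 1), seed: int = 0,
                  ) -> tuple[list, list]:
    """Random disjoint train/test partition; |train| = round(n * 2/3) at 2:1."""
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    frac = ratio[0] / (ratio[0] + ratio[1])
    n_train = int(round(n * frac))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` non-improving epochs.

    The wait counter resets on improvement and after each reduction.
    """

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 5):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def step(self, value: float) -> bool:
        """Record one epoch's monitored value; returns True if LR dropped."""
        if value < self.best:
            self.best = value
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            self.lr *= self.factor
            self.wait = 0
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int = 15):
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def step(self, value: float) -> bool:
        if value < self.best:
            self.best = value
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def to_sample(image: FundusImage, masks: LesionMaskSet,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Convert an image/mask pair to network input/target arrays."""
    x = image.pixels.astype(np.float64).transpose(2, 0, 1) / 255.0
    y = masks.as_array(image.shape).astype(np.float64)
    return x, y


def train(network: EADNet, train_set: list[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig, log=None) -> tuple[dict, TrainHistory]:
    """Optimise ``network`` on ``train_set`` under the plateau protocol.

    ``train_set`` holds ``(input, target)`` array pairs from
    :func:`to_sample`.  Returns the best-loss weights (a state dict) and
    the per-epoch history.
    """
    if not train_set:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters(), lr=config.learning_rate)
    sched = PlateauScheduler(config.learning_rate, config.lr_factor, config.lr_patience)
    stopper = EarlyStopping(config.early_stop_patience)
    history = TrainHistory()
    best_loss = np.inf
    best_state = network.state_dict()
    network.train()
    n = len(train_set)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(np.stack([train_set[i][0] for i in idx]))
            yb = np.stack([train_set[i][1] for i in idx])
            pred = network(xb)
            loss = _bce_dice_loss_graph(pred, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        epoch_loss = float(np.mean(epoch_losses))
        history.loss.append(epoch_loss)
        history.learning_rate.append(opt.lr)
        if log is not None:
            log(epoch, epoch_loss, opt.lr)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = network.state_dict()
        if sched.step(epoch_loss):
            opt.lr = sched.lr
        if stopper.step(epoch_loss):
            history.stop_epoch = epoch
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_epoch = config.max_epochs
        history.stop_reason = "max_epochs"
    network.load_state_dict(best_state)
    return best_state, history
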