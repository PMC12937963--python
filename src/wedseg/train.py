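"""Training loop: dice + categorical cross-entropy, Adam, callbacks.

The loss is a 1:1 (configurable) combination of macro soft-dice over the
class channels and pixel-mean categorical cross-entropy, both computed on
the softmax probabilities.  Optimization is Adam with decoupled weight
decay applied to convolution kernels only.  Validation loss after each
epoch drives two callbacks: reduce-on-plateau (multiply the learning rate
by a factor after ``plateau_patience`` non-improving epochs) and early
stopping (halt after ``early_stop_patience`` non-improving epochs); the
best-validation weights are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SegmentationNet, softmax_channels

__all__ = [
    "TrainConfig", "TrainHistory", "DatasetSplit", "TrainingError",
    "split_dataset", "one_hot_encode", "dice_ce_loss", "dice_ce_loss_grad",
    "images_to_input", "train", "predict_batch",
]


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 4e-4
    batch_size: int = 16
    epochs: int = 100
    split_fraction: float = 0.8
    weight_decay: float = 1e-5
    early_stop_patience: int = 10
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-6
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    smooth: float = 1e-6
    log_eps: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0,1)")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.dice_weight < 0 or self.ce_weight < 0 or \
                (self.dice_weight == 0 and self.ce_weight == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


@dataclass
class TrainHistory:
    """Per-epoch records of losses, validation metrics, and learning rate."""

    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def record(self, **kw) -> None:
        for key, value in kw.items():
            getattr(self, key).append(value)


@dataclass
class DatasetSplit:
    """Disjoint train/test partition with the index permutation kept."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)


def split_dataset(n_or_items, split_fraction: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Deterministic shuffled split; train size = round(split_fraction * N).

    Accepts either a count or a sized collection.
    """
    n = n_or_items if isinstance(n_or_items, (int, np.integer)) else len(n_or_items)
    if n < 1:
        raise ValueError("cannot split an empty dataset")
    n_train = int(np.floor(split_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(train_indices=perm[:n_train], test_indices=perm[n_train:])


def one_hot_encode(mask: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """(H, W) labels -> (num_classes, H, W) indicator grid."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ValueError(f"mask values must lie in [0,{num_classes}), got "
                         f"[{mask.min()},{mask.max()}]")
    return np.moveaxis(np.eye(num_classes, dtype=np.float64)[mask], -1, 0)


def dice_ce_loss(pred: np.ndarray, target: np.ndarray,
                 loss_weights: tuple[float, float] = (1.0, 1.0),
                 smooth: float = 1e-6, log_eps: float = 1e-7) -> float:
    """Combined loss on probabilities.

    ``pred`` and ``target`` are (..., C, H, W) with the class axis third
    from last; a leading batch axis is optional.  The dice term pools
    pixels over the whole batch per class and macro-averages; the
    cross-entropy term is the mean over pixels of -log p at the true class.
    """
    loss, _ = _dice_ce(pred, target, loss_weights, smooth, log_eps)
    return loss


def _dice_ce(pred, target, loss_weights, smooth, log_eps):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if pred.ndim == 3:
        pred, target = pred[None], target[None]
    dice_w, ce_w = loss_weights
    n_pix = pred.shape[0] * pred.shape[2] * pred.shape[3]
    k = pred.shape[1]

    sum_axes = (0, 2, 3)
    inter = (pred * target).sum(axis=sum_axes)
    sizes = pred.sum(axis=sum_axes) + target.sum(axis=sum_axes)
    dice_per_class = (2.0 * inter + smooth) / (sizes + smooth)
    dice_loss = 1.0 - dice_per_class.mean()
    ce = -(target * np.log(pred + log_eps)).sum() / n_pix
    loss = dice_w * dice_loss + ce_w * ce

    # dL/d(pred): dice term uses the quotient rule on pooled sums.
    dpred = -dice_w * (2.0 * target * (sizes + smooth)[:, None, None]
                       - (2.0 * inter + smooth)[:, None, None]) \
        / ((sizes + smooth) ** 2)[:, None, None] / k
    dpred -= ce_w * target / (pred + log_eps) / n_pix
    return float(loss), dpred


def dice_ce_loss_grad(logits: np.ndarray, target: np.ndarray,
                      loss_weights: tuple[float, float] = (1.0, 1.0),
                      smooth: float = 1e-6, log_eps: float = 1e-7
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss, gradient w.r.t. logits, and the probabilities, in one pass."""
    probs = softmax_channels(logits)
    loss, dprobs = _dice_ce(probs, target, loss_weights, smooth, log_eps)
    if probs.ndim == 3:
        probs = probs[None]
        if dprobs.ndim == 3:
            dprobs = dprobs[None]
    # Softmax Jacobian: dz = p * (g - sum_c g_c p_c)
    dlogits = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
    return loss, dlogits.reshape(logits.shape), probs.reshape(logits.shape)


class AdamW:
    """Adam with decoupled weight decay restricted to convolution kernels."""

    def __init__(self, net: SegmentationNet, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key, name, layer in self.net.param_items():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(key, np.zeros_like(layer.params[name]))
            v = self.v.setdefault(key, np.zeros_like(layer.params[name]))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p = layer.params[name]
            if self.weight_decay and name == "W":
                p -= self.lr * self.weight_decay * p
            p -= self.lr * update


def images_to_input(images, dtype=np.float64) -> np.ndarray:
    """uint8 (N, H, W, 3) RGB images -> normalized (N, 3, H, W) input."""
    arr = np.asarray(images, dtype=dtype) / 255.0
    if arr.ndim == 3:
        arr = arr[None]
    return arr.transpose(0, 3, 1, 2)


def predict_batch(net: SegmentationNet, images, batch_size: int = 16) -> np.ndarray:
    """Inference-mode probabilities (N, C, H, W) for a batch of RGB images."""
    if len(images) == 0:
        return np.zeros((0, net.config.num_classes, 0, 0), dtype=np.float64)
    x = images_to_input(images, dtype=net.dtype)
    out = [net.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def train(net: SegmentationNet, images, masks, split: DatasetSplit,
          config: TrainConfig = TrainConfig(), verbose: bool = False
          ) -> TrainHistory:
    """Fit ``net`` on 3-class targets; restores best-validation weights.

    ``images`` is (N, H, W, 3) uint8, ``masks`` (N, H, W) over {0,1,2}.
    The test partition of ``split`` serves as the validation set for the
    loss monitored by both callbacks.
    """
    from .metrics import dataset_pixel_accuracy, dice_macro_pooled, mean_iou_pooled

    x_all = images_to_input(images, dtype=net.dtype)
    t_all = np.stack([one_hot_encode(m, net.config.num_classes) for m in masks]) \
        .astype(net.dtype)
    y_all = np.asarray(masks)
    tr, va = split.train_indices, split.test_indices
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("both split partitions must be non-empty")

    rng = np.random.default_rng(config.seed)
    optimizer = AdamW(net, lr=config.learning_rate, weight_decay=config.weight_decay)
    weights = (config.dice_weight, config.ce_weight)
    history = TrainHistory()
    best_loss = np.inf
    best_weights = net.get_weights()
    wait_plateau = wait_stop = 0

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(tr)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward_logits(x_all[idx], training=True, rng=rng)
            loss, dlogits, _ = dice_ce_loss_grad(
                logits, t_all[idx], weights, config.smooth, config.log_eps)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits.astype(net.dtype))
            optimizer.step()
            epoch_losses.append(loss)

        val_loss, val_labels = _evaluate_split(net, x_all, t_all, va, weights, config)
        truths = [y_all[i] for i in va]
        history.record(
            epoch=epoch, lr=optimizer.lr,
            train_loss=float(np.mean(epoch_losses)), val_loss=val_loss,
            val_dice=dice_macro_pooled(val_labels, truths),
            val_iou=mean_iou_pooled(val_labels, truths),
            val_accuracy=dataset_pixel_accuracy(val_labels, truths),
        )
        if verbose:
            print(f"epoch {epoch:3d} lr {optimizer.lr:.2e} "
                  f"train {history.train_loss[-1]:.4f} val {val_loss:.4f} "
                  f"dice {history.val_dice[-1]:.4f}")

        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = net.get_weights()
            history.best_epoch = epoch
            wait_plateau = wait_stop = 0
        else:
            wait_plateau += 1
            wait_stop += 1
            if wait_plateau >= config.plateau_patience:
                optimizer.lr = max(optimizer.lr * config.plateau_factor, config.min_lr)
                wait_plateau = 0
            if wait_stop >= config.early_stop_patience:
                history.stopped_early = True
                break

    net.set_weights(best_weights)
    return history


def _evaluate_split(net, x_all, t_all, indices, weights, config):
    losses, counts, labels = [], [], []
    for start in range(0, len(indices), config.batch_size):
        idx = indices[start:start + config.batch_size]
        probs = net.forward(x_all[idx])
        losses.append(dice_ce_loss(probs, t_all[idx], weights,
                                   config.smooth, config.log_eps))
        counts.append(len(idx))
        labels.extend(probs.argmax(axis=1).astype(np.uint8))
    val_loss = float(np.average(losses, weights=counts))
    return val_loss, labels
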