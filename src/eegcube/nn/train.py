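"""Transfer-learning training of the classifier head.

Training follows the transfer-learning recipe: the convolutional backbone
is frozen (weights and batch-norm statistics immutable) and only the dense
head is optimized with Adam on cross-entropy, batch size 4, learning rate
1e-4 by default.  Because a frozen backbone in evaluation mode is a fixed
deterministic map, its features are computed once up front and the head is
trained on the cached features — identical arithmetic to re-running the
frozen forward pass every epoch, at a fraction of the cost.  Setting
``freeze_backbone=False`` trains end-to-end through the convolutional
layers' backward passes instead.

The returned model is the checkpoint from the epoch with the lowest
training loss, mirroring saving weights at the point of least loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Adam, softmax_cross_entropy
from .model import Classifier

__all__ = ["TrainConfig", "TrainingError", "DivergenceError", "train_transfer"]


class TrainingError(ValueError):
    pass


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 200
    batch_size: int = 4
    shuffle: bool = True
    split_ratio: float = 0.8
    seed: int = 0
    freeze_backbone: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split ratio must lie in (0, 1)")


def train_transfer(
    model: Classifier, x: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> tuple[Classifier, dict]:
    """Train the classifier on inputs ``x`` (n x 3 x w x H x W) and labels.

    Returns the model restored to its lowest-loss epoch plus a history dict
    with per-epoch mean loss and training accuracy.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise TrainingError(
            f"training data contains {classes.size} class(es); need >= 2"
        )
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]

    if cfg.freeze_backbone:
        feats = model.backbone.forward_batched(x)
        params = model.head.params()
        grad_fn = model.head.grads

        def run_batch(idx):
            logits = model.head.forward(feats[idx], train=True)
            loss, grad, probs = softmax_cross_entropy(logits, labels[idx])
            model.head.backward(grad)
            return loss, probs
    else:
        params = {**{f"backbone.{k}": v for k, v in model.backbone.params().items()},
                  **{f"head.{k}": v for k, v in model.head.params().items()}}

        def grad_fn():
            return {**{f"backbone.{k}": v
                       for k, v in model.backbone.grads().items()},
                    **{f"head.{k}": v for k, v in model.head.grads().items()}}

        def run_batch(idx):
            f = model.backbone.forward(x[idx], train=True)
            logits = model.head.forward(f, train=True)
            loss, grad, probs = softmax_cross_entropy(logits, labels[idx])
            model.backbone.backward(model.head.backward(grad))
            return loss, probs

    opt = Adam(params, lr=cfg.learning_rate)
    history = {"loss": [], "accuracy": []}
    best = (np.inf, None)
    for epoch in range(cfg.max_epochs):
        idx = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            batch = idx[start : start + cfg.batch_size]
            loss, probs = run_batch(batch)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.step(grad_fn())
            epoch_loss += loss * batch.size
            correct += int((probs.argmax(axis=1) == labels[batch]).sum())
        epoch_loss /= n
        history["loss"].append(epoch_loss)
        history["accuracy"].append(correct / n)
        if epoch_loss < best[0]:
            best = (epoch_loss, {k: v.copy() for k, v in model.head.state().items()})
            history["best_epoch"] = epoch
    if best[1] is not None:
        model.head.load_state(best[1])
    return model, history
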