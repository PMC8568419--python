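"""Training loop: Adam, early stopping and learning-rate decay on val mIOU.

The loss is pixel-wise categorical cross-entropy over the two softmax
channels. After every epoch the foreground mIOU is measured on the
(un-augmented) validation images; the checkpoint with the best validation
mIOU is returned. Training halts when the metric has not strictly improved
for ``early_stop_patience`` epochs, and the learning rate is multiplied by
``lr_decay_factor`` after ``lr_decay_patience`` non-improving epochs
(the decay counter then restarts). Everything — data order, weight
initialization, augmentation — is seeded, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .unet import UNet

__all__ = ["TrainConfig", "TrainHistory", "TrainingSample", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters (defaults: Adam at 1e-4, batch 4,
    up to 1000 epochs, both patience values 100 epochs)."""

    lr: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 1000
    early_stop_patience: int = 100
    lr_decay_patience: int = 100
    lr_decay_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "max_epochs", "early_stop_patience",
                     "lr_decay_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class TrainHistory:
    """Per-epoch trace of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_miou: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0

    @property
    def best_val_miou(self) -> float:
        return self.val_miou[self.best_epoch - 1]


@dataclass
class TrainingSample:
    """One network-ready sample: normalized image, label mask, patient id."""

    image: np.ndarray  # float32 (H, W) in [0, 1]
    mask: np.ndarray  # uint8 (H, W) in {0, 1}
    patient_id: str = ""


def _foreground_iou(pred: np.ndarray, gt: np.ndarray) -> float:
    inter = int(np.count_nonzero(pred & gt))
    union = int(np.count_nonzero(pred | gt))
    return 1.0 if union == 0 else inter / union


def _val_miou(network: UNet, val_set) -> float:
    scores = []
    for s in val_set:
        logits = network.forward(s.image[None, None].astype(np.float32),
                                 train=False)
        pred = np.argmax(logits[0], axis=0).astype(np.uint8)
        scores.append(_foreground_iou(pred.astype(bool), s.mask.astype(bool)))
    return float(np.mean(scores))


def train(network: UNet, train_set, val_set, config: TrainConfig):
    """Fit the network; returns (network restored to best weights, history).

    ``train_set``/``val_set`` are sequences of TrainingSample. The two sets
    must be patient-disjoint (checked when patient ids are present).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    tr_ids = {s.patient_id for s in train_set if s.patient_id}
    va_ids = {s.patient_id for s in val_set if s.patient_id}
    leak = tr_ids & va_ids
    if leak:
        raise ValueError(f"patients present in both train and val: {sorted(leak)}")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(network.params, lr=config.lr)
    history = TrainHistory()
    best_state = network.get_state()
    best_miou = -np.inf
    bad_epochs = 0
    decay_bad = 0

    images = np.stack([s.image for s in train_set]).astype(np.float32)
    masks = np.stack([s.mask for s in train_set]).astype(np.int64)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = images[idx][:, None]
            y = masks[idx]
            logits = network.forward(x, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            network.backward(dlogits.astype(np.float32))
            opt.step()
            losses.append(loss)

        miou = _val_miou(network, val_set)
        history.train_loss.append(float(np.mean(losses)))
        history.val_miou.append(miou)
        history.lr.append(opt.lr)
        history.stopped_epoch = epoch

        if miou > best_miou:
            best_miou = miou
            best_state = network.get_state()
            history.best_epoch = epoch
            bad_epochs = 0
            decay_bad = 0
        else:
            bad_epochs += 1
            decay_bad += 1
            if decay_bad >= config.lr_decay_patience:
                opt.lr *= config.lr_decay_factor
                decay_bad = 0
            if bad_epochs >= config.early_stop_patience:
                break

    network.set_state(best_state)
    return network, history
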