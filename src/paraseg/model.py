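"""High-level model facade: build, fit, inspect, reuse.

``UNetSegmenter`` bundles the network architecture and the training policy;
``fit`` consumes patient records (HU slice + ROI mask pairs), derives the
HU-filtered ground truth, optionally expands the training partition with
CT-aware augmentation, trains with early stopping on validation mIOU, and
returns a :class:`SegmentationResults` carrying the fitted network, the
training history, evaluation helpers and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctda import augment_dataset
from .dataset import apply_hu_filter, normalize_hu
from .evaluation import EvalResult, evaluate_samples
from .training import TrainConfig, TrainHistory, TrainingSample, train
from .unet import UNet, UNetConfig, build, load_checkpoint, predict, save_checkpoint

__all__ = ["UNetSegmenter", "SegmentationResults"]


def _records_to_samples(records) -> list[TrainingSample]:
    samples = []
    for rec in records:
        for img, roi in rec.slices:
            gt = apply_hu_filter(img, roi)
            samples.append(TrainingSample(normalize_hu(img), gt.pixels,
                                          rec.patient_id))
    return samples


class UNetSegmenter:
    """Paravertebral-muscle segmentation model (architecture + training policy)."""

    def __init__(self, unet_config: UNetConfig | None = None,
                 train_config: TrainConfig | None = None,
                 augment_factor: int = 1, augment_seed: int = 0):
        self.unet_config = unet_config or UNetConfig()
        self.train_config = train_config or TrainConfig()
        self.augment_factor = augment_factor
        self.augment_seed = augment_seed

    def fit(self, train_records, val_records) -> "SegmentationResults":
        """Train on patient records; validation guides early stopping."""
        val_set = _records_to_samples(val_records)
        if self.augment_factor > 1:
            raw = []
            pids = []
            for rec in train_records:
                for img, roi in rec.slices:
                    raw.append((img, apply_hu_filter(img, roi).pixels))
                    pids.append(rec.patient_id)
            aug = augment_dataset(raw, factor=self.augment_factor,
                                  seed=self.augment_seed)
            train_set = [TrainingSample(normalize_hu(a.image), a.mask,
                                        pids[a.source_index]) for a in aug]
        else:
            train_set = _records_to_samples(train_records)
        network, history = train(build(self.unet_config), train_set, val_set,
                                 self.train_config)
        return SegmentationResults(self, network, history,
                                   n_train=len(train_set), n_val=len(val_set))


@dataclass
class SegmentationResults:
    """Fitted model with its history and evaluation interface."""

    model: UNetSegmenter
    network: UNet
    history: TrainHistory
    n_train: int = 0
    n_val: int = 0

    def predict(self, hu_image):
        """Segment one HU slice (normalization applied here)."""
        return predict(self.network, normalize_hu(np.asarray(hu_image)))

    def evaluate(self, records, two_class: bool = False) -> EvalResult:
        return evaluate_samples(self.network, _records_to_samples(records),
                                two_class=two_class)

    def save(self, path) -> None:
        save_checkpoint(self.network, path)

    @staticmethod
    def load_network(path) -> UNet:
        return load_checkpoint(path)

    def summary(self) -> str:
        cfg, tcfg, h = self.model.unet_config, self.model.train_config, self.history
        lines = [
            "U-Net paravertebral muscle segmentation — fit summary",
            "=" * 56,
            f"{'first-level filters (n_base)':36s} {cfg.n_base}",
            f"{'encoder depth (L)':36s} {cfg.depth}",
            f"{'parameters':36s} {self.network.n_parameters()}",
            f"{'optimizer':36s} Adam (lr {tcfg.lr:g}, batch {tcfg.batch_size})",
            f"{'training samples':36s} {self.n_train}",
            f"{'validation samples':36s} {self.n_val}",
            f"{'epochs run':36s} {h.stopped_epoch}",
            f"{'best epoch (val mIOU)':36s} {h.best_epoch}",
            f"{'best validation mIOU':36s} {h.best_val_miou:.4f}",
            f"{'final training loss':36s} {h.train_loss[-1]:.4f}",
        ]
        return "\n".join(lines)
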