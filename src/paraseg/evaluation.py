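"""Jaccard/mIOU scoring, TP/FN/FP overlays and repeated holdout CV.

The headline metric is the foreground-class Jaccard index (intersection
over union) averaged over evaluation images; "mIOU" here means that
per-image average. When both masks are empty the score is defined as 1.0 —
perfect agreement on an empty slice is not penalized (this convention
affects per-image averages and is applied everywhere). A two-class-averaged
variant is available via ``two_class=True`` but is not the headline number.

Holdout cross-validation draws a fresh patient-level 6:2:2 split per round,
trains every model of the grid (n_base x with/without augmentation) on that
round's training set, scores it on that round's test set, and averages the
rounds without weighting; the selected model maximizes the final mean, with
lower across-round sd breaking ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctda import augment_dataset
from .dataset import apply_hu_filter, normalize_hu, split_by_patient
from .training import TrainConfig, TrainingSample, train
from .unet import UNetConfig, build

__all__ = ["EvalResult", "CVReport", "ModelVariant", "jaccard",
           "confusion_counts", "confusion_map", "evaluate_samples", "run_cv",
           "DEFAULT_MODEL_GRID"]

_COLORS = {
    "tp": (255, 255, 255),  # white
    "fn": (0, 255, 0),      # green
    "fp": (255, 0, 0),      # red
    "tn": (0, 0, 0),        # black
}


def _as_binary(mask, name):
    m = np.asarray(mask)
    u = np.unique(m)
    if not np.isin(u, (0, 1)).all():
        raise ValueError(f"{name} must be binary over {{0,1}}, found {u}")
    return m.astype(bool)


def jaccard(pred, gt) -> float:
    """Foreground |pred & gt| / |pred | gt|; 1.0 when both masks are empty."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    union = int(np.count_nonzero(p | g))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(p & g)) / union


def confusion_counts(pred, gt) -> dict[str, int]:
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    return {
        "tp": int(np.count_nonzero(p & g)),
        "fp": int(np.count_nonzero(p & ~g)),
        "fn": int(np.count_nonzero(~p & g)),
        "tn": int(np.count_nonzero(~p & ~g)),
    }


def confusion_map(pred, gt):
    """RGB overlay: TP white, FN green, FP red, TN black.

    Returns (rgb uint8 (H, W, 3), counts dict); the counts match
    :func:`confusion_counts` on the same pair.
    """
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    rgb = np.zeros(p.shape + (3,), dtype=np.uint8)
    rgb[p & g] = _COLORS["tp"]
    rgb[~p & g] = _COLORS["fn"]
    rgb[p & ~g] = _COLORS["fp"]
    return rgb, confusion_counts(pred, gt)


@dataclass
class EvalResult:
    """Per-image Jaccard scores with their mean and sd across images."""

    per_image: list[float]
    confusions: list[dict[str, int]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_image))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_image, ddof=1)) if len(self.per_image) > 1 else 0.0


def evaluate_samples(network, samples, two_class: bool = False) -> EvalResult:
    """Score a network on TrainingSample-like items (image in [0,1], mask)."""
    scores, confs = [], []
    for s in samples:
        logits = network.forward(s.image[None, None].astype(np.float32),
                                 train=False)
        pred = np.argmax(logits[0], axis=0).astype(np.uint8)
        fg = jaccard(pred, s.mask)
        if two_class:
            bg = jaccard(1 - pred, 1 - np.asarray(s.mask))
            scores.append((fg + bg) / 2.0)
        else:
            scores.append(fg)
        confs.append(confusion_counts(pred, s.mask))
    return EvalResult(scores, confs)


@dataclass(frozen=True)
class ModelVariant:
    """One cell of the model grid: first-level filter count x augmentation."""

    n_base: int
    augment: bool

    @property
    def label(self) -> str:
        return f"nbase{self.n_base}_{'DA' if self.augment else 'noDA'}"


DEFAULT_MODEL_GRID = (
    ModelVariant(16, False),
    ModelVariant(16, True),
    ModelVariant(32, False),
    ModelVariant(32, True),
)


@dataclass
class CVReport:
    """Three-round holdout CV result for a model grid."""

    rounds: list[dict[str, tuple[float, float]]]  # label -> (mean, sd)
    final: dict[str, float] = field(default_factory=dict)
    final_sd: dict[str, float] = field(default_factory=dict)
    selected_model: str = ""
    seeds: tuple[int, ...] = ()

    def finalize(self):
        labels = self.rounds[0].keys()
        for lab in labels:
            means = [r[lab][0] for r in self.rounds]
            self.final[lab] = float(np.mean(means))
            self.final_sd[lab] = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
        # best final mean; lower sd wins ties
        self.selected_model = min(
            self.final, key=lambda lab: (-self.final[lab], self.final_sd[lab]))
        return self


def _samples_for(cohort, ids):
    out = []
    for rec in cohort:
        if rec.patient_id not in ids:
            continue
        for img, roi in rec.slices:
            gt = apply_hu_filter(img, roi)
            out.append((img, gt.pixels, rec.patient_id))
    return out


def _to_training(samples):
    return [TrainingSample(normalize_hu(img), mask, pid)
            for img, mask, pid in samples]


def _derive_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def run_cv(cohort, model_grid=DEFAULT_MODEL_GRID, n_rounds: int = 3,
           seeds=None, unet_depth: int = 5, train_config: TrainConfig | None = None,
           augment_factor: int = 5, ratios=(0.6, 0.2, 0.2)) -> CVReport:
    """Repeated holdout CV over the model grid.

    Each round trains every model from scratch on its own seeded 6:2:2
    patient split and scores foreground mIOU on that round's test images.
    Deterministic given (cohort, seeds): all per-model seeds are derived
    from the round seed and the model's grid position.
    """
    if len(cohort) < 5:
        raise ValueError("cohort must contain at least 5 patients")
    if seeds is None:
        seeds = tuple(range(1, n_rounds + 1))
    seeds = tuple(int(s) for s in seeds)
    if len(set(seeds)) < n_rounds:
        raise ValueError(f"need {n_rounds} distinct seeds, got {seeds}")
    train_config = train_config or TrainConfig()
    ids = {rec.patient_id for rec in cohort}

    report = CVReport(rounds=[], seeds=seeds[:n_rounds])
    for r, round_seed in enumerate(seeds[:n_rounds]):
        split = split_by_patient(ids, ratios=ratios, seed=round_seed)
        train_raw = _samples_for(cohort, split.train_ids)
        val_set = _to_training(_samples_for(cohort, split.val_ids))
        test_set = _to_training(_samples_for(cohort, split.test_ids))
        round_scores = {}
        for m, variant in enumerate(model_grid):
            if variant.augment and augment_factor > 1:
                aug = augment_dataset(
                    [(img, mask) for img, mask, _ in train_raw],
                    factor=augment_factor,
                    seed=_derive_seed(round_seed, m, 1),
                )
                train_set = [
                    TrainingSample(normalize_hu(a.image), a.mask,
                                   train_raw[a.source_index][2])
                    for a in aug
                ]
            else:
                train_set = _to_training(train_raw)
            cfg = UNetConfig(n_base=variant.n_base, depth=unet_depth,
                             seed=_derive_seed(round_seed, m, 2))
            tcfg = TrainConfig(
                lr=train_config.lr, batch_size=train_config.batch_size,
                max_epochs=train_config.max_epochs,
                early_stop_patience=train_config.early_stop_patience,
                lr_decay_patience=train_config.lr_decay_patience,
                lr_decay_factor=train_config.lr_decay_factor,
                seed=_derive_seed(round_seed, m, 3),
            )
            net, _ = train(build(cfg), train_set, val_set, tcfg)
            res = evaluate_samples(net, test_set)
            round_scores[variant.label] = (res.mean, res.sd)
        report.rounds.append(round_scores)
    return report.finalize()
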