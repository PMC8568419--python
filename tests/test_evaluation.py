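"""Jaccard metric against brute-force set arithmetic; overlays; CV harness."""

import numpy as np
import pytest

from paraseg.evaluation import (
    CVReport,
    ModelVariant,
    confusion_counts,
    confusion_map,
    jaccard,
    run_cv,
)
from paraseg.training import TrainConfig


def brute_force_jaccard(pred, gt):
    """Independent oracle: explicit pixel-coordinate set arithmetic."""
    a = {(r, c) for r, c in zip(*np.nonzero(pred))}
    b = {(r, c) for r, c in zip(*np.nonzero(gt))}
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


class TestJaccard:
    def test_identical_nonempty_is_one(self):
        m = np.eye(4, dtype=np.uint8)
        assert jaccard(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert jaccard(a, b) == 0.0

    def test_two_by_two_overlap_is_one_third(self):
        """pred={p1,p2}, gt={p2,p3}: |∩|=1, |∪|=3."""
        pred = np.array([[1, 1], [0, 0]], np.uint8)
        gt = np.array([[0, 1], [1, 0]], np.uint8)
        assert jaccard(pred, gt) == pytest.approx(1 / 3)
        assert jaccard(pred, gt) == brute_force_jaccard(pred, gt)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3), np.uint8)
        assert jaccard(z, z) == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            jaccard(np.full((2, 2), 2), np.zeros((2, 2)))

    def test_matches_brute_force_on_random_small_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            h = int(rng.integers(1, 9))
            w = int(rng.integers(1, 9))
            pred = rng.integers(0, 2, (h, w)).astype(np.uint8)
            gt = rng.integers(0, 2, (h, w)).astype(np.uint8)
            assert jaccard(pred, gt) == pytest.approx(brute_force_jaccard(pred, gt))

    def test_symmetry_and_confusion_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            pred = rng.integers(0, 2, (6, 6)).astype(np.uint8)
            gt = rng.integers(0, 2, (6, 6)).astype(np.uint8)
            assert jaccard(pred, gt) == jaccard(gt, pred)
            c = confusion_counts(pred, gt)
            denom = c["tp"] + c["fp"] + c["fn"]
            if denom:
                assert jaccard(pred, gt) == pytest.approx(c["tp"] / denom)
            assert sum(c.values()) == pred.size


class TestConfusionMap:
    def test_perfect_prediction_only_white_and_black(self):
        gt = np.zeros((5, 5), np.uint8)
        gt[1:3, 1:3] = 1
        rgb, counts = confusion_map(gt, gt)
        colors = {tuple(c) for c in rgb.reshape(-1, 3)}
        assert colors <= {(255, 255, 255), (0, 0, 0)}
        assert counts["fp"] == counts["fn"] == 0

    def test_all_background_prediction_is_green_foreground(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[0] = 1
        rgb, _ = confusion_map(np.zeros_like(gt), gt)
        assert (rgb[0] == (0, 255, 0)).all()
        assert (rgb[1:] == 0).all()

    def test_color_counts_reproduce_confusion_on_enumerated_pair(self):
        pred = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]], np.uint8)
        gt = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 0]], np.uint8)
        # brute force enumeration of the 9 pixels
        tp = fn = fp = tn = 0
        for r in range(3):
            for c in range(3):
                if pred[r, c] and gt[r, c]:
                    tp += 1
                elif pred[r, c]:
                    fp += 1
                elif gt[r, c]:
                    fn += 1
                else:
                    tn += 1
        rgb, counts = confusion_map(pred, gt)
        assert counts == {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        flat = rgb.reshape(-1, 3)
        assert (flat == (255, 255, 255)).all(axis=1).sum() == tp
        assert (flat == (0, 255, 0)).all(axis=1).sum() == fn
        assert (flat == (255, 0, 0)).all(axis=1).sum() == fp
        assert (flat == (0, 0, 0)).all(axis=1).sum() == tn

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_map(np.zeros((2, 2)), np.zeros((3, 3)))


class TestCVReport:
    def test_final_is_unweighted_mean(self):
        rounds = [{"m": (0.9, 0.01)}, {"m": (0.8, 0.02)}, {"m": (0.7, 0.03)}]
        rep = CVReport(rounds=rounds).finalize()
        assert rep.final["m"] == pytest.approx((0.9 + 0.8 + 0.7) / 3, abs=1e-15)

    def test_selection_prefers_mean_then_lower_sd(self):
        rounds = [
            {"a": (0.9, 0.05), "b": (0.9, 0.01), "c": (0.5, 0.0)},
        ]
        rep = CVReport(rounds=rounds).finalize()
        # equal means: lower across-round sd wins; with one round both sd are
        # 0, so order falls back on the stable key ordering of equal tuples
        assert rep.selected_model in ("a", "b")
        rounds = [{"a": (0.9, 0.0), "b": (0.8, 0.0)}]
        assert CVReport(rounds=rounds).finalize().selected_model == "a"


@pytest.fixture(scope="module")
def tiny_cv_report(tiny_cohort):
    grid = (ModelVariant(2, False), ModelVariant(2, True))
    cfg = TrainConfig(lr=1e-3, max_epochs=2, early_stop_patience=5,
                      lr_decay_patience=5)
    return grid, run_cv(tiny_cohort, model_grid=grid, n_rounds=3,
                        seeds=(11, 12, 13), unet_depth=3, train_config=cfg,
                        augment_factor=2)


class TestRunCV:
    def test_report_structure_and_exact_averaging(self, tiny_cv_report):
        grid, rep = tiny_cv_report
        assert len(rep.rounds) == 3
        for v in grid:
            means = [r[v.label][0] for r in rep.rounds]
            assert rep.final[v.label] == pytest.approx(np.mean(means), abs=0)
        assert rep.selected_model in {v.label for v in grid}

    def test_round_splits_differ(self, tiny_cohort):
        from paraseg.dataset import split_by_patient

        ids = {r.patient_id for r in tiny_cohort}
        splits = [split_by_patient(ids, seed=s) for s in (11, 12, 13)]
        assert len({s.train_ids for s in splits}) > 1

    def test_duplicate_seeds_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="distinct"):
            run_cv(tiny_cohort, n_rounds=3, seeds=(1, 1, 2), unet_depth=3,
                   train_config=TrainConfig(max_epochs=1))

    def test_single_model_grid_selects_it(self, tiny_cohort):
        grid = (ModelVariant(2, False),)
        cfg = TrainConfig(lr=1e-3, max_epochs=1, early_stop_patience=2,
                          lr_decay_patience=2)
        rep = run_cv(tiny_cohort, model_grid=grid, n_rounds=2, seeds=(5, 6),
                     unet_depth=3, train_config=cfg)
        assert rep.selected_model == grid[0].label
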