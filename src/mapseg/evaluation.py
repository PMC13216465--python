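"""Segmentation metrics, aggregation protocols and bias handling.

IoU (Jaccard) and Dice are computed from pixel confusion counts,

    IoU = TP / (TP + FP + FN),    Dice = 2*TP / (2*TP + FP + FN),

aggregated either over a whole directory of mask pairs or with a
repeated group-sampling protocol (five groups of 100 images, averaged,
over 50 independent trials) used to compare against methods that report
subset-sampled scores. A paired Student's t-test compares per-image
scores between two methods.

`add_bias_patch` paints a black square over the lower-left corner of a
frame; public endoscopy corpora carry a position thumbnail there whose
presence correlates with the label, and masking it prevents shortcut
learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

#: side of the black square painted over the lower-left corner
BIAS_PATCH_SIZE = 64


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricResult:
    per_image: dict  # name -> (iou, dice)
    iou_mean: float
    iou_sd: float
    dice_mean: float
    dice_sd: float


@dataclass
class SamplingProtocol:
    groups: int = 5
    group_size: int = 100
    trials: int = 50
    seed: int = 0


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def iou_dice(c: ConfusionCounts) -> tuple:
    """(IoU, Dice); two empty masks agree perfectly by convention."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0, 1.0
    iou = c.tp / denom
    dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return iou, dice


def evaluate_masks(pred: np.ndarray, gt: np.ndarray) -> tuple:
    return iou_dice(confusion_counts(pred, gt))


def evaluate_dataset(pred_dir, gt_dir) -> MetricResult:
    """Per-image IoU/Dice over matching filenames; mean and population
    standard deviation."""
    from .io import mask_read

    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    pred_names = {p.name for p in pred_dir.glob("*.png")}
    gt_names = {p.name for p in gt_dir.glob("*.png")}
    common = sorted(pred_names & gt_names)
    if not common:
        raise FileNotFoundError(
            f"no matching mask filenames between {pred_dir} and {gt_dir}"
        )
    missing = sorted(pred_names ^ gt_names)
    if missing:
        raise FileNotFoundError(f"unpaired masks: {missing}")
    per_image = {}
    for name in common:
        per_image[name] = evaluate_masks(mask_read(pred_dir / name), mask_read(gt_dir / name))
    ious = np.array([v[0] for v in per_image.values()])
    dices = np.array([v[1] for v in per_image.values()])
    return MetricResult(
        per_image=per_image,
        iou_mean=float(ious.mean()),
        iou_sd=float(ious.std()),
        dice_mean=float(dices.mean()),
        dice_sd=float(dices.std()),
    )


def sampling_evaluation(scores, protocol: SamplingProtocol) -> dict:
    """Repeated-trial group sampling of per-image scores.

    Each trial draws ``groups`` disjoint groups of ``group_size``
    images (without replacement), averages the metric per group, then
    averages the group means; the across-trial mean and population sd
    are reported.
    """
    scores = np.asarray(scores, dtype=np.float64)
    need = protocol.groups * protocol.group_size
    if need > scores.size:
        raise ValueError(
            f"protocol needs {need} images but only {scores.size} scores given"
        )
    trial_means = np.empty(protocol.trials)
    root = np.random.SeedSequence(protocol.seed)
    for t, child in enumerate(root.spawn(protocol.trials)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(scores.size)[:need]
        group_means = scores[perm].reshape(protocol.groups, protocol.group_size).mean(axis=1)
        trial_means[t] = group_means.mean()
    return {
        "trial_means": trial_means,
        "mean": float(trial_means.mean()),
        "sd": float(trial_means.std()),
    }


def paired_t_test(scores_a, scores_b) -> tuple:
    """Two-sided paired Student's t-test on per-image differences."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score vectors of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("degenerate paired differences: zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def add_bias_patch(image: np.ndarray, size: int = BIAS_PATCH_SIZE) -> np.ndarray:
    """Paint a black square over the lower-left corner (idempotent)."""
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than bias patch {size}")
    out = image.copy()
    out[h - size :, :size] = 0
    return out
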