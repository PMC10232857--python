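"""Soft Dice loss, segmentation-ability scores, lesion-volume accounting
and the segmentation evaluation metrics.

Scientific background
---------------------
The federation weighs clients two ways:

* **Segmentation ability** ``P_i`` — per training iteration, the mean
  predicted probability on true-lesion voxels times (1 - soft Dice loss).
  Lesions occupy ~1% of the brain, so confidence restricted to true
  positives is far more informative than whole-image entropy.  The round
  mean of P_i becomes the client's aggregation weight.
* **Lesion volume ratio** ``vr_i`` — lesion voxels over brain voxels
  (brain = nonzero-intensity support), running-averaged over rounds.
  Clients with smaller lesion loads receive a larger loss weight.

Evaluation uses the case-averaged Dice (C-Dice) and voxel-pooled Dice
(V-Dice), plus TPR and FPR from the pooled confusion counts.  Note the
reported "FPR" is FP/(TP+FP), i.e. the false-discovery rate; it is kept
in that form to stay comparable with published multi-site lesion
segmentation tables.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AbilityObservation",
    "ClientState",
    "ConfusionCounts",
    "MetricsReport",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "segmentation_ability",
    "entropy_ability",
    "lesion_volume_ratio",
    "update_running_ratio",
    "confusion_counts",
    "volume_metrics",
    "evaluate_cases",
]

DICE_EPS = 1e-5


def _check_shapes(pred, target):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return pred, target.astype(np.float64)


def soft_dice_loss(pred, target, eps: float = DICE_EPS) -> float:
    """Soft Dice loss for probabilistic binary segmentation.

    ``1 - (2*sum(p*y) + eps) / (sum(p^2) + sum(y^2) + eps)``.  The eps
    smoothing (in numerator and denominator alike) makes a perfect binary
    prediction score exactly 0 and an empty/empty pair score 0 instead of
    being undefined.
    """
    p, y = _check_shapes(pred, target)
    num = 2.0 * float((p * y).sum()) + eps
    den = float((p * p).sum()) + float((y * y).sum()) + eps
    return 1.0 - num / den


def soft_dice_loss_grad(pred, target, eps: float = DICE_EPS) -> np.ndarray:
    """d(soft_dice_loss)/d(pred), for backpropagation."""
    p, y = _check_shapes(pred, target)
    num = 2.0 * (p * y).sum() + eps
    den = (p * p).sum() + (y * y).sum() + eps
    return ((2.0 * p * num) / den**2 - 2.0 * y / den).astype(np.float64)


@dataclass(frozen=True)
class AbilityObservation:
    """One iteration's segmentation-ability measurement.

    Absent (value None) exactly when the iteration's ground truth had no
    lesion voxels, where the ability score is undefined.
    """

    value: float | None
    reason_absent: str | None = None

    @property
    def present(self) -> bool:
        return self.value is not None


def segmentation_ability(pred, target) -> AbilityObservation:
    """Ability score: (mean predicted prob on lesion voxels) * (1 - Dice loss)."""
    p, y = _check_shapes(pred, target)
    ysum = float(y.sum())
    if ysum == 0:
        return AbilityObservation(value=None, reason_absent="empty_ground_truth")
    confidence = float((p * y).sum()) / ysum
    value = confidence * (1.0 - soft_dice_loss(p, y))
    return AbilityObservation(value=float(np.clip(value, 0.0, 1.0)))


def entropy_ability(pred, target) -> float:
    """Entropy-based ability variant: mean(-p*log p) * (1 - Dice loss).

    Whole-map prediction entropy replaces the true-positive confidence;
    natural log, with 0*log(0) := 0.
    """
    p, y = _check_shapes(pred, target)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(p > 0, -p * np.log(p), 0.0)
    return float(ent.mean()) * (1.0 - soft_dice_loss(p, y))


def lesion_volume_ratio(volume_patch, mask_patch) -> float:
    """Lesion voxels / brain voxels in a patch; brain = nonzero intensity.

    Returns 0 for an all-background patch.
    """
    vol = np.asarray(volume_patch)
    msk = np.asarray(mask_patch)
    if vol.shape != msk.shape:
        raise ValueError(f"shape mismatch: {vol.shape} vs {msk.shape}")
    brain = int(np.count_nonzero(vol))
    if brain == 0:
        return 0.0
    return float(np.count_nonzero(msk)) / brain


@dataclass
class ClientState:
    """Per-client running state across federated rounds.

    vr: running mean lesion-volume ratio over all completed rounds.
    rounds_seen: number of completed rounds k.
    round_ability: mean of the present ability observations in the last
        round (None if every observation was absent).
    """

    vr: float = 0.0
    rounds_seen: int = 0
    round_ability: float | None = None


def update_running_ratio(state: ClientState, round_mean: float) -> ClientState:
    """Fold one round's mean lesion-volume ratio into the running mean.

    vr <- ((k-1)*vr + round_mean) / k with k the new round count, i.e. the
    exact arithmetic mean of all round means seen so far.
    """
    if round_mean < 0:
        raise ValueError(f"round_mean must be >= 0, got {round_mean}")
    k = state.rounds_seen + 1
    vr = ((k - 1) * state.vr + round_mean) / k
    return ClientState(vr=vr, rounds_seen=k, round_ability=state.round_ability)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise confusion counts (true negatives are not tracked)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def confusion_counts(pred_mask, true_mask) -> ConfusionCounts:
    """Voxel confusion counts between two binary masks."""
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(true_mask).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def volume_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(dice, tpr, fpr) from confusion counts, on the 0-1 scale.

    dice = 2TP/(FN+2TP+FP); tpr = TP/(TP+FN); fpr = FP/(TP+FP) — the
    precision-complement form used in multi-site lesion segmentation
    reports.  Zero-denominator conventions: dice=1 when TP=FP=FN=0,
    tpr=1 when TP+FN=0, fpr=0 when TP+FP=0.
    """
    dice = 1.0 if (c.tp + c.fp + c.fn) == 0 else 2 * c.tp / (c.fn + 2 * c.tp + c.fp)
    tpr = 1.0 if (c.tp + c.fn) == 0 else c.tp / (c.tp + c.fn)
    fpr = 0.0 if (c.tp + c.fp) == 0 else c.fp / (c.tp + c.fp)
    return dice, tpr, fpr


@dataclass
class MetricsReport:
    """Segmentation metrics, in percent, plus the pooled counts behind them.

    c_dice: mean of per-case Dice scores.
    v_dice / v_tpr / v_fpr: computed from confusion counts pooled over
        every voxel of every case.
    """

    c_dice: float
    v_dice: float
    v_tpr: float
    v_fpr: float
    counts: ConfusionCounts
    n_cases: int
    per_case_dice: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "C-Dice": self.c_dice,
            "V-Dice": self.v_dice,
            "V-TPR": self.v_tpr,
            "V-FPR": self.v_fpr,
            "n_cases": self.n_cases,
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
        }

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @staticmethod
    def write_csv(path, reports: dict[str, "MetricsReport"]):
        """One row per client: (client, C-Dice, V-Dice, V-TPR, V-FPR)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["client", "C-Dice", "V-Dice", "V-TPR", "V-FPR"])
            for client, r in reports.items():
                w.writerow(
                    [client] + [f"{v:.2f}" for v in (r.c_dice, r.v_dice, r.v_tpr, r.v_fpr)]
                )


def evaluate_cases(
    predictions: dict[str, np.ndarray], ground_truth: dict[str, np.ndarray]
) -> MetricsReport:
    """Score predicted binary masks against reference masks.

    C-Dice averages per-case Dice scores; the V-metrics pool confusion
    counts over all cases first.  All four are reported in percent.
    """
    if not predictions:
        raise ValueError("need at least one case")
    if set(predictions) != set(ground_truth):
        raise ValueError("prediction and ground-truth case ids differ")
    total = ConfusionCounts(0, 0, 0)
    per_case = {}
    for case_id in sorted(predictions):
        pred, true = predictions[case_id], ground_truth[case_id]
        if np.asarray(pred).shape != np.asarray(true).shape:
            raise ValueError(f"shape mismatch in case {case_id!r}")
        c = confusion_counts(pred, true)
        per_case[case_id] = volume_metrics(c)[0]
        total = total + c
    v_dice, v_tpr, v_fpr = volume_metrics(total)
    return MetricsReport(
        c_dice=100.0 * float(np.mean(list(per_case.values()))),
        v_dice=100.0 * v_dice,
        v_tpr=100.0 * v_tpr,
        v_fpr=100.0 * v_fpr,
        counts=total,
        n_cases=len(per_case),
        per_case_dice={k: 100.0 * v for k, v in per_case.items()},
    )
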