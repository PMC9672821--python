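"""Cross-validation planning and the reported metrics.

Within each treatment arm a patient-level fivefold split is assigned once
and reused by every prediction method.  For the trained networks a
validation subset (15% of each fold's training portion) is carved out, so
the nominal allocation is 68% training / 12% validation / 20% testing.

Metrics: Dice overlap of the binarized prediction, an empirical ROC built
from 100 binarization thresholds with per-patient curves averaged pointwise
into the method curve, signed and absolute lesion volume errors in ml, and
Spearman rank correlations between learned temporal feature maps and the
four perfusion parameter maps.  Probability maps are binarized at the
leave-one-out optimal threshold scanned over 101 values (0 .. 1, step 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import ThresholdGrid, loo_optimize, probability_threshold_grid

__all__ = [
    "FoldPlan",
    "TRAIN_FRACTION",
    "VAL_FRACTION",
    "TEST_FRACTION",
    "assign_folds",
    "dice",
    "roc_curve_auc",
    "average_roc",
    "volume_errors",
    "binarize_optimal",
    "correlate_features",
]

N_FOLDS = 5
VAL_OF_TRAIN = 0.15  # validation share of each fold's training portion
TEST_FRACTION = 1.0 / N_FOLDS                      # 20%
VAL_FRACTION = (1 - TEST_FRACTION) * VAL_OF_TRAIN  # 12%
TRAIN_FRACTION = 1 - TEST_FRACTION - VAL_FRACTION  # 68%
N_ROC_THRESHOLDS = 100


@dataclass
class FoldPlan:
    """Patient-to-fold assignment for one arm, plus per-fold validation lists."""

    arm: str
    folds: dict[str, int]                      # patient id -> test-fold index
    validation: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return max(self.folds.values()) + 1

    def test_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.folds.items() if f == fold)

    def val_patients(self, fold: int) -> list[str]:
        return list(self.validation.get(fold, []))

    def train_patients(self, fold: int) -> list[str]:
        """Training portion of the fold minus its validation patients."""
        val = set(self.val_patients(fold))
        return sorted(
            p for p, f in self.folds.items() if f != fold and p not in val
        )


def assign_folds(
    cohort: pd.DataFrame, seed: int, n_folds: int = N_FOLDS
) -> dict[str, FoldPlan]:
    """Deterministic per-arm fold plans from a cohort manifest.

    Patients are shuffled once per arm and dealt into ``n_folds`` near-equal
    test folds; each fold's validation set samples 15% (at least one
    patient) of its training portion.  The plan is a pure function of the
    manifest and the seed and is reused across all methods.
    """
    plans: dict[str, FoldPlan] = {}
    for arm, group in cohort.groupby("arm", sort=True):
        pids = sorted(group["patient_id"].tolist())
        if len(pids) < n_folds:
            raise ValueError(
                f"arm {arm}: {len(pids)} patients < {n_folds} folds"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(hash_arm(arm),))
        )
        order = [pids[i] for i in rng.permutation(len(pids))]
        folds = {p: i % n_folds for i, p in enumerate(order)}
        plan = FoldPlan(arm=str(arm), folds=folds)
        for fold in range(n_folds):
            pool = sorted(p for p, f in folds.items() if f != fold)
            n_val = max(1, int(round(VAL_OF_TRAIN * len(pool))))
            pick = rng.permutation(len(pool))[:n_val]
            plan.validation[fold] = sorted(pool[i] for i in pick)
        plans[str(arm)] = plan
    return plans


def hash_arm(arm: str) -> int:
    return int.from_bytes(arm.encode()[:4].ljust(4, b"\0"), "big")


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|P∩G| / (|P|+|G|); two empty masks count as 1."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth grids differ")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def roc_curve_auc(
    prob: np.ndarray,
    truth: np.ndarray,
    n_thresholds: int = N_ROC_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical per-patient ROC from a fixed threshold grid.

    ``prob`` and ``truth`` are flat arrays restricted to in-hemisphere
    voxels.  Binarization is ``prob > t`` for t in 0.00, 0.01, ... (100
    values); the curve is anchored at (0,0) and (1,1) and the AUC is the
    trapezoid area over the patient's own curve.  Returns
    ``(fpr, tpr, auc)``; a single-class truth yields NaN AUC.
    """
    prob = np.asarray(prob, dtype=float).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if prob.shape != truth.shape:
        raise ValueError("prob and truth lengths differ")
    npos = int(truth.sum())
    nneg = truth.size - npos
    grid = np.arange(n_thresholds) / n_thresholds
    # vectorized confusion counts per threshold
    pred = prob[None, :] > grid[:, None]
    tp = (pred & truth[None, :]).sum(axis=1)
    fp = (pred & ~truth[None, :]).sum(axis=1)
    if npos == 0 or nneg == 0:
        return np.full(n_thresholds, np.nan), np.full(n_thresholds, np.nan), float("nan")
    tpr = tp / npos
    fpr = fp / nneg
    xs = np.concatenate([[0.0], fpr[::-1], [1.0]])
    ys = np.concatenate([[0.0], tpr[::-1], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return fpr, tpr, auc


def average_roc(curves: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Method-level ROC: pointwise mean of patient curves at matching
    thresholds (single-class patients excluded beforehand)."""
    fprs = np.stack([c[0] for c in curves])
    tprs = np.stack([c[1] for c in curves])
    return fprs.mean(axis=0), tprs.mean(axis=0)


def volume_errors(
    pred: np.ndarray, truth: np.ndarray, voxel_spacing: tuple[float, float, float]
) -> tuple[float, float]:
    """Signed (positive = overestimate) and absolute volume error in ml."""
    voxvol_ml = float(np.prod(voxel_spacing)) / 1000.0
    signed = (int(np.asarray(pred).astype(bool).sum())
              - int(np.asarray(truth).astype(bool).sum())) * voxvol_ml
    return signed, abs(signed)


def binarize_optimal(
    prob_maps: list[np.ndarray],
    truths: list[np.ndarray],
    grid: ThresholdGrid | None = None,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Leave-one-out optimal binarization for an arm's probability maps.

    Builds the patient x grid Dice table, delegates threshold selection to
    the leave-one-out optimizer, and returns
    ``(masks, thresholds, dice_table)``.
    """
    grid = grid or probability_threshold_grid()
    if len(prob_maps) != len(truths) or len(prob_maps) < 2:
        raise ValueError("need matching prob/truth lists with >= 2 patients")
    table = np.empty((len(prob_maps), len(grid)))
    for i, (p, g) in enumerate(zip(prob_maps, truths)):
        for j, t in enumerate(grid.values):
            table[i, j] = dice(p > t, g)
    thresholds = loo_optimize(table, grid)
    masks = [p > t for p, t in zip(prob_maps, thresholds)]
    return masks, thresholds, table


def correlate_features(
    feature_maps: np.ndarray,
    param_maps: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Spearman rho between each learned feature channel and each perfusion
    parameter channel over pooled in-mask voxels.

    ``feature_maps``: (F, ...) learned channels; ``param_maps``: (P, ...);
    returns an (F, P) table.  Constant channels yield NaN entries.
    """
    F = feature_maps.shape[0]
    P = param_maps.shape[0]
    fm = feature_maps[:, mask]
    pm = param_maps[:, mask]
    out = np.full((F, P), np.nan)
    for i in range(F):
        if np.ptp(fm[i]) == 0:
            continue
        for j in range(P):
            if np.ptp(pm[j]) == 0:
                continue
            out[i, j] = stats.spearmanr(fm[i], pm[j]).statistic
    return out


def __getattr__(name):  # pragma: no cover - thin re-export
    """Expose the experiment driver on the evaluation surface without a
    circular import."""
    if name == "run_experiment":
        from .pipeline import run_experiment

        return run_experiment
    raise AttributeError(name)
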