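"""Comparison predictors: optimal Tmax thresholding and a voxelwise forest.

Tmax thresholding predicts infarct where Tmax strictly exceeds a threshold;
the operating threshold is chosen per patient by leave-one-out (LOO)
maximization of the mean Dice over the other patients of the same treatment
arm, scanned over 120 candidate thresholds (0.2 .. 24.0 s in 0.2 s steps).
The widely used clinical operating point reported for the reference cohort
is 7.2 s (:data:`REFERENCE_TMAX_THRESHOLD_S`); it is cohort-dependent.

The random decision forest (RDF) is a regression forest over the four
perfusion parameters (CBF, CBV, MTT, Tmax) of each voxel: 100 trees, each
fitted on a random half (r = 0.5) of the pooled training instances.  Class
balance is restored per patient by stratified random undersampling before
pooling.  Because the voxelwise forest ignores spatial context, its binarized
predictions are denoised by in-slice morphological closing (3x3) followed by
removal of 3D connected components smaller than 10 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ThresholdGrid",
    "RDFConfig",
    "REFERENCE_TMAX_THRESHOLD_S",
    "tmax_threshold_grid",
    "probability_threshold_grid",
    "tmax_predict",
    "loo_optimize",
    "stratified_undersample",
    "rdf_train",
    "rdf_predict",
    "noise_filter",
]

REFERENCE_TMAX_THRESHOLD_S = 7.2


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing candidate thresholds (seconds or probability)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("threshold grid must be a nonempty 1D array")
        if not np.all(np.isfinite(v)) or np.any(np.diff(v) <= 0):
            raise ValueError("threshold grid must be finite and strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def tmax_threshold_grid() -> ThresholdGrid:
    """120 Tmax thresholds spanning (0, 24] s at 0.2 s intervals.

    The degenerate 0 s threshold is excluded, keeping 0.2 .. 24.0.
    """
    return ThresholdGrid(np.round(np.arange(1, 121) * 0.2, 10))


def probability_threshold_grid() -> ThresholdGrid:
    """101 probability thresholds 0.00 .. 1.00 at 0.01 intervals."""
    return ThresholdGrid(np.round(np.arange(101) * 0.01, 10))


def tmax_predict(tmax_map: np.ndarray, threshold: float) -> np.ndarray:
    """Infarct prediction: voxels whose Tmax strictly exceeds the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return np.asarray(tmax_map) > threshold


@dataclass(frozen=True)
class RDFConfig:
    n_trees: int = 100
    r: float = 0.5  # fraction of pooled training instances per tree
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r <= 1:
            raise ValueError("r must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def loo_optimize(dice_table: np.ndarray, grid: ThresholdGrid) -> np.ndarray:
    """Per-patient leave-one-out optimal threshold.

    ``dice_table[i, j]`` is patient *i*'s Dice at grid threshold *j*.  For
    each patient the threshold maximizing the mean Dice over *all other*
    patients is returned; ties resolve to the smallest threshold.
    """
    table = np.asarray(dice_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != len(grid):
        raise ValueError("dice_table must be (patients x grid)")
    n = table.shape[0]
    if n < 2:
        raise ValueError("leave-one-out needs at least two patients")
    loo_mean = (table.sum(axis=0)[None, :] - table) / (n - 1)
    best = np.argmax(loo_mean, axis=1)  # first (smallest) argmax on ties
    return grid.values[best]


def stratified_undersample(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of all minority-class instances plus an equal number of
    randomly drawn majority-class instances (exact 1:1 balance)."""
    labels = np.asarray(labels).astype(bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for undersampling")
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    chosen = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, chosen]))


def rdf_train(
    features_per_patient: list[np.ndarray],
    labels_per_patient: list[np.ndarray],
    cfg: RDFConfig | None = None,
) -> RandomForestRegressor:
    """Train the voxelwise regression forest.

    ``features_per_patient[i]`` is an (n_voxels, 4) array of CBF/CBV/MTT/Tmax
    for one training patient; undersampling is applied per patient before
    pooling so each patient contributes a balanced sample.
    """
    cfg = cfg or RDFConfig()
    rng = np.random.default_rng(cfg.seed)
    xs, ys = [], []
    for feats, labels in zip(features_per_patient, labels_per_patient):
        labels = np.asarray(labels).astype(bool).ravel()
        if feats.shape[0] != labels.size:
            raise ValueError("features and labels disagree in length")
        idx = stratified_undersample(labels, rng)
        xs.append(np.asarray(feats, dtype=float)[idx])
        ys.append(labels[idx].astype(float))
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_samples=cfg.r,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def rdf_predict(model: RandomForestRegressor, features: np.ndarray) -> np.ndarray:
    """Probabilistic tissue outcome in [0, 1]: the mean over tree outputs."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"expected (n, {model.n_features_in_}) features, got {features.shape}"
        )
    return np.clip(model.predict(features), 0.0, 1.0)


def noise_filter(mask: np.ndarray, min_component_voxels: int = 10) -> np.ndarray:
    """Denoise a binary lesion mask.

    In-slice morphological closing with a 3x3 kernel (per z-slice), then
    removal of 3D 6-connected components with fewer than
    ``min_component_voxels`` voxels (strictly fewer; 10-voxel components
    survive the default).
    """
    mask = np.asarray(mask).astype(bool)
    closed = np.empty_like(mask)
    footprint = np.ones((3, 3), dtype=bool)
    for z in range(mask.shape[2]):
        closed[:, :, z] = ndimage.binary_closing(mask[:, :, z], structure=footprint)
    labels, n = ndimage.label(
        closed, structure=ndimage.generate_binary_structure(3, 1)
    )
    if n == 0:
        return closed
    sizes = ndimage.sum_labels(closed, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_voxels) + 1
    return np.isin(labels, keep)
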