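"""Raw 4D perfusion series -> concentration-time curves + masks.

Stages, in acquisition order: baseline average over the first three frames,
(no-op) motion-correction hook, baseline subtraction, temporal resampling to
1 s with B-spline smoothing, brain-mask extraction from the baseline average,
and a midsagittal hemisphere split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline, CubicSpline

__all__ = [
    "PerfusionSeries",
    "MaskSet",
    "baseline_average",
    "baseline_subtract",
    "motion_correct",
    "temporal_resample",
    "brain_mask",
    "hemisphere_split",
]

N_BASELINE = 3  # frames averaged for the pre-contrast baseline


@dataclass
class PerfusionSeries:
    """4D scalar series (X, Y, Z, T) with spacing metadata.

    ``domain`` tracks the processing state: ``raw`` (HU), ``concentration``
    (baseline-subtracted HU), or ``residual`` (deconvolved flow-scaled
    residue curves).
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    dt: float
    domain: str = "raw"

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("PerfusionSeries expects a 4D array (X,Y,Z,T)")
        if self.values.shape[-1] < 4:
            raise ValueError("PerfusionSeries needs at least 4 timepoints")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.domain not in {"raw", "concentration", "residual"}:
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[-1]

    @property
    def timepoints(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt


@dataclass
class MaskSet:
    """Brain mask partitioned into hemispheres; left/right are disjoint."""

    brain: np.ndarray
    left: np.ndarray
    right: np.ndarray
    ipsilateral: str = "left"

    def hemisphere(self, side: str) -> np.ndarray:
        if side not in {"left", "right"}:
            raise ValueError("side must be 'left' or 'right'")
        return self.left if side == "left" else self.right


def baseline_average(series: PerfusionSeries) -> np.ndarray:
    """Temporal mean intensity projection of the first three timepoints."""
    if series.n_timepoints < N_BASELINE:
        raise ValueError("baseline average requires at least 3 timepoints")
    if series.domain != "raw":
        raise ValueError("baseline average is defined on the raw series")
    return series.values[..., :N_BASELINE].mean(axis=-1)


def motion_correct(
    series: PerfusionSeries,
    baseline: np.ndarray,
    register: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> PerfusionSeries:
    """Hook for 3D rigid motion correction against the baseline average.

    The default is a pass-through (motion-free synthetic data); a custom
    per-frame registration callable ``register(frame, reference) -> frame``
    may be supplied for data that needs it.
    """
    if register is None:
        return series
    frames = [
        register(series.values[..., t], baseline)
        for t in range(series.n_timepoints)
    ]
    return replace(series, values=np.stack(frames, axis=-1))


def baseline_subtract(
    series: PerfusionSeries, baseline: np.ndarray
) -> PerfusionSeries:
    """Subtract the baseline average from each frame -> concentration domain."""
    if baseline.shape != series.values.shape[:3]:
        raise ValueError(
            f"baseline shape {baseline.shape} does not match series "
            f"{series.values.shape[:3]}"
        )
    return replace(
        series, values=series.values - baseline[..., None], domain="concentration"
    )


def _lsq_bspline_operator(
    t_in: np.ndarray, t_out: np.ndarray, knot_every: int = 2, degree: int = 3
) -> np.ndarray:
    """Linear operator mapping samples on t_in to a smoothed evaluation on
    t_out via least-squares cubic B-spline approximation with interior knots
    every ``knot_every`` input samples."""
    interior = t_in[knot_every:-1:knot_every]
    knots = np.concatenate(
        [np.repeat(t_in[0], degree + 1), interior, np.repeat(t_in[-1], degree + 1)]
    )
    A_in = BSpline.design_matrix(t_in, knots, degree).toarray()
    A_out = BSpline.design_matrix(np.clip(t_out, t_in[0], t_in[-1]), knots, degree)
    return A_out.toarray() @ np.linalg.pinv(A_in)


def temporal_resample(
    series: PerfusionSeries, target_dt: float = 1.0, smooth: bool = True
) -> PerfusionSeries:
    """Resample the time axis to ``target_dt`` (default 1 s).

    With ``smooth=True`` the curves are replaced by a least-squares cubic
    B-spline approximation (interior knots every 2 input samples) evaluated
    on the new grid; otherwise an interpolating cubic spline is used.  The
    covered duration is preserved to within one output sample.
    """
    if series.n_timepoints < 4:
        raise ValueError("temporal resampling requires at least 4 timepoints")
    t_in = series.timepoints
    if not smooth and abs(series.dt - target_dt) < 1e-12:
        return replace(series, values=series.values.copy())
    n_out = int(np.floor(t_in[-1] / target_dt)) + 1
    t_out = np.arange(n_out) * target_dt
    if smooth:
        M = _lsq_bspline_operator(t_in, t_out)
        values = np.tensordot(series.values, M, axes=([3], [1]))
    else:
        cs = CubicSpline(t_in, series.values, axis=-1)
        values = cs(t_out)
    return replace(series, values=values, dt=target_dt)


def brain_mask(
    baseline_avg: np.ndarray,
    blur_sigma: tuple[float, float, float] = (1.0, 1.0, 0.0),
    hu_range: tuple[float, float] = (1.0, 100.0),
    kernel: tuple[int, int, int] = (5, 5, 1),
) -> np.ndarray:
    """Brain tissue mask from the baseline average image.

    Pipeline: Gaussian blur, exclusive threshold ``lo < HU < hi``, erosion by
    a 5x5x1 kernel, largest 6-connected 3D component, dilation by the same
    kernel.  The skull shell (>100 HU) and air are excluded; CSF is kept.
    """
    blurred = ndimage.gaussian_filter(np.asarray(baseline_avg, float), blur_sigma)
    lo, hi = hu_range
    mask = (blurred > lo) & (blurred < hi)
    if not mask.any():
        raise ValueError("no brain found: threshold range selected no voxels")
    structure = np.ones(kernel, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=structure)
    if not eroded.any():
        raise ValueError("no brain found: erosion removed all voxels")
    labels, n = ndimage.label(eroded, structure=ndimage.generate_binary_structure(3, 1))
    largest = np.argmax(ndimage.sum_labels(eroded, labels, index=range(1, n + 1))) + 1
    component = labels == largest
    return ndimage.binary_dilation(component, structure=structure)


def hemisphere_split(brain: np.ndarray, ipsilateral: str = "left") -> MaskSet:
    """Partition the brain mask at the midsagittal plane of its bounding box.

    'Left' is the lower-x half (radiological convention on phantom grids).
    """
    if not brain.any():
        raise ValueError("cannot split an empty brain mask")
    xs = np.flatnonzero(brain.any(axis=(1, 2)))
    mid = (xs[0] + xs[-1]) / 2  # midsagittal plane of the bounding box
    x = np.arange(brain.shape[0])[:, None, None]
    left = brain & (x < mid)
    right = brain & (x >= mid)
    return MaskSet(brain=brain, left=left, right=right, ipsilateral=ipsilateral)
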