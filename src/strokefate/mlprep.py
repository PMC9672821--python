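"""Model-ready tensors: temporal ROI, hemisphere cropping/padding, scaling.

The spatiotemporal inputs (concentration and residue curves) are reduced to a
fixed 32-timepoint window.  Concentration curves are centered on the global
enhancement peak found within 40 s of contrast arrival (arrival = first frame
whose in-mask mean exceeds 115% of the baseline mean); residue curves, having
no bolus delay left after deconvolution, are simply cropped to the first 32
timepoints.  Windows extending past either end of the series are filled with
the mean of the first/last three existing timepoints.

Spatially, each volume is masked to the ipsilateral hemisphere, cropped
in-slice to the hemisphere bounding box and padded symmetrically to a fixed
in-slice shape (clinical default 480x320 at 0.45 mm; desk-scale phantoms use
smaller shapes).  Standardization is a plain z-score with parameters fitted
on training data only and shared across all timepoints of a feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preproc import MaskSet, PerfusionSeries, baseline_average

__all__ = [
    "ROIConfig",
    "SpatialLayout",
    "Standardizer",
    "detect_arrival",
    "roi_center",
    "temporal_roi",
    "crop_leading",
    "spatial_prepare",
    "spatial_restore",
]

logger = logging.getLogger(__name__)

CLINICAL_PAD_SHAPE = (480, 320)
CLINICAL_INSLICE_MM = 0.45


@dataclass(frozen=True)
class ROIConfig:
    window_len: int = 32          # timepoints kept for spatiotemporal models
    arrival_factor: float = 1.15  # mean enhancement ratio defining arrival
    search_horizon_s: float = 40.0  # peak search window after arrival (s)
    edge_pad_samples: int = 3     # samples averaged for edge padding

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.arrival_factor <= 1:
            raise ValueError("arrival_factor must exceed 1")


def detect_arrival(
    series_raw: PerfusionSeries, brain: np.ndarray, cfg: ROIConfig | None = None
) -> int | None:
    """First timepoint whose in-mask mean HU exceeds ``arrival_factor`` times
    the in-mask mean of the baseline average image; ``None`` if no frame
    qualifies (flat or non-enhancing series)."""
    cfg = cfg or ROIConfig()
    if series_raw.domain != "raw":
        raise ValueError("arrival detection uses the raw (pre-subtraction) series")
    if not brain.any():
        raise ValueError("empty brain mask")
    ref = float(baseline_average(series_raw)[brain].mean())
    means = series_raw.values[brain].mean(axis=0)
    qualifying = np.flatnonzero(means > cfg.arrival_factor * ref)
    return int(qualifying[0]) if qualifying.size else None


def roi_center(
    series: PerfusionSeries,
    arrival: int | None,
    brain: np.ndarray,
    cfg: ROIConfig | None = None,
) -> int:
    """Timepoint of maximum in-mask mean intensity within the search horizon
    after arrival.  With no detected arrival the global peak is used."""
    cfg = cfg or ROIConfig()
    means = series.values[brain].mean(axis=0)
    if arrival is None:
        logger.warning("no contrast arrival detected; centering on global peak")
        return int(np.argmax(means))
    if arrival >= series.n_timepoints:
        raise ValueError("arrival index beyond the end of the series")
    stop = min(series.n_timepoints, arrival + int(cfg.search_horizon_s / series.dt) + 1)
    return arrival + int(np.argmax(means[arrival:stop]))


def _window(values: np.ndarray, start: int, cfg: ROIConfig) -> np.ndarray:
    """Extract ``[start, start+window_len)`` along the last axis, padding
    out-of-range samples with the mean of the first/last existing samples."""
    T = values.shape[-1]
    n = cfg.window_len
    stop = start + n
    head = values[..., : cfg.edge_pad_samples].mean(axis=-1, keepdims=True)
    tail = values[..., -cfg.edge_pad_samples:].mean(axis=-1, keepdims=True)
    parts = []
    if start < 0:
        parts.append(np.repeat(head, -start, axis=-1))
    parts.append(values[..., max(start, 0): min(stop, T)])
    if stop > T:
        parts.append(np.repeat(tail, stop - T, axis=-1))
    return np.concatenate(parts, axis=-1)


def temporal_roi(
    series: PerfusionSeries, center: int, cfg: ROIConfig | None = None
) -> PerfusionSeries:
    """Fixed-length window with the peak at position ``window_len // 2``.

    For the default 32-sample window the center sits at 0-based index 16,
    i.e. the window covers ``[center-16, center+15]``.
    """
    cfg = cfg or ROIConfig()
    half = cfg.window_len // 2
    values = _window(series.values, center - half, cfg)
    out = PerfusionSeries(
        values=values, voxel_spacing=series.voxel_spacing, dt=series.dt,
        domain=series.domain,
    )
    return out


def crop_leading(
    series: PerfusionSeries, cfg: ROIConfig | None = None
) -> PerfusionSeries:
    """First ``window_len`` timepoints (used for residue curves, which carry
    no bolus delay); tail-padded with the last-3-sample mean if shorter."""
    cfg = cfg or ROIConfig()
    values = _window(series.values, 0, cfg)
    return PerfusionSeries(
        values=values, voxel_spacing=series.voxel_spacing, dt=series.dt,
        domain=series.domain,
    )


# --------------------------------------------------------------------------
# spatial preparation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialLayout:
    """Bookkeeping to undo hemisphere crop + pad (maps back to scan space)."""

    volume_shape: tuple[int, int, int]
    crop_origin: tuple[int, int]      # in-slice origin of the hemisphere bbox
    crop_shape: tuple[int, int]
    pad_offset: tuple[int, int]       # content origin inside the padded slice
    pad_shape: tuple[int, int]


def spatial_prepare(
    volume: np.ndarray,
    masks: MaskSet,
    side: str | None = None,
    pad_shape: tuple[int, int] = CLINICAL_PAD_SHAPE,
    zoom_factor: float | None = None,
) -> tuple[np.ndarray, SpatialLayout]:
    """Mask a volume to one hemisphere and pad in-slice to a fixed shape.

    ``volume`` may be 3D (X,Y,Z) or 4D (X,Y,Z,T); out-of-mask voxels are
    zeroed, the in-slice field of view is cropped to the hemisphere bounding
    box and padded symmetrically to ``pad_shape`` (ties toward the leading
    edge).  ``zoom_factor`` optionally resamples in-slice first (clinical
    0.45 mm regridding); phantoms keep their native grid.
    """
    side = side or masks.ipsilateral
    hemi = masks.hemisphere(side)
    if volume.shape[:3] != hemi.shape:
        raise ValueError("volume and mask grids differ")
    masked = np.where(hemi[..., None] if volume.ndim == 4 else hemi, volume, 0.0)
    if zoom_factor is not None and zoom_factor != 1.0:
        zoom = [zoom_factor, zoom_factor, 1.0] + ([1.0] if volume.ndim == 4 else [])
        masked = ndimage.zoom(masked, zoom, order=1)
        hemi = ndimage.zoom(hemi.astype(float), zoom[:3], order=0) > 0.5
    xs = np.flatnonzero(hemi.any(axis=(1, 2)))
    ys = np.flatnonzero(hemi.any(axis=(0, 2)))
    crop_origin = (int(xs[0]), int(ys[0]))
    crop_shape = (int(xs[-1] - xs[0] + 1), int(ys[-1] - ys[0] + 1))
    if crop_shape[0] > pad_shape[0] or crop_shape[1] > pad_shape[1]:
        raise ValueError(
            f"hemisphere content {crop_shape} exceeds pad shape {pad_shape}"
        )
    cropped = masked[xs[0]: xs[-1] + 1, ys[0]: ys[-1] + 1]
    off = tuple((p - c + 1) // 2 for p, c in zip(pad_shape, crop_shape))
    out_shape = (pad_shape[0], pad_shape[1]) + masked.shape[2:]
    out = np.zeros(out_shape, dtype=float)
    out[off[0]: off[0] + crop_shape[0], off[1]: off[1] + crop_shape[1]] = cropped
    layout = SpatialLayout(
        volume_shape=tuple(int(s) for s in hemi.shape),
        crop_origin=crop_origin,
        crop_shape=crop_shape,
        pad_offset=(int(off[0]), int(off[1])),
        pad_shape=tuple(pad_shape),
    )
    return out, layout


def spatial_restore(padded: np.ndarray, layout: SpatialLayout) -> np.ndarray:
    """Invert :func:`spatial_prepare` (native-grid layouts only)."""
    ox, oy = layout.pad_offset
    cx, cy = layout.crop_shape
    content = padded[ox: ox + cx, oy: oy + cy]
    out = np.zeros(layout.volume_shape[:2] + padded.shape[2:], dtype=padded.dtype)
    gx, gy = layout.crop_origin
    out[gx: gx + cx, gy: gy + cy] = content
    return out


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

class Standardizer:
    """Per-feature z-scoring fitted on training data.

    A 'feature' is the leading channel axis; statistics pool every other axis
    including time, so all timepoints of a spatiotemporal feature share one
    (mean, std) pair.  Test-time data is transformed with the training
    parameters only.
    """

    def __init__(self, eps: float = 1e-12) -> None:
        self.eps = eps
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, stack: np.ndarray) -> "Standardizer":
        axes = tuple(range(1, stack.ndim))
        self.mean_ = stack.mean(axis=axes)
        std = stack.std(axis=axes)
        if np.any(std <= self.eps):
            warnings.warn("constant feature channel; epsilon-guarded scale")
        self.std_ = np.maximum(std, self.eps)
        return self

    def _check(self) -> None:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fitted before use")

    def _shaped(self, arr: np.ndarray, ndim: int) -> np.ndarray:
        return arr.reshape((-1,) + (1,) * (ndim - 1))

    def transform(self, stack: np.ndarray) -> np.ndarray:
        self._check()
        return (stack - self._shaped(self.mean_, stack.ndim)) / self._shaped(
            self.std_, stack.ndim
        )

    def inverse_transform(self, stack: np.ndarray) -> np.ndarray:
        self._check()
        return stack * self._shaped(self.std_, stack.ndim) + self._shaped(
            self.mean_, stack.ndim
        )

    def fit_transform(self, stack: np.ndarray) -> np.ndarray:
        return self.fit(stack).transform(stack)

    def state(self) -> dict:
        self._check()
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_state(cls, state: dict) -> "Standardizer":
        obj = cls()
        obj.mean_ = np.asarray(state["mean"], dtype=float)
        obj.std_ = np.asarray(state["std"], dtype=float)
        return obj
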