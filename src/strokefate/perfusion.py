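"""Deconvolution of concentration-time curves and perfusion parameter maps.

Tissue curves relate to the arterial input function (AIF) through
``C(t) = (AIF * k)(t)`` with the flow-scaled residue ``k(t) = CBF * R(t)``.
The inverse problem is solved with block-circulant singular value
decomposition (bcSVD): the AIF convolution matrix is zero-padded to a
circulant matrix (making the deconvolution insensitive to bolus delay) and
regularized by truncating singular values below a fraction of the largest
one (default 15%).

Parameter conventions, in relative units:
  CBF  = max_t k(t)
  Tmax = dt * argmax_t k(t)
  CBV  = integral(CTC) / integral(AIF)
  MTT  = CBV / CBF   (central volume theorem; 0 and flagged where CBF ~ 0)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preproc import PerfusionSeries

__all__ = [
    "DeconvConfig",
    "ParameterMaps",
    "truncate_singular_values",
    "bcsvd_operator",
    "bcsvd_deconvolve",
    "parameter_maps",
    "pick_aif_voxel",
]


@dataclass(frozen=True)
class DeconvConfig:
    truncation_fraction: float = 0.15
    pad_factor: int = 2
    clip_negative: bool = False  # clip negative residue samples before CBF

    def __post_init__(self) -> None:
        if not 0 <= self.truncation_fraction < 1:
            raise ValueError("truncation_fraction must be in [0, 1)")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")


@dataclass
class ParameterMaps:
    """Co-registered CBF/CBV/MTT/Tmax grids (relative flow/volume units, s)."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    tmax: np.ndarray
    low_flow: np.ndarray | None = None  # voxels where MTT was undefined

    def stack(self) -> np.ndarray:
        """(4, X, Y, Z) feature array ordered CBF, CBV, MTT, Tmax."""
        return np.stack([self.cbf, self.cbv, self.mtt, self.tmax])


def truncate_singular_values(s: np.ndarray, fraction: float) -> np.ndarray:
    """Zero all singular values below ``fraction * max(s)``."""
    s = np.asarray(s, dtype=float)
    return np.where(s >= fraction * s.max(), s, 0.0)


def bcsvd_operator(aif: np.ndarray, dt: float, cfg: DeconvConfig) -> np.ndarray:
    """Truncated pseudo-inverse of the padded circulant AIF operator.

    The forward operator is ``D[i, j] = dt * aif_padded[(i - j) mod L]`` with
    ``L = pad_factor * T``; its regularized inverse is shared by every voxel.
    """
    aif = np.asarray(aif, dtype=float)
    if not np.any(aif):
        raise ValueError("AIF is identically zero")
    T = aif.size
    L = cfg.pad_factor * T
    padded = np.zeros(L)
    padded[:T] = aif
    idx = (np.arange(L)[:, None] - np.arange(L)[None, :]) % L
    D = dt * padded[idx]
    U, s, Vt = np.linalg.svd(D)
    s_trunc = truncate_singular_values(s, cfg.truncation_fraction)
    s_inv = np.divide(1.0, s_trunc, out=np.zeros_like(s_trunc), where=s_trunc > 0)
    return (Vt.T * s_inv) @ U.T


def bcsvd_deconvolve(
    ctc: PerfusionSeries, aif: np.ndarray, cfg: DeconvConfig | None = None
) -> PerfusionSeries:
    """Deconvolve every voxel's concentration curve with the AIF.

    Returns the flow-scaled residue series ``k`` (domain ``residual``) of the
    same length as the input; circulant padding is discarded.
    """
    cfg = cfg or DeconvConfig()
    if ctc.domain != "concentration":
        raise ValueError("bcsvd_deconvolve expects a concentration-domain series")
    aif = np.asarray(aif, dtype=float)
    if aif.size != ctc.n_timepoints:
        raise ValueError("AIF length must match the series' timepoints")
    Dinv = bcsvd_operator(aif, ctc.dt, cfg)
    T = ctc.n_timepoints
    L = Dinv.shape[0]
    flat = ctc.values.reshape(-1, T)
    padded = np.zeros((flat.shape[0], L))
    padded[:, :T] = flat
    k = padded @ Dinv.T
    values = k[:, :T].reshape(ctc.values.shape)
    return replace(ctc, values=values, domain="residual")


def parameter_maps(
    residual: PerfusionSeries,
    ctc: PerfusionSeries,
    aif: np.ndarray,
    brain: np.ndarray | None = None,
    low_flow_tol: float = 1e-6,
    clip_negative: bool = False,
) -> ParameterMaps:
    """Perfusion parameter maps from residue and concentration curves."""
    if residual.domain != "residual":
        raise ValueError("residual series expected (run bcsvd_deconvolve first)")
    aif = np.asarray(aif, dtype=float)
    aif_integral = np.trapezoid(aif, dx=residual.dt)
    if aif_integral <= 0:
        raise ValueError("AIF integral must be positive")
    k = residual.values
    if clip_negative:
        k = np.clip(k, 0.0, None)
    cbf = k.max(axis=-1)
    tmax = residual.dt * k.argmax(axis=-1).astype(float)
    cbv = np.trapezoid(ctc.values, dx=ctc.dt, axis=-1) / aif_integral
    low = cbf <= low_flow_tol
    mtt = np.zeros_like(cbf)
    np.divide(cbv, cbf, out=mtt, where=~low)
    if brain is not None:
        outside = ~brain
        for arr in (cbf, cbv, mtt, tmax):
            arr[outside] = 0.0
    return ParameterMaps(cbf=cbf, cbv=cbv, mtt=mtt, tmax=tmax, low_flow=low)


def pick_aif_voxel(
    ctc: PerfusionSeries, brain: np.ndarray
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Convenience AIF: the in-mask voxel with the largest peak concentration.

    A deliberately simple heuristic for data without a known AIF; synthetic
    patients carry their generating AIF and should use it directly.
    """
    peaks = np.where(brain, ctc.values.max(axis=-1), -np.inf)
    idx = np.unravel_index(int(np.argmax(peaks)), peaks.shape)
    return ctc.values[idx], idx
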