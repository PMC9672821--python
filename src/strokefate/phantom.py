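"""Synthetic 4D CT-perfusion phantom with known hemodynamic ground truth.

A digital head phantom stands in for clinical CTP studies: concentric
ellipsoids give a skull shell (~1000 HU), brain parenchyma (~35 HU) and
ventricular CSF (~5 HU); each brain voxel carries a contrast
concentration-time curve obtained by convolving a gamma-variate arterial
input function (AIF) with a delayed-exponential vascular residue function

    C(t) = dt * (AIF  *  CBF * R)(t),      R(t) = exp(-(t - delta)/MTT) * 1[t >= delta]

so that the per-voxel ground truth is exactly (CBF, CBV = CBF*MTT, MTT,
Tmax = delta).  One hemisphere contains a hypoperfused ellipsoidal lesion
with a smooth core-to-rim gradient: CBF drops and the bolus delay and MTT
grow toward the core.  A follow-up infarct mask is drawn per voxel from a
logistic model that is increasing in Tmax and decreasing in CBF, giving the
downstream classifiers a learnable but (configurably) noisy target.

Cohorts mirror a two-arm treatment study: by default 145 patients, 102 in
the thrombectomy arm (IA) and 43 in the thrombolysis arm (IV), with
arm-specific lesion-volume distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "AIFModel",
    "PhantomConfig",
    "PhantomTruth",
    "CohortSpec",
    "gen_aif",
    "gen_tissue_curves",
    "gen_patient",
    "gen_cohort",
]


# --------------------------------------------------------------------------
# arterial input function
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AIFModel:
    """Gamma-variate arterial input function.

    ``aif(t) = amplitude * ((t-t0)/(a*b))**a * exp(a - (t-t0)/b)`` for
    ``t > t0`` and 0 before bolus arrival.  The curve peaks at
    ``t0 + a*b`` with value ``amplitude``.

    Parameters
    ----------
    t0 : bolus arrival delay (s)
    a : gamma shape (dimensionless), > 0
    b : gamma scale (s), > 0
    amplitude : peak height (HU)
    """

    t0: float = 8.0
    a: float = 1.5
    b: float = 0.8
    amplitude: float = 6.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.t0 < 0:
            raise ValueError("AIFModel requires a > 0, b > 0, t0 >= 0")

    @property
    def peak_time(self) -> float:
        """Analytic mode: t0 + a*b."""
        return self.t0 + self.a * self.b

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = t - self.t0
        out = np.zeros_like(tau)
        pos = tau > 0
        x = tau[pos] / (self.a * self.b)
        out[pos] = self.amplitude * np.exp(
            self.a * (np.log(x) + 1.0) - tau[pos] / self.b
        )
        return out


def gen_aif(model: AIFModel, timepoints: np.ndarray) -> np.ndarray:
    """Sample the AIF on a strictly increasing uniform time grid."""
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1D with at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time grid must be strictly increasing and uniform")
    return model(t)


# --------------------------------------------------------------------------
# phantom geometry and hemodynamics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, acquisition and lesion-model parameters of one phantom head.

    Defaults are desk-scale but clinically shaped: a 64x64x8 grid at
    3x3x5 mm sampled every 1.8 s for 48 frames.
    """

    shape: tuple[int, int, int] = (64, 64, 8)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    dt: float = 1.8
    n_timepoints: int = 48
    # tissue HU
    hu_air: float = 0.0
    hu_brain: float = 35.0
    hu_csf: float = 5.0
    hu_skull: float = 1000.0
    noise_sigma: float = 2.0          # additive Gaussian HU noise
    # normal hemodynamics (relative flow/volume units, seconds)
    cbf_normal: float = 1.0
    mtt_normal: float = 4.0
    delay_normal: float = 1.8   # one frame interval: residue peak on-grid
    # lesion severity at the core
    lesion_cbf_factor: float = 0.15   # core CBF as a fraction of normal
    lesion_delay: float = 9.0         # extra bolus delay at the core (s)
    lesion_mtt_factor: float = 2.5    # core MTT as a multiple of normal
    # infarct-outcome logistic link p = sigmoid(bt*(Tmax-tc) + bf*(fc-CBF))
    tmax_center: float = 6.0
    cbf_center: float = 0.45
    tmax_slope: float = 1.5           # 1/s; math.inf => deterministic Tmax rule
    cbf_slope: float = 4.0            # per relative-flow unit
    lesion_scale: float = 1.0         # isotropic multiplier on lesion radii
    aif: AIFModel = field(default_factory=AIFModel)

    @property
    def timepoints(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt


@dataclass
class PhantomTruth:
    """Per-voxel hemodynamic ground truth for one synthetic patient."""

    cbf_map: np.ndarray
    cbv_map: np.ndarray
    mtt_map: np.ndarray
    tmax_map: np.ndarray
    lesion_mask: np.ndarray        # hypoperfused (perfusion-lesion) region
    brain_mask: np.ndarray
    base_hu: np.ndarray
    aif: AIFModel
    noise_sigma: float
    voxel_spacing: tuple[float, float, float]
    dt: float

    def validate(self) -> None:
        flowing = self.cbf_map > 0
        if not np.allclose(
            self.mtt_map[flowing] * self.cbf_map[flowing], self.cbv_map[flowing]
        ):
            raise ValueError("central volume violated: mtt*cbf != cbv")
        if np.any(self.tmax_map < 0):
            raise ValueError("tmax_map must be nonnegative")
        if np.any(self.lesion_mask & ~self.brain_mask):
            raise ValueError("lesion_mask must lie inside the brain")


def _ellipsoid(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _head_geometry(cfg: PhantomConfig):
    """Skull shell, subarachnoid CSF gap, brain, and ventricles as
    concentric ellipsoids (the gap keeps blurred skull HU out of the brain,
    as the subarachnoid space does in real heads)."""
    nx, ny, nz = cfg.shape
    sx, sy, sz = cfg.voxel_spacing
    center = ((nx - 1) / 2 * sx, (ny - 1) / 2 * sy, (nz - 1) / 2 * sz)
    extent = (nx * sx, ny * sy, nz * sz)
    outer = (0.46 * extent[0], 0.47 * extent[1], extent[2] * 4)
    skull_in = (outer[0] - 2.2 * sx, outer[1] - 2.2 * sy, outer[2])
    brain_r = (skull_in[0] - 1.6 * sx, skull_in[1] - 1.6 * sy, outer[2])
    skull_out_m = _ellipsoid(cfg.shape, cfg.voxel_spacing, center, outer)
    skull_in_m = _ellipsoid(cfg.shape, cfg.voxel_spacing, center, skull_in)
    brain = _ellipsoid(cfg.shape, cfg.voxel_spacing, center, brain_r)
    skull = skull_out_m & ~skull_in_m
    csf_gap = skull_in_m & ~brain
    vent_r = (0.10 * extent[0], 0.16 * extent[1], extent[2])
    vent = np.zeros(cfg.shape, dtype=bool)
    for dx in (-0.11, 0.11):
        c = (center[0] + dx * extent[0], center[1], center[2])
        vent |= _ellipsoid(cfg.shape, cfg.voxel_spacing, c, vent_r)
    vent &= brain
    return skull, csf_gap, brain, vent


def _make_truth(cfg: PhantomConfig, rng: np.random.Generator) -> PhantomTruth:
    skull, csf_gap, brain, vent = _head_geometry(cfg)
    nx, ny, nz = cfg.shape
    sx, sy, sz = cfg.voxel_spacing

    base_hu = np.full(cfg.shape, cfg.hu_air)
    base_hu[csf_gap] = cfg.hu_csf
    base_hu[brain] = cfg.hu_brain
    base_hu[vent] = cfg.hu_csf
    base_hu[skull] = cfg.hu_skull

    parenchyma = brain & ~vent
    cbf = np.zeros(cfg.shape)
    mtt = np.zeros(cfg.shape)
    delay = np.zeros(cfg.shape)
    cbf[parenchyma] = cfg.cbf_normal
    mtt[parenchyma] = cfg.mtt_normal
    delay[parenchyma] = cfg.delay_normal

    # ellipsoidal lesion in one hemisphere with a smooth core->rim gradient
    side = -1.0 if rng.random() < 0.5 else 1.0
    center = np.array([(nx - 1) / 2 * sx, (ny - 1) / 2 * sy, (nz - 1) / 2 * sz])
    center[0] += side * 0.20 * nx * sx
    center[1] += rng.uniform(-0.10, 0.10) * ny * sy
    radii = cfg.lesion_scale * np.array(
        [
            rng.uniform(0.13, 0.19) * nx * sx,
            rng.uniform(0.17, 0.25) * ny * sy,
            rng.uniform(0.45, 0.75) * nz * sz,
        ]
    )
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(cfg.shape, cfg.voxel_spacing)),
        indexing="ij",
    )
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    rho = np.sqrt(rho2)                    # 0 at core, 1 at lesion boundary
    lesion = (rho <= 1.0) & parenchyma
    # plateau-like severity: near-maximal deficit over the core, falling
    # smoothly to zero at the rim (1 - rho^2)
    severity = np.clip(1.0 - rho2, 0.0, 1.0)
    s = severity[lesion]
    cbf[lesion] = cfg.cbf_normal * (1.0 - (1.0 - cfg.lesion_cbf_factor) * s)
    delay[lesion] = cfg.delay_normal + cfg.lesion_delay * s
    mtt[lesion] = cfg.mtt_normal * (1.0 + (cfg.lesion_mtt_factor - 1.0) * s)

    truth = PhantomTruth(
        cbf_map=cbf,
        cbv_map=cbf * mtt,
        mtt_map=mtt,
        tmax_map=delay,
        lesion_mask=lesion,
        brain_mask=brain,
        base_hu=base_hu,
        aif=cfg.aif,
        noise_sigma=cfg.noise_sigma,
        voxel_spacing=cfg.voxel_spacing,
        dt=cfg.dt,
    )
    truth.validate()
    return truth


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def gen_tissue_curves(truth: PhantomTruth, timepoints: np.ndarray) -> np.ndarray:
    """Contrast concentration-time curves for every voxel (X,Y,Z,T).

    Discrete forward model ``C[n] = dt * sum_m aif[m] * k[n-m]`` with the
    scaled residue ``k(t) = CBF * exp(-(t-delta)/MTT)`` for ``t >= delta``.
    Zero-flow voxels yield identically zero curves.
    """
    t = np.asarray(timepoints, dtype=float)
    dt = truth.dt
    T = t.size
    flowing = truth.cbf_map > 0
    if np.any(truth.mtt_map[flowing] <= 0):
        raise ValueError("MTT must be positive wherever CBF > 0")
    aif = gen_aif(truth.aif, t)

    cbf = truth.cbf_map[flowing]
    mtt = truth.mtt_map[flowing]
    delay = truth.tmax_map[flowing]
    # residue curves, (Nvox, T)
    tau = t[None, :] - delay[:, None]
    k = np.where(tau >= 0, np.exp(-np.maximum(tau, 0.0) / mtt[:, None]), 0.0)
    k *= cbf[:, None]
    # linear convolution along time via FFT, truncated to T samples
    L = 2 * T
    K = np.fft.rfft(k, n=L, axis=1)
    A = np.fft.rfft(aif, n=L)
    conv = np.fft.irfft(K * A[None, :], n=L, axis=1)[:, :T]
    curves = np.zeros((*truth.cbf_map.shape, T))
    curves[flowing] = dt * conv
    return curves


def _infarct_probability(truth: PhantomTruth, cfg: PhantomConfig) -> np.ndarray:
    logit = np.zeros(truth.tmax_map.shape)
    if math.isinf(cfg.tmax_slope):
        p = (truth.tmax_map > cfg.tmax_center).astype(float)
    else:
        logit = cfg.tmax_slope * (truth.tmax_map - cfg.tmax_center)
        logit += cfg.cbf_slope * (cfg.cbf_center - truth.cbf_map)
        p = 1.0 / (1.0 + np.exp(-logit))
    p[~truth.brain_mask] = 0.0
    return p


def gen_patient(
    cfg: PhantomConfig, patient_seed: int
) -> tuple[np.ndarray, PhantomTruth, np.ndarray]:
    """One synthetic patient: (HU series X,Y,Z,T, truth, follow-up infarct mask).

    The HU series is base tissue HU + contrast concentration + i.i.d. Gaussian
    noise.  The follow-up mask is a per-voxel Bernoulli draw from the logistic
    infarct model; with ``tmax_slope = inf`` it degenerates to the
    deterministic rule ``Tmax > tmax_center``.  The same ``patient_seed``
    reproduces bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(patient_seed))
    truth = _make_truth(cfg, rng)
    curves = gen_tissue_curves(truth, cfg.timepoints)
    series = truth.base_hu[..., None] + curves
    if cfg.noise_sigma > 0:
        series = series + rng.normal(0.0, cfg.noise_sigma, series.shape)
    p = _infarct_probability(truth, cfg)
    followup = rng.random(p.shape) < p
    followup &= truth.brain_mask
    return series, truth, followup


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A two-arm cohort: IA (thrombectomy) and IV (thrombolysis) strata.

    Default sizes mirror a 145-patient study split 102 (70%) IA / 43 (30%) IV.
    Per-arm lognormal lesion-volume parameters are in ml; patient lesion sizes
    are realized geometrically by scaling the lesion radii.
    """

    n_total: int = 145
    n_arm_ia: int = 102
    n_arm_iv: int = 43
    seed: int = 0
    # per-arm lognormal lesion-volume parameters, (mean, sd) in ml
    lesion_volume_ia_ml: tuple[float, float] = (55.6, 74.4)
    lesion_volume_iv_ml: tuple[float, float] = (117.5, 134.9)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        if self.n_arm_ia + self.n_arm_iv != self.n_total:
            raise ValueError("n_arm_ia + n_arm_iv must equal n_total")

    @property
    def arms(self) -> list[str]:
        return ["IA"] * self.n_arm_ia + ["IV"] * self.n_arm_iv


def _draw_lesion_scale(spec: CohortSpec, arm: str, seed_i: int) -> float:
    """Radius multiplier realizing an arm-specific lognormal lesion volume."""
    mean, sd = (
        spec.lesion_volume_ia_ml if arm == "IA" else spec.lesion_volume_iv_ml
    )
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    rng = np.random.default_rng(np.random.SeedSequence(seed_i, spawn_key=(1,)))
    target_ml = float(np.exp(rng.normal(mu, math.sqrt(sigma2))))
    cfg = spec.phantom
    nx, ny, nz = cfg.shape
    sx, sy, sz = cfg.voxel_spacing
    ref_ml = (
        4.0 / 3.0 * math.pi
        * (0.16 * nx * sx) * (0.21 * ny * sy) * (0.60 * nz * sz)
        / 1000.0
    )
    brain_ml = 0.55 * nx * sx * ny * sy * nz * sz / 1000.0  # rough brain volume
    target_ml = float(np.clip(target_ml, 0.02 * brain_ml, 0.35 * brain_ml))
    return (target_ml / ref_ml) ** (1.0 / 3.0)


def patient_seed(spec_seed: int, index: int) -> int:
    """Deterministic per-patient seed derived from the cohort seed."""
    ss = np.random.SeedSequence(entropy=spec_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def gen_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Generate a cohort on disk: per-patient NIfTI set + manifest CSV.

    Per patient: 4D HU series, truth parameter maps, brain and lesion masks,
    follow-up infarct mask, AIF samples as CSV, and a JSON truth sidecar.
    Fails explicitly if a manifest already exists in ``out_dir``.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists():
        raise FileExistsError(f"cohort manifest already exists: {manifest_path}")
    out_dir.mkdir(parents=True, exist_ok=True)

    voxvol_ml = float(np.prod(spec.phantom.voxel_spacing)) / 1000.0
    rows = []
    for i, arm in enumerate(spec.arms):
        pid = f"p{i:03d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        seed_i = patient_seed(spec.seed, i)
        cfg_i = replace(
            spec.phantom, lesion_scale=_draw_lesion_scale(spec, arm, seed_i)
        )
        series, truth, followup = gen_patient(cfg_i, seed_i)
        sp = spec.phantom.voxel_spacing
        io.write_volume(pdir / "ctp_4d.nii.gz", series, sp, dt=spec.phantom.dt)
        for name, arr in [
            ("cbf", truth.cbf_map),
            ("cbv", truth.cbv_map),
            ("mtt", truth.mtt_map),
            ("tmax", truth.tmax_map),
        ]:
            io.write_volume(pdir / f"truth_{name}.nii.gz", arr, sp)
        io.write_mask(pdir / "truth_brain.nii.gz", truth.brain_mask, sp)
        io.write_mask(pdir / "truth_lesion.nii.gz", truth.lesion_mask, sp)
        io.write_mask(pdir / "followup_infarct.nii.gz", followup, sp)
        tgrid = spec.phantom.timepoints
        pd.DataFrame({"time_s": tgrid, "aif_hu": gen_aif(truth.aif, tgrid)}).to_csv(
            pdir / "aif.csv", index=False
        )
        lesion_x = np.argwhere(truth.lesion_mask)[:, 0]
        side = "left" if lesion_x.mean() < (spec.phantom.shape[0] - 1) / 2 else "right"
        io.write_json(
            pdir / "truth.json",
            {
                "patient_id": pid,
                "arm": arm,
                "patient_seed": seed_i,
                "aif": asdict(truth.aif),
                "noise_sigma": truth.noise_sigma,
                "dt": truth.dt,
                "voxel_spacing": list(sp),
                "ipsilateral_side": side,
            },
        )
        rows.append(
            {
                "patient_id": pid,
                "arm": arm,
                "patient_seed": seed_i,
                "ipsilateral_side": side,
                "lesion_volume_ml": round(float(followup.sum()) * voxvol_ml, 6),
                "path": pid,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
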