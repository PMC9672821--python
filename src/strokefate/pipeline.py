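"""End-to-end orchestration: phantom cohort -> preprocessing -> perfusion
maps -> model-ready tensors -> per-method cross-validated predictions ->
metrics tables.

Every method is evaluated on the identical fold plan; probability maps are
restored to scan space, masked to the ipsilateral hemisphere, binarized at
the leave-one-out optimal threshold within the treatment arm, and scored
with Dice, ROC-AUC, and signed/absolute volume errors.  Each method is also
re-scored after noise-reduction filtering (in-slice closing + small
component removal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, deepnet, evalharness, io, mlprep, perfusion, phantom, preproc
from .config import ExperimentConfig, config_hash

__all__ = ["PatientData", "prepare_patient", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class PatientData:
    """Everything one patient contributes to training and evaluation."""

    patient_id: str
    arm: str
    voxel_spacing: tuple[float, float, float]
    hemi_mask: np.ndarray            # ipsilateral hemisphere, native grid
    truth_native: np.ndarray         # follow-up infarct ∧ hemisphere
    tmax_native: np.ndarray          # Tmax map masked to hemisphere
    param_stack: np.ndarray          # (4, X, Y, Z) CBF/CBV/MTT/Tmax
    layout: mlprep.SpatialLayout
    map_slices: np.ndarray           # (Z, 4, H, W)
    ctc_slices: np.ndarray           # (Z, H, W, 32)
    rc_slices: np.ndarray            # (Z, H, W, 32)
    truth_slices: np.ndarray         # (Z, H, W)


def _to_slices(prepared: np.ndarray) -> np.ndarray:
    """(H, W, Z[, T]) -> (Z, H, W[, T])."""
    if prepared.ndim == 4:
        return prepared.transpose(2, 0, 1, 3)
    return prepared.transpose(2, 0, 1)


def _from_slices(slices: np.ndarray) -> np.ndarray:
    """(Z, H, W) -> (H, W, Z)."""
    return slices.transpose(1, 2, 0)


def prepare_patient(
    patient_dir: str | Path, cfg: ExperimentConfig
) -> PatientData:
    """Run the full preprocessing/perfusion/tensor chain for one patient."""
    pdir = Path(patient_dir)
    meta = io.read_json(pdir / "truth.json")
    values, spacing, dt = io.read_volume(pdir / "ctp_4d.nii.gz")
    raw = preproc.PerfusionSeries(
        values=values, voxel_spacing=spacing, dt=dt, domain="raw"
    )
    followup = io.read_mask(pdir / "followup_infarct.nii.gz")

    baseline = preproc.baseline_average(raw)
    raw = preproc.motion_correct(raw, baseline)
    brain = preproc.brain_mask(baseline)
    side = meta["ipsilateral_side"]
    masks = preproc.hemisphere_split(brain, ipsilateral=side)

    arrival_raw = mlprep.detect_arrival(raw, brain, cfg.roi)
    conc = preproc.baseline_subtract(raw, baseline)
    conc = preproc.temporal_resample(conc, target_dt=cfg.target_dt)
    arrival = (
        None if arrival_raw is None
        else int(round(arrival_raw * dt / cfg.target_dt))
    )

    # the AIF is measured on the native time grid and passed through the
    # identical resampling/smoothing operator as the tissue curves, so both
    # sides of the deconvolution share one temporal transfer function
    aif_model = phantom.AIFModel(**meta["aif"])
    aif_native = phantom.gen_aif(aif_model, np.arange(values.shape[-1]) * dt)
    aif_series = preproc.PerfusionSeries(
        aif_native.reshape(1, 1, 1, -1), spacing, dt, domain="concentration"
    )
    aif = preproc.temporal_resample(aif_series, target_dt=cfg.target_dt).values[
        0, 0, 0
    ]
    residual = perfusion.bcsvd_deconvolve(conc, aif, cfg.deconv)
    maps = perfusion.parameter_maps(
        residual, conc, aif, brain=brain,
        clip_negative=cfg.deconv.clip_negative,
    )

    center = mlprep.roi_center(conc, arrival, brain, cfg.roi)
    ctc32 = mlprep.temporal_roi(conc, center, cfg.roi)
    rc32 = mlprep.crop_leading(residual, cfg.roi)

    hemi = masks.hemisphere(side)
    stack = maps.stack()
    prepared_maps = []
    layout = None
    for c in range(stack.shape[0]):
        prep, layout = mlprep.spatial_prepare(
            stack[c], masks, side, pad_shape=cfg.pad_shape
        )
        prepared_maps.append(prep)
    map_slices = np.stack([_to_slices(p) for p in prepared_maps], axis=1)
    ctc_prep, _ = mlprep.spatial_prepare(ctc32.values, masks, side, cfg.pad_shape)
    rc_prep, _ = mlprep.spatial_prepare(rc32.values, masks, side, cfg.pad_shape)
    truth_native = followup & hemi
    truth_prep, _ = mlprep.spatial_prepare(
        truth_native.astype(float), masks, side, cfg.pad_shape
    )
    return PatientData(
        patient_id=meta["patient_id"],
        arm=meta["arm"],
        voxel_spacing=spacing,
        hemi_mask=hemi,
        truth_native=truth_native,
        tmax_native=np.where(hemi, maps.tmax, 0.0),
        param_stack=stack,
        layout=layout,
        map_slices=map_slices,
        ctc_slices=_to_slices(ctc_prep),
        rc_slices=_to_slices(rc_prep),
        truth_slices=_to_slices(truth_prep) > 0.5,
    )


# --------------------------------------------------------------------------
# per-method probability maps
# --------------------------------------------------------------------------

def _restore_prob(slices: np.ndarray, patient: PatientData) -> np.ndarray:
    vol = mlprep.spatial_restore(_from_slices(slices), patient.layout)
    return np.where(patient.hemi_mask, vol, 0.0)


def _rdf_features(patient: PatientData) -> np.ndarray:
    return patient.param_stack[:, patient.hemi_mask].T  # (n_voxels, 4)


def _method_seed(base: int, method: str, fold: int) -> int:
    return int(
        np.random.SeedSequence(
            base, spawn_key=(evalharness.hash_arm(method), fold)
        ).generate_state(1)[0] % (2**31 - 1)
    )


def _predict_rdf(
    patients: dict[str, PatientData], plan: evalharness.FoldPlan,
    cfg: ExperimentConfig,
) -> dict[str, np.ndarray]:
    probs: dict[str, np.ndarray] = {}
    for fold in range(plan.n_folds):
        train_ids = plan.train_patients(fold) + plan.val_patients(fold)
        rdf_cfg = baselines.RDFConfig(
            n_trees=cfg.rdf.n_trees, r=cfg.rdf.r,
            seed=_method_seed(cfg.undersampling_seed, "rdf", fold),
        )
        model = baselines.rdf_train(
            [_rdf_features(patients[p]) for p in train_ids],
            [patients[p].truth_native[patients[p].hemi_mask] for p in train_ids],
            rdf_cfg,
        )
        for pid in plan.test_patients(fold):
            pat = patients[pid]
            pred = baselines.rdf_predict(model, _rdf_features(pat))
            vol = np.zeros(pat.hemi_mask.shape)
            vol[pat.hemi_mask] = pred
            probs[pid] = vol
    return probs


def _val_dice(model, vx: np.ndarray, vy: np.ndarray, batch_size: int) -> float:
    """Validation Dice at the best threshold from a coarse sweep."""
    prob = deepnet.predict_volume(model, vx, batch_size)
    truth = vy > 0.5
    return max(
        evalharness.dice(prob > t, truth) for t in np.arange(0.1, 1.0, 0.1)
    )


def _feature_correlations(
    patients: dict[str, PatientData], plan: evalharness.FoldPlan,
    method: str, cfg: ExperimentConfig, fold_models: dict[int, tuple],
) -> np.ndarray:
    """Spearman rho between the learned temporal feature channels and the
    four perfusion parameters, pooled over all test voxels of the arm."""
    feats_pool, params_pool = [], []
    for fold, (model, std) in fold_models.items():
        for pid in plan.test_patients(fold):
            pat = patients[pid]
            x = _apply_standardizer(std, _slices_for(pat, method), method)
            Z, H, W, T = x.shape
            feats = model.temporal_block.forward(
                x.reshape(Z * H * W, 1, T)
            ).reshape(Z, H, W, -1)
            native = np.stack(
                [
                    _restore_prob(feats[..., c], pat)[pat.hemi_mask]
                    for c in range(feats.shape[-1])
                ]
            )
            feats_pool.append(native)
            params_pool.append(pat.param_stack[:, pat.hemi_mask])
    fm = np.concatenate(feats_pool, axis=1)
    pm = np.concatenate(params_pool, axis=1)
    return evalharness.correlate_features(
        fm, pm, np.ones(fm.shape[1], dtype=bool)
    )


def _slices_for(patient: PatientData, method: str) -> np.ndarray:
    if method == "param_unet":
        return patient.map_slices
    if method in ("rc_simple", "rc_causal"):
        return patient.rc_slices
    if method == "ctc_causal":
        return patient.ctc_slices
    raise ValueError(method)


def _fit_standardizer(stacks: list[np.ndarray], method: str) -> mlprep.Standardizer:
    if method == "param_unet":
        data = np.concatenate(stacks, axis=0)       # (sumZ, 4, H, W)
        data = np.moveaxis(data, 1, 0)              # channel-leading
    else:
        data = np.concatenate(stacks, axis=0)[None]  # one spatiotemporal feature
    return mlprep.Standardizer().fit(data)


def _apply_standardizer(
    std: mlprep.Standardizer, slices: np.ndarray, method: str
) -> np.ndarray:
    if method == "param_unet":
        return np.moveaxis(std.transform(np.moveaxis(slices, 1, 0)), 0, 1)
    return std.transform(slices[None])[0]


def _predict_deep(
    patients: dict[str, PatientData], plan: evalharness.FoldPlan,
    method: str, cfg: ExperimentConfig, folds: list[int] | None = None,
) -> tuple[dict[str, np.ndarray], list[dict], dict[int, tuple]]:
    probs: dict[str, np.ndarray] = {}
    fold_info = []
    fold_models: dict[int, tuple] = {}
    for fold in (folds if folds is not None else range(plan.n_folds)):
        train_ids = plan.train_patients(fold)
        val_ids = plan.val_patients(fold)
        std = _fit_standardizer(
            [_slices_for(patients[p], method) for p in train_ids], method
        )
        def stack_of(ids):
            xs = np.concatenate(
                [_apply_standardizer(std, _slices_for(patients[p], method), method)
                 for p in ids], axis=0,
            )
            ys = np.concatenate([patients[p].truth_slices for p in ids], axis=0)
            return xs, ys.astype(float)

        tx, ty = stack_of(train_ids)
        vx, vy = stack_of(val_ids)
        # the soft-Dice landscape has an all-background plateau; rare stalled
        # folds are retrained deterministically with a shifted seed and a
        # doubled learning rate.  Attempts are compared by their validation
        # Dice at the best swept threshold (a direct ranking-quality score;
        # the raw validation loss can mislead when calibration is off) and
        # the best-scoring attempt is kept.
        base_seed = _method_seed(cfg.training_seed, method, fold)
        best_attempt = None
        for attempt in range(3):
            seed = base_seed + 1000 * attempt
            model = deepnet.build_model(
                method, unet_cfg=cfg.unet, block_cfg=cfg.temporal, seed=seed
            )
            tcfg = deepnet.TrainConfig(
                lr=cfg.train.lr * 2.0**attempt,
                beta1=cfg.train.beta1, beta2=cfg.train.beta2,
                eps=cfg.train.eps, l2_factor=cfg.train.l2_factor,
                dice_smooth=cfg.train.dice_smooth,
                batch_size=cfg.train.batch_size,
                max_epochs=cfg.train.max_epochs, patience=cfg.train.patience,
                seed=seed,
            )
            result = deepnet.train(model, tx, ty, vx, vy, tcfg)
            score = _val_dice(model, vx, vy, cfg.train.batch_size)
            if best_attempt is None or score > best_attempt[0]:
                best_attempt = (score, result, model, seed)
            if score >= 0.2:
                break
            logger.warning(
                "%s fold %d: training stalled (val dice %.3f, val loss "
                "%.3f); retrying with shifted seed",
                method, fold, score, result["best_val_loss"],
            )
        _, result, model, seed = best_attempt
        fold_info.append(
            {"method": method, "fold": fold, "best_epoch": result["best_epoch"],
             "n_epochs": len(result["history"]),
             "best_val_loss": result["best_val_loss"], "seed": seed}
        )
        fold_models[fold] = (model, std)
        for pid in plan.test_patients(fold):
            pat = patients[pid]
            x = _apply_standardizer(std, _slices_for(pat, method), method)
            prob = deepnet.predict_volume(model, x, cfg.train.batch_size)
            probs[pid] = _restore_prob(prob, pat)
    return probs, fold_info, fold_models


# --------------------------------------------------------------------------
# experiment driver
# --------------------------------------------------------------------------

def _score_arm(
    method: str, arm: str, ids: list[str],
    patients: dict[str, PatientData], prob_maps: dict[str, np.ndarray],
    grid: baselines.ThresholdGrid, roc_scale: float,
) -> tuple[list[dict], tuple[np.ndarray, np.ndarray] | None]:
    truths = [patients[p].truth_native for p in ids]
    probs = [prob_maps[p] for p in ids]
    masks, thresholds, _ = evalharness.binarize_optimal(probs, truths, grid)
    rows = []
    curves = []
    for pid, pred, thr in zip(ids, masks, thresholds):
        pat = patients[pid]
        truth = pat.truth_native
        hemi = pat.hemi_mask
        prob = prob_maps[pid]
        fpr, tpr, auc = evalharness.roc_curve_auc(
            np.clip(prob[hemi] / roc_scale, 0.0, 1.0), truth[hemi]
        )
        if np.isfinite(auc):
            curves.append((fpr, tpr))
        filtered = baselines.noise_filter(pred)
        vol_err, abs_err = evalharness.volume_errors(
            pred, truth, pat.voxel_spacing
        )
        rows.append(
            {
                "patient_id": pid, "arm": arm, "model": method,
                "threshold": float(thr),
                "dice": evalharness.dice(pred, truth),
                "dice_filtered": evalharness.dice(filtered, truth),
                "roc_auc": auc,
                "volume_error_ml": vol_err,
                "abs_volume_error_ml": abs_err,
            }
        )
    mean_curve = evalharness.average_roc(curves) if curves else None
    return rows, mean_curve


def run_experiment(
    cfg: ExperimentConfig, workdir: str | Path, reuse_cohort: bool = True
) -> dict:
    """Run every configured method under the shared fold plan.

    Writes ``metrics.csv`` (per-patient rows), ``summary.csv`` (per
    arm x method means/SDs), ``roc_curves.csv``, ``fold_plan.json`` and
    ``training_log.csv`` into ``workdir``, each stamped with the config
    hash, and returns the tables in memory.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    cohort_dir = workdir / "cohort"
    manifest_path = cohort_dir / "manifest.csv"
    if manifest_path.exists() and reuse_cohort:
        manifest = pd.read_csv(manifest_path)
    else:
        manifest = phantom.gen_cohort(cfg.cohort, cohort_dir)
    plans = evalharness.assign_folds(manifest, cfg.folds_seed)
    io.write_json(
        workdir / "fold_plan.json",
        {
            "config_hash": chash,
            "arms": {
                arm: {"folds": plan.folds, "validation": plan.validation}
                for arm, plan in plans.items()
            },
        },
    )
    logger.info("preparing %d patients", len(manifest))
    patients = {
        row.patient_id: prepare_patient(cohort_dir / row.path, cfg)
        for row in manifest.itertuples()
    }

    all_rows: list[dict] = []
    roc_rows: list[dict] = []
    train_rows: list[dict] = []
    corr_rows: list[dict] = []
    for arm, plan in sorted(plans.items()):
        ids = sorted(plan.folds)
        for method in cfg.methods:
            logger.info("arm %s: running %s", arm, method)
            if method == "tmax":
                probs = {p: patients[p].tmax_native for p in ids}
                grid = baselines.tmax_threshold_grid()
                roc_scale = float(grid.values.max())
            elif method == "rdf":
                probs = _predict_rdf(patients, plan, cfg)
                grid = baselines.probability_threshold_grid()
                roc_scale = 1.0
            else:
                probs, info, fold_models = _predict_deep(
                    patients, plan, method, cfg
                )
                for rec in info:
                    train_rows.append({"arm": arm, **rec})
                grid = baselines.probability_threshold_grid()
                roc_scale = 1.0
                if cfg.compute_feature_correlations and method != "param_unet":
                    rho = _feature_correlations(
                        patients, plan, method, cfg, fold_models
                    )
                    for f in range(rho.shape[0]):
                        for p, pname in enumerate(("cbf", "cbv", "mtt", "tmax")):
                            corr_rows.append(
                                {"arm": arm, "model": method, "feature": f,
                                 "parameter": pname, "spearman_rho": rho[f, p]}
                            )
            rows, mean_curve = _score_arm(
                method, arm, ids, patients, probs, grid, roc_scale
            )
            all_rows.extend(rows)
            if mean_curve is not None:
                for f, t in zip(*mean_curve):
                    roc_rows.append(
                        {"arm": arm, "model": method, "fpr": f, "tpr": t}
                    )

    metrics = pd.DataFrame(all_rows)
    metrics.insert(0, "config_hash", chash)
    value_cols = [
        "dice", "dice_filtered", "roc_auc", "volume_error_ml",
        "abs_volume_error_ml",
    ]
    summary = (
        metrics.groupby(["arm", "model"], sort=True)[value_cols]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    summary = summary.reset_index()
    summary.insert(0, "config_hash", chash)

    metrics.to_csv(workdir / "metrics.csv", index=False, float_format="%.10g")
    summary.to_csv(workdir / "summary.csv", index=False, float_format="%.10g")
    roc_df = pd.DataFrame(roc_rows)
    roc_df.insert(0, "config_hash", chash)
    roc_df.to_csv(workdir / "roc_curves.csv", index=False, float_format="%.10g")
    train_df = pd.DataFrame(train_rows)
    train_df.insert(0, "config_hash", chash)
    train_df.to_csv(workdir / "training_log.csv", index=False)
    if corr_rows:
        corr_df = pd.DataFrame(corr_rows)
        corr_df.insert(0, "config_hash", chash)
        corr_df.to_csv(
            workdir / "feature_correlations.csv", index=False,
            float_format="%.10g",
        )
    return {"metrics": metrics, "summary": summary, "fold_plans": plans,
            "feature_correlations": pd.DataFrame(corr_rows)}
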