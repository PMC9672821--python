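# strokefate

Voxelwise tissue-outcome prediction for acute ischemic stroke from 4D CT
perfusion (CTP), end to end: baseline correction and temporal resampling of
the raw series, block-circulant SVD deconvolution with an arterial input
function (AIF), CBF/CBV/MTT/Tmax perfusion parameter maps, and five
predictors of the follow-up infarct evaluated under patient-level fivefold
cross-validation. A synthetic head phantom with known per-voxel
hemodynamics makes the whole chain runnable and testable without clinical
data.

It is written for researchers building or benchmarking perfusion-based
outcome models: the perfusion pipeline, the comparison baselines, and the
evaluation harness are importable pieces, and every stage is driven by
explicit seeds so experiments reproduce bit for bit.

## The model

Each voxel's contrast concentration-time curve relates to the AIF through

    C(t) = (AIF ∗ k)(t),    k(t) = CBF · R(t),

with residue function R(t) (tracer fraction remaining at time t). The
inverse problem is solved with block-circulant singular value
decomposition — the padded circulant AIF operator is delay-insensitive —
regularized by truncating singular values below 15% of the largest. From
the recovered k: CBF = max k, Tmax = argmax k, CBV = ∫C/∫AIF, MTT =
CBV/CBF (relative units).

Predicting the follow-up infarct from the admission data is then a
voxelwise classification problem, addressed by:

| method | input | description |
| --- | --- | --- |
| `tmax` | Tmax map | infarct where Tmax > threshold; per-patient leave-one-out optimal threshold over 120 candidates (0.2–24 s) |
| `rdf` | 4 parameter maps | regression forest, 100 trees, half the pooled instances per tree, per-patient stratified undersampling |
| `param_unet` | 4 parameter maps | 2D UNet with zero-padded convolutions and a two-channel softmax head, soft Dice loss |
| `rc_simple` | residue curves | three pairs of unpadded width-3 1D convolutions (32/16/8 filters) collapse 32 timepoints to 8 learned features feeding the same UNet |
| `rc_causal` / `ctc_causal` | residue curves / raw concentration curves | five dilated causal 1D convolutions (8 filters, width 2, dilations 1,2,4,8,16); the last temporal element — receptive field exactly 32 — feeds the UNet |

The networks run on a small NumPy layer library with explicit
backpropagation (finite-difference checked in the tests); training uses
Adam, a weak L2 kernel regularizer, omission of infarct-free slices, and
patience-8 early stopping with best-epoch restoration.

## Worked example

Simulate a small single-arm cohort and evaluate the two fast predictors
under the shared fivefold plan:

```bash
cat > cohort.yaml <<'YAML'
cohort:
  n_total: 8
  n_arm_ia: 8
  n_arm_iv: 0
  seed: 3
  phantom:
    noise_sigma: 1.0
methods: [tmax, rdf]
pad_shape: [32, 64]
folds_seed: 1
undersampling_seed: 2
YAML
strokefate evaluate --config cohort.yaml --workdir run/
```

prints (abridged):

```
config hash: 321a2da60155
arm model  dice_mean  dice_filtered_mean  roc_auc_mean  volume_error_ml_mean
 IA   rdf   0.659005            0.786778      0.979120              3.751875
 IA  tmax   0.174795            0.171176      0.815151             72.146250
```

Read: on this noisy 8-patient phantom arm the voxelwise forest reaches a
mean Dice of 0.66 against the ground-truth infarcts (0.79 after the
in-slice closing + small-component noise filter, which helps a voxelwise
model substantially) with near-perfect voxel ranking (ROC-AUC 0.98) and a
~4 ml mean volume error, while simple Tmax thresholding — whose single
global threshold cannot express the phantom's joint (Tmax, CBF) infarct
rule — overestimates volumes by ~72 ml and reaches Dice 0.17. Per-patient
rows land in `run/metrics.csv`, summaries in `run/summary.csv`, ROC curves
in `run/roc_curves.csv`, all stamped with the config hash.

The deep models run through the same driver (`methods:
[tmax, rdf, param_unet, rc_simple, rc_causal, ctc_causal]`); see
`strokefate.config.scaled_experiment` for the desk-scale preset used by
the acceptance script, where the learned models clearly outrank the Tmax
baseline.

Other CLI stages: `strokefate simulate` (cohort to disk),
`preprocess` (masks + concentration curves), `perfusion` (deconvolution +
maps), `prepare` (model-ready tensors), `train` / `predict` (single-fold
checkpoint workflow).

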