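# ctperf

Comparison of **arrival-time-sensitive (ATS)** and **arrival-time-insensitive
(ATI)** CT-perfusion post-processing for predicting the final infarct volume
(FIV) in acute ischemic stroke — implemented as a fully synthetic, testable
pipeline: a digital perfusion phantom with known ground truth, SVD-based
deconvolution engines, full-range threshold sweeps with voxel-wise ROC /
Dice / Youden evaluation, and cohort-level volume statistics.

## The problem

Dynamic CT perfusion produces a 4D dataset from which perfusion parameters
are derived by deconvolving each tissue time-attenuation curve with an
arterial input function (AIF): the tissue curve is modelled as
`C(t) = CBF · (AIF ⊛ R)(t − δ)` with residue function `R(t) = exp(−t/MTT)`
and bolus-arrival delay `δ`. The central volume principle ties the
parameters together: `MTT = CBV / CBF`.

*Arrival-time-sensitive* processing inverts the causal (lower-triangular
Toeplitz) convolution system by truncated SVD; under a bolus-arrival delay
the regularised causal inverse smears the residue onset, so CBF is
underestimated and MTT overestimated. *Arrival-time-insensitive* processing
inverts a block-circulant system on a zero-padded grid; the circulant
inverse is shift-invariant, leaving CBF unaffected by the delay, which
instead appears as **Tmax** — the time of the residue maximum.

To compare the two families for FIV prediction, each parametric map (CBF,
CBV, MTT, Tmax/TTP, and their contralateral-relative `_rel` variants) is
swept over a full threshold grid (e.g. Tmax 1–16 s in 0.5 s steps — 31
binary maps). Each threshold yields a binary prediction scored voxel-wise
against the reference infarct mask inside the evaluable region (CTP
coverage ∩ valid deconvolution); each threshold contributes one point of a
ROC curve, and "optimal" thresholds maximise the Youden index
(sensitivity + specificity − 1) or Dice's coefficient, per subject or
pooled over subjects. Predicted lesion volumes are correlated with the
reference volume (Pearson's r). Two groups are modelled: group A (no or
failed thrombectomy — the whole hypoperfused territory infarcts, so the
reference is core ∪ penumbra) and group B (successful thrombectomy — the
penumbra is salvaged, reference = core).

Because the patient data behind such comparisons are not shareable, the
first-class data source here is a phantom: gamma-variate AIF, three tissue
compartments with known CBF/MTT/delay, additive Gaussian noise, optional
reduced craniocaudal coverage, and exact ground-truth infarct masks.

## Worked example

```python
from ctperf import (PhantomSpec, DeconvConfig, build_subject, evaluate_aif,
                    compute_map_set, compute_relative_maps, make_eval_mask,
                    TABLE_GRIDS, roc_curve, optimal_threshold)

spec = PhantomSpec(noise_sd=0.0)                      # one noiseless subject
study, truth = build_subject(spec, group="A", seed=1)
aif = evaluate_aif(spec.aif, spec.times)
cfg = DeconvConfig.ati(spatial_smoothing_sigma=0.0)   # no smoothing needed at noise 0
maps = compute_relative_maps(compute_map_set(study, aif, cfg))
em = make_eval_mask(study, maps)
roc = roc_curve(maps["tmax"], TABLE_GRIDS["tmax"], truth.fiv_mask_true, em)
opt = optimal_threshold(maps["tmax"], TABLE_GRIDS["tmax"],
                        truth.fiv_mask_true, em, "dice")
print(f"Tmax AUC {roc.auc:.2f}, Dice-optimal threshold {opt.threshold} s "
      f"(Dice {opt.score:.2f})")
```

prints

```
Tmax AUC 1.00, Dice-optimal threshold 3.5 s (Dice 1.00)
```

— on noiseless data the Tmax map separates the hypoperfused territory
(penumbra delay 3 s, core delay 6 s) perfectly from normal tissue (delay
0), and the most specific threshold on the perfect-score plateau sits one
grid step below the smallest lesion Tmax.

The full cohort experiment is driven by the numbered scripts:

```bash
python analysis/01_simulate_cohort.py   # 25 group-A + 29 group-B subjects
python analysis/02_compute_maps.py      # ATS + ATI maps for every subject
python analysis/03_threshold_sweep.py   # pooled ROC/AUC + optimal thresholds
python analysis/04_volume_stats.py      # volumes, Pearson r, Wilcoxon tests
```

Step 03, for instance, reports (seed 1):

```
best ATI estimators of penumbra (group A):
  cbf       AUC 0.990
  cbf_rel   AUC 0.976
  cbv       AUC 0.879
  per-subject tmax optima (dice): 1.5-5.5, median 3.5
```

and step 04 the volume correlations per group, e.g.
`ati_dice_volume_ml  r = +0.781` for group A. Tables land in `results/`,
NIfTI volumes in `scratch/`.

The same experiment is available behind one command (`ctpstudy run
--config run.yaml`), with subcommands `phantom`, `perfusion`, `align` and
`report` for the individual stages.

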