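# Methods

## Forward model (phantom)

Each synthetic subject is a 4D attenuation volume on a left-right
symmetric grid (default 32 × 32 × 8 voxels of 4 × 4 × 5 mm, 30 timepoints
at dt = 2 s, i.e. a 60 s acquisition). Tissue is partitioned into three
compartments — normal, penumbra, core — where the lesion compartments are
nested ellipsoids confined to one hemisphere so that the mirrored voxel of
any lesion voxel is normal tissue (an intact contralateral reference).

The arterial input is a gamma-variate,
`AIF(t) = A·(t−t0)^α·exp(−(t−t0)/β)` for `t > t0` (defaults A = 10,
t0 = 8 s, α = 3, β = 1.5 s; peak at t0 + αβ = 12.5 s). Every voxel's
curve follows the indicator-dilution model

```
C(t) = (CBF/6000) · [AIF ⊛ R](t − δ),    R(t) = exp(−t/MTT),
```

discretised as a left-rectangle Riemann sum on the dt grid. The factor
6000 converts CBF from ml/100 g/min to ml/g/s. The delay δ is rounded to
the nearest sample (half up) and applied as an exact shift, so the
ground-truth Tmax is well defined on the discrete grid; sub-sample delays
are out of scope. Truth maps satisfy the central volume principle
`CBV = CBF·MTT/60` exactly; CBV is always derived, never stored.

Default compartment parameters (simulator defaults, not measured cohort
values): normal CBF 60 ml/100 g/min, MTT 4 s, δ 0 s; penumbra 25, 7 s,
3 s; core 8, 10 s, 6 s — the ordering that lesion thresholding
presupposes (reduced flow/volume, prolonged times in the lesion).

Noise is additive i.i.d. Gaussian on the attenuation curves. The default
sd (0.24) was calibrated once so that the peak contrast between the
default normal and core curves is five times the noise floor (a 5:1
contrast-to-noise ratio), the simplest model that meaningfully stresses
the deconvolution. Subjects acquired with a reduced craniocaudal field of
view are emulated by cropping the coverage mask to a central slab
(default: half of the cohort gets a half-thickness slab).

Cohorts draw per-subject compartment parameters, lesion scale and
coverage from configurable uniform ranges using seeds spawned from one
global seed (`numpy.random.SeedSequence`), so cohorts are reproducible
and each subject independently perturbed. The group semantics follow the
clinical endpoints: group A (no/failed thrombectomy) has reference
infarct = core ∪ penumbra, group B (successful thrombectomy) = core.

What the phantom does **not** emulate: partial-volume effects, beam
hardening, motion, scanner physics, vessel signal, recirculation, or
sub-voxel lesion boundaries. Passing tests therefore demonstrate the
correctness and contracts of the *post-processing*, not clinical
performance on real data.

## Deconvolution engines

Both engines estimate the scaled residue `k(t) = CBF·R(t)` from the
baseline-subtracted tissue and arterial curves.

* **ATS (arrival-time-sensitive)**: truncated SVD of the lower-triangular
  Toeplitz matrix `A[i,j] = dt·AIF[i−j]`. Singular values below
  `truncation_fraction × s_max` are zeroed. Because the generator uses
  the same left-rectangle discretisation, the un-truncated system would
  invert exactly; all systematic error comes from the truncation, which
  smears a delayed residue onset — reproducing the known behaviour that
  causal-SVD CBF estimates degrade with bolus-arrival delay.
* **ATI (arrival-time-insensitive)**: truncated SVD of the circulant
  convolution matrix on a grid zero-padded to `padding_factor × N`
  (default 2N, preventing wrap-around of delayed residues). The singular
  values of a circulant matrix are the DFT magnitudes of its first
  column, so the truncation is applied in the Fourier domain and the
  solve costs one FFT per voxel. The estimated residue peak time on the
  unpadded axis is Tmax; the peak height is delay-independent.

Truncation defaults are 0.05 (ATS) and 0.02 (ATI). They were chosen so
that noiseless round trips on the default compartment grid recover CBF
within 10% and MTT within 15%, and ATI Tmax equals the true delay
exactly on the sample grid; larger truncation (0.1–0.2, typical for
noisy clinical data) biases noiseless CBF down by 20–30% and breaks
those contracts. Both values are exposed in `DeconvConfig` — the vendor
settings they stand in for are proprietary and unknown.

Per-voxel noise amplification at low truncation is countered the way
clinical packages do: a Gaussian **spatial pre-filter** (default σ = 1
voxel, configurable, 0 disables) applied to each time frame before
deconvolution. On the default-noise cohort this moves the pooled Tmax
AUC from ≈0.6 (noise-dominated argmax) to ≈0.85–0.95.

Derived quantities: `CBF = max_t k(t)` (restricted to the physical,
unpadded time axis) scaled by a single global calibration constant
(default 1; density/hematocrit corrections folded into one factor —
only relative behaviour and thresholds matter downstream);
`CBV = 100·Σtissue/ΣAIF − CBF·dt/120`; `MTT = 60·CBV/CBF` (exact by
construction wherever both are valid). The `− CBF·dt/120` term is a
half-sample trapezoid correction: the left-rectangle sum of the residue
overestimates its area by dt/2 (27% of MTT at MTT = 4 s, dt = 2 s),
which would otherwise push MTT far outside its recovery tolerance. TTP
(ATS map set) is the argmax time of the raw tissue curve; Tmax (ATI set)
the argmax time of the residue. Relative maps divide each voxel by its
exact mirror across the midline sagittal plane; a voxel is invalid in a
relative map where either side is invalid or the denominator is ≤ 1e−9
(this matters for `tmax_rel`, whose contralateral denominator is 0 in
noiseless normal tissue — validity is therefore tracked **per relative
map**, not shared).

Numerical caveat recorded by the tests: the ATS-CBF-vs-delay curve is
monotone non-increasing only up to a ≈0.5% truncation ripple once the
estimate has flattened (observed 0.01 ml/100 g/min upticks at long MTT);
the tests assert monotonicity with that tolerance and the >5% drop at
6 s delay on the canonical normal-tissue curve (the drop shrinks with
MTT — 4.8% at MTT 10 s — because a fixed delay matters less relative to
a longer transit).

## Alignment and the evaluable region

Reference masks are brought onto the CTP grid by nearest-neighbour
resampling between NIfTI affines (the conventional choice for label
images; it preserves binarity). Registration itself is delegated — real
masks must arrive in CTP space; synthetic data share a grid, where
resampling is the identity. All overlap statistics are restricted to the
evaluable region `coverage ∩ valid`; reference voxels outside it are
dropped from every count. An empty evaluable region is a fatal error.

## Threshold evaluation

Grids are generated by integer step index `min + k·inc` with a
half-increment endpoint tolerance, so the endpoint is always included
and the count is exactly `floor((max−min)/inc) + 1` (the Tmax grid
1–16 s / 0.5 s is an exact 31-threshold contract). Default sweep ranges:
Tmax 1–16/0.5 s, MTT 1–20/0.5 s, CBF 1–90/1, CBV 1–10/0.1, CBV_rel
0.05–3.5/0.05, MTT_rel 0.05–3/0.05, CBF_rel 0.05–3/0.05, Tmax_rel
0.05–4/0.05. TTP has no published range and reuses the Tmax bounds
(same units and physiological span). Lesion direction is `above`
(strictly greater) for time parameters and `below` for flow/volume —
the only direction under which the ranges bracket plausible optima.

Sweeps are computed by sorting lesion and background values once and
counting threshold crossings by binary search — identical to per-threshold
binarisation but O((V+T)·log V). Pooled mode sums tp/fp/tn/fn across
subjects before computing rates (one ROC point per threshold); a
per-subject mode provides the optimal-threshold distributions. AUC is the
trapezoid area over points sorted by 1−specificity with (0,0) and (1,1)
appended.

Design choices in scoring: Dice is undefined (NaN, excluded) when both
sets are empty rather than scored 0 or 1. Ties in the criterion maximum
are broken toward the **most specific** prediction — the largest tied
threshold for direction `above`, the smallest for `below`. With Tmax
quantised to the 2-s sample grid, any perfect-separation plateau spans
from one step above the largest background value to the smallest lesion
value, and the most-specific rule selects the threshold hugging the
lesion side — which is what makes a planted 6-s delay cutoff recoverable
to within one 0.5-s grid step. (A smallest-threshold rule would land a
full sample lower; both rules are deterministic, only this one is
consistent with cutoff recovery under quantisation.)

The vendor-default ATS rule is fixed: hypoperfused = {relative MTT >
1.5}, core = hypoperfused ∧ {CBV < 2 ml/100 g}, penumbra = the
difference. Group A is evaluated against the hypoperfused prediction,
group B against the core prediction.

## Cohort statistics

Volumes are voxel counts × voxel volume in ml. Pearson's r (flagged
undefined on zero variance, ≥3 subjects required) correlates predicted
with reference volumes. Group comparisons use two-sided Wilcoxon
rank-sum tests: exact enumeration of the rank-sum distribution (midranks
for ties, p = 2·min(tails) capped at 1) for combined n ≤ 20, the
tie-corrected normal approximation otherwise; all-tied data gives p = 1.
The ATI-vs-ATS comparison of dependent overlapping correlations (both
against the same reference volumes on the same subjects) uses a
Steiger-type z test on Fisher-transformed correlations — the method is
our choice, since no canonical test exists for this design.

## Pipeline, determinism and problem sizes

`run_pipeline` drives phantom → maps → evaluation → sweeps → report from
one validated YAML config, with per-subject failure isolation
(skip-and-log; fatal only if every subject fails) and a manifest carrying
a hash of the scientific configuration, the seed and package versions.
Given a seed, reruns are byte-identical (gzip members are written with a
zeroed mtime). The default experiment uses the 25 + 29 = 54-subject
cohort on the 32 × 32 × 8 grid — about 8 200 voxels × 30 timepoints per
subject — which keeps a full two-algorithm, ten-parameter sweep under a
few seconds per cohort while leaving every contrast of interest
resolvable; the acceptance script's planted-cutoff check uses 10
subjects at zero and three increasing noise levels.

## Known limitations

* Tmax lives on the 2-s sample grid; 0.5-s threshold granularity is only
  approximate and sub-sample interpolation is an open extension.
* CBF is in calibrated units up to one global constant; absolute values
  should not be compared against clinical scanners.
* The phantom's penumbra/core contrast is sharper than clinical reality
  (no partial volume, no dispersion of the AIF), so AUCs on the synthetic
  cohort run higher than published patient values; the pipeline's
  contracts, not those magnitudes, are the tested claims.
* Automated vessel selection, DICOM ingestion and nonrigid registration
  are out of scope; real-mode inputs must be pre-aligned NIfTI.
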