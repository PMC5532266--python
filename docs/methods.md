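# Methods

## Problem and data model

Each patient contributes four co-registered 3-D CT-perfusion parameter maps
(CBF, CBV, MTT, TTD), a binary follow-up infarct mask and a binary mask of
parenchymal voxels in the ischemic hemisphere, all on the same grid (NIfTI-1;
voxel dimensions from the header). Patients belong to one of two groups by
recanalization outcome — successful (TICI 2b-3) or persistent occlusion
(TICI 0-2a) — and models are always fitted per parameter × group. Inputs are
assumed co-registered and slice-interpolated upstream; the package performs
no resampling or registration and reads no DICOM.

The statistical sample space is the pooled set of hemisphere parenchyma
voxels of all patients in a group: one row per voxel, predictor x = the
perfusion value, response y ∈ {0,1} = the follow-up infarct label. Only the
ischemic hemisphere enters, because contralateral voxels would contribute
meaningless true negatives that inflate specificity and AUC. For the timing
parameters (MTT, TTD) voxels with CBV below a reliability floor are excluded
from training *and* prediction — at very low blood volume the contrast bolus
cannot be timed. The floor defaults to 0.5 ml·100 g⁻¹ and is configurable;
the level itself is a package choice, made explicit so it is
test-controllable. Excluded voxels keep their segmented lesion label in the
*observed* volume, which derives from segmentation, not from any predictor's
sample space.

## The two estimators

**Optimal-threshold.** ROC analysis over the pooled sample, with the
infarct-positive direction fixed by physiology (lower is positive for
CBF/CBV, higher for MTT/TTD). Candidate cutoffs are the sorted unique
observed values; classification is strict (a voxel exactly at the cutoff is
negative). The AUC is the trapezoidal area under the ROC polyline closed at
(0,0) and (1,1), which equals the Mann–Whitney rank statistic with ties
counted ½ (asserted to 1e−12 in the tests). The operating cutoff maximizes
J = sensitivity + specificity − 1; ties in J (within 1e−12) resolve to the
cutoff classifying the fewest voxels positive, then the smallest cutoff — a
deterministic, conservative rule. Predicted volume = positive-voxel count ×
voxel volume.

**Threshold-free.** A univariate logistic model π(x) = expit(β₀ + β₁x) is
fitted to the same pooled sample by Newton/IRLS on a standardized predictor,
with step-halving to keep the likelihood monotone. Convergence is declared
when the log-likelihood improves by < 1e−8 or the coefficient change is
< 1e−8 (max 100 iterations); one extra Newton step is then taken so the
score equations hold to machine precision. That polish step matters: the
intercept score equation Σπ̂ = Σy is what makes the group-total predicted
volume equal the group-total observed volume *exactly* on the training
sample space, and the package asserts this identity to 1e−6 ml at ~1.5
million voxels. A ridge of 1e−6 rescues numerically singular Newton steps
only; complete or quasi-complete separation is detected up front (disjoint
or touching class ranges) and raised as an error, never papered over.
Probabilities are never clipped; extreme linear predictors go through an
overflow-safe logistic. Predicted volume = Σπ over eligible voxels × voxel
volume — no threshold anywhere.

Pooling voxels ignores within-patient correlation, deliberately: voxels are
the sample, patients only define resampling units and cross-validation
folds. Robustness of the coefficients and out-of-sample per-patient accuracy
come from leave-one-patient-out cross-validation, which refits on all other
patients and predicts the held-out patient's volume.

## Evaluation

Per-patient records (V_p, V_o) are summarized by RMSE = √(Σ(V_p − V_o)²/N)
(ideal 0 ml). Uncertainty: percentile (2.5 %, 97.5 %) bootstrap over
*patients* — RMSE is a patient-level statistic — with 100 000 resamples by
default. Method comparison: a paired randomization test with statistic
RMSE(a) − RMSE(b); the null swaps, independently per patient, which method's
prediction carries which label (the only exchangeable structure in a paired
design), two-sided with the add-one correction p = (1 + #{|T*| ≥ |T|})/(1 +
n_perm), 100 000 samples by default. Both resamplers are vectorized,
chunked, and deterministic given a seed; tests and the acceptance script use
10 000 samples, a scaled-down setting exposed as an explicit flag/argument.
Group summaries report mean, SD, median and IQR (Q3 − Q1,
linear-interpolation quantiles, fixed for reproducibility).

## Synthetic cohorts

The simulator generates what the analysis assumes, not raw CTP physics: no
time–attenuation curves, deconvolution or anatomy. Per patient:

1. a lesion-severity scalar — the target ischemic fraction of the
   hemisphere — is drawn lognormal per group (median 0.10, σ_log = 0.9
   recanalized; median 0.45, σ_log = 0.5 persistent; capped at 0.95), giving
   right-skewed volume distributions with the persistent group markedly
   larger, as real cohorts show;
2. the ischemic core is the k = severity × hemisphere-size voxels nearest a
   random center in the (fixed left) hemisphere — truncation at grid
   boundaries therefore never erodes the target fraction — blurred with a
   6 mm Gaussian and peak-normalized into a smooth field d ∈ [0,1];
3. maps are baseline + severity-scaled deviation + noise: CBF = 65(1−0.85d),
   CBV = 4.0(1−0.60d), MTT = 4.5 + 9.0d s, TTD = 5.5 + 11.0d s, with voxel
   noise SDs (8, 0.6, 1.0, 1.2) sharing a common component (correlation 0.3)
   so the four maps co-vary as hemodynamics do;
4. each hemisphere voxel's true infarct probability comes from a generating
   logistic link on the (noisy) driver map — CBF by default, with the
   published reference coefficients — and the lesion is drawn voxel-wise
   Bernoulli. The threshold-free model is thus *correctly specified* under
   the defaults, making its calibration and its advantage over binarization
   provable properties of the simulation rather than tuning accidents;
5. a configurable fraction (default 2 %) of hemisphere voxels is forced
   below the CBV floor to exercise the exclusion rule.

Defaults are 93 + 68 patients on 32³ grids with 2×2×5 mm voxels (hemisphere
≈ 328 ml), sized so the full two-group pipeline runs in seconds on one CPU.
Consequences of the scaled-down geometry and of the correct specification:
recanalized-group medians land in the tens of ml with the realistic
right-skew, but the persistent group's absolute volumes sit somewhat below
large real cohorts (the 328 ml hemisphere caps the tail), and per-patient
threshold-free errors are only the Bernoulli sampling noise (≪ real-data
errors, where the model is misspecified and outcomes depend on unmodelled
covariates such as time to recanalization). Passing tests therefore
demonstrate the estimators' algebraic and statistical properties — not
clinical-grade accuracy on real CTP. A misspecification probe exists:
fitting a non-driver parameter (e.g. MTT when CBF generates the lesion)
exercises the methods under a wrong-but-monotone model, and the generating
coefficients, noise, correlation and driver are all configurable.

## Numerical and degenerate-input choices

* Geometry: all of a patient's volumes must agree in shape and voxel
  dimensions (tolerance 1e−4 mm); masks coerce with > 0.5 ⇒ true; voxel
  volume = dx·dy·dz/1000 ml.
* Single-outcome-class samples are errors for ROC and logistic fitting
  (degenerate ROC / unidentifiable likelihood), as are constant predictors.
* ROC candidate cutoffs are unique observed values, not midpoints — with
  strict inequalities the two differ only in label, and the empirical Youden
  search is exact either way.
* Bootstrap and randomization chunk their resample matrices (≤ 2×10⁷
  entries) to bound memory at the default 100 000 samples.
* All randomness flows through explicit integer seeds; fitting itself is
  deterministic.

## Known limitations

Univariate models only (no multi-parameter or time-to-recanalization
covariates, no Tmax); voxel independence (no spatial clustering of
predictions); the simulator's lesions are probabilistically, not
anatomically, shaped; the CBV reliability floor is a stated convention, not
an estimated quantity.
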