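# Methods

## The problem

Mechanical ventilation deforms lung tissue. The regional (voxel-level)
share of that deformation — the strain — is not uniform: in a supine
subject it grows toward the gravitationally dependent (dorsal) lung,
where airless, collapsed tissue (atelectasis) concentrates. Activated
pro-inflammatory macrophages, imaged with a somatostatin-receptor PET
tracer, accumulate in the same regions. This package quantifies both
spatial fields from standard volumetric images and measures their
topographic coupling.

## Models and estimators

### CT aeration (module `aeration`)

A lung voxel's density interpolates linearly between air (−1000 HU,
fully gaseous) and water (0 HU, fully consolidated). Its gas fraction is
therefore −HU/1000, its gas volume

    V_vox,gas = V_vox · (−HU / 1000),

and its nongaseous (tissue + fluid) volume the exact complement
V_vox − V_vox,gas. HU outside [−1000, 0] is clamped to the nearest
boundary before conversion (the count of clamped voxels is logged and
reported); the alternative — propagating negative gas volumes — has no
physical reading. Masks are inputs; segmentation is out of scope.

### Strain field (module `strain`)

With lung strain defined against the resting state as
(V₁ − V_FRC)/V_FRC, and assuming deformation is homogeneous within a
voxel and purely normal to its faces, the per-axis voxel-associated
normal strain between the reference (ZEEP) and inflated states is

    VoStrain_i = (1/3) · (V_i,1 − V_i,FRC) / V_i,FRC

computed from the two CT-derived gas contents. Completely gasless
reference voxels would make the ratio infinite; they receive a gas floor
of 0.01% of the voxel volume (`floor_fraction = 1e-4`, configurable),
which deliberately produces very large — but finite and comparable —
strain values over atelectatic tissue. No recruitment correction is
applied to the denominator. Slice summaries report mean, population SD,
median and IQR.

### SUVR (module `suvr`)

SUVR(x,y,z) = c_voxel / c_ref, with c_ref the arithmetic mean activity
over a blood-pool (left-ventricle) ROI of the same image. A 4-D dynamic
series is reduced to the frame whose mid-time is nearest 3596 s
(≈ 1 h post-injection); static volumes pass through. Decay correction
and kinetic modeling are assumed done upstream or out of scope.

### Iso-gravitational profiles (module `profiles`)

The masked lung extent along the gravity axis is split into 100
equal-thickness layers (layer 1 nondependent); each layer's mean over
masked voxels forms the profile. Layers partition the *lung* extent, not
the image height, so profiles are comparable across subjects with
different lung sizes. Cohort profiles average per-layer across subjects
(SE = between-subject SD/√k). Empty layers (irregular masks) are
flagged, carried as NaN, and excluded from fits.

The gravitational course is summarized by OLS of layer mean on layer
index over the central quartiles, layers 25–75 inclusive (51 points) —
the progressively leaning part of the profiles. Two conditions are
compared by:

* the extra-sum-of-squares **F test** of one common line against two
  separate lines (2 numerator df — slope and intercept jointly;
  denominator df n_A + n_B − 4);
* the **Z test** on angular coefficients,
  Z = (b₁ − b₂)/√(se₁² + se₂²), for slope-only comparisons (used for
  the SUVR-vs-nongaseous regressions, where a zero-intercept slope is
  also reported to ease comparison);
* **Wilcoxon** tests for location: rank-sum (Mann–Whitney) for
  independent groups — with the exact null distribution for tie-free
  samples up to n = 25, matching small animal cohorts — and signed-rank
  for paired data. Independent-group comparisons use the rank-sum form;
  both are exposed.

OLS is computed by closed-form normal equations (slope, intercept, slope
SE, residual R²); a constant profile returns slope 0 and R² 0 by
convention. statsmodels serves as an independent cross-check in the test
suite, not as the implementation, so the Monte-Carlo calibration tests
stay fast.

### Linear mutual information (module `lmi`)

Under a Gaussian model of the paired voxel intensities, mutual
information is I = ½·ln[var(x)·var(y)/det C] nats, normalized to [0, 1]
by the generalized-correlation transform lmi = √(1 − e^(−2I/d)). For
scalar intensities (d = 1, the only case image pairs present) this
equals |Pearson r|, which is the oracle the tests compare against; the
implementation computes r² directly from the covariance for numerical
stability near |r| = 1. Zero-variance inputs raise rather than return a
silent 0. LMI is computed over lung-mask voxels only. Strain spans
orders of magnitude; an optional log1p transform of the strain input is
available (`lmi_log_strain`), with raw values the default.

## Synthetic phantom (module `phantom`)

The generator emulates the statistical structure the analysis assumes,
not anatomy: an ellipsoidal lung with a disjoint spherical blood pool in
the ventral mediastinum, on a (24, 128, 48) grid (apico-basal,
gravitational, lateral) of 3.6 µl voxels — 128 planes along gravity so
100 layers stay populated.

* **Reference aeration**: gas fraction 0.6 at the ventral boundary
  falling linearly by 0.45 per unit normalized depth (0.6 → 0.15),
  typical of supine ZEEP; voxels in the dependent
  `atelectasis_depth_fraction` of the lung are fully degassed.
* **Inflation**: ventilated voxels multiply gas by `inflation_factor`,
  capped at gas fraction 1. Because dependent voxels start from a lower
  gas fraction, the capped relative expansion — hence strain — grows
  with depth, producing the progressively leaning profiles; in the
  uncapped regime strain is uniformly (1/3)(f − 1), which the parameter-
  recovery tests exploit. Atelectatic voxels reopen by default to gas
  fraction 0.3 (recruitment at high inflation pressure), exercising the
  strain floor; reopening can be disabled.
* **Ground truth**: `truth_strain` uses the same 0.01% floor convention
  as the estimator; voxels closed in both states carry zero physical
  strain (the floored estimator would report −1/3 there, which only
  arises with reopening disabled).
* **Macrophage signal**: activation = baseline + κ·s/(s + s₀) with
  saturation s₀ = 1, so floored strains in the hundreds cannot produce
  unbounded activity. Baseline 0.5 and blood-pool activity 1.0 MBq/mL
  put healthy SUVR near 0.5 and injured dependent-lung SUVR near 1.4,
  the plausible range for this tracer.
* **Noise**: additive Gaussian on HU (σ = 15 HU) and additive
  truncated-at-zero Gaussian on PET activity (σ = 0.05 MBq/mL),
  i.i.d. per voxel. Real CT/PET noise is spatially correlated and PET
  noise is closer to Poisson; both are deliberate simplifications, so
  passing tests demonstrate estimator correctness under the assumed
  model, not robustness to scanner physics.

HU is generated by exactly inverting the gas-fraction transform before
noise, so noise-free phantoms round-trip through the aeration analysis
to machine precision. A fixed seed gives bit-identical phantoms.

### Demo study conditions

The demo cohort mirrors a 7-injured vs 3-control design at two
transverse levels (fractional apico-basal positions 0.8
"para-diaphragmatic" and 0.5 "mid-thoracic"):

| parameter | injured (VILI-like) | healthy-like |
|---|---|---|
| atelectasis_depth_fraction | 0.3 | 0.02 |
| inflation_factor | 4.0 | 2.0 |
| coupling_kappa | 0.9 | 0.1 |

Per-subject seeds derive from the study seed via `SeedSequence`, so the
whole report is reproducible byte-for-byte.

## Numerical and design choices

* Slice descriptive SD is the population (n-denominator) SD; IQR uses
  linearly interpolated percentiles.
* Layer binning assigns each voxel by its plane center within the masked
  extent; the voxel-count-weighted mean of layer means equals the
  whole-mask mean exactly.
* The F test compares slope and intercept jointly; slope-only questions
  go through the Z test.
* Covariances use the sample (n−1) denominator; the normalized LMI is
  invariant to this choice.
* c_ref is the ROI mean (not median).
* Nongaseous-content profiles are taken from the reference (ZEEP) CT,
  where the gravitational gradient is monotone.
* `run_study` writes intermediate NIfTI volumes only on request
  (`save_volumes=True`); reports are JSON/CSV and deterministic.

## Problem sizes

Tests and the acceptance script run phantoms at the default
(24, 128, 48) grid (≈ 49 k lung voxels), the strain oracle at 10⁶
voxels, LMI calibration at 10⁵ samples, F-test calibration with 10⁴
Monte-Carlo replicates, and slope recovery over 50 seeds — sizes chosen
to exercise the estimators at full statistical fidelity while keeping a
complete run in minutes on one CPU.

## Known limitations

* Volumes are assumed voxel-wise co-registered; no deformable
  registration is provided (a rigid pre-alignment could be added ahead
  of the aeration stage without touching any estimator).
* Voxel-level LMI and profile regressions ignore spatial autocorrelation
  between voxels; p-values for within-image comparisons are therefore
  optimistic on real data. Group-level tests (rank-sum across subjects)
  do not suffer from this.
* Shear strain is not computable from gas-content changes and is not
  attempted; strains over recruited tissue reflect the floor convention,
  not elastic deformation.
* The phantom's step-like condition contrasts are stylized; effect sizes
  on real data will be smaller than on phantoms.
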