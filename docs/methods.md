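# Methods

## Dose–volume curves and features

The cumulative dose–volume curve of an organ is cV(d) = (number of
masked voxels with dose ≥ d) / (number of masked voxels), evaluated on a
regular dose grid (default resolution 0.1 Gy, far finer than any feature
spacing used) from 0 Gy to one step beyond the maximum voxel dose, so the
curve always starts at 1 and ends at 0. Voxel inclusion is "≥ d"; a
differential bin is half-open [a, b). These two conventions make
dV<sub>a–b</sub>Gy = cV(a) − cV(b) an identity rather than an
approximation, which is what the telescoping tests assert. Feature
values at doses between grid points are linearly interpolated; the
interpolation error is below one resolution step of curve mass.

Differential schedules start at 5 Gy and advance by the bin width while
the lower edge stays below 60 Gy; every bin keeps its full width, so the
final bin may end above 60 Gy (width 6 ends at 59–65 Gy). This
reproduces the clinically named features (dV5-7Gy, dV37-41Gy, dV45-53Gy)
and avoids a ragged terminal bin; the terminal edge is otherwise a free
choice. Volumes are reported in percent (0–100), MLD in Gy. MLD from a
feature table is the voxel mean; the curve integral ∫cV(d)dd equals it
up to curve-resolution error (≤ 0.5% relative at 0.1 Gy in practice, 1%
asserted), which is a useful internal consistency check, not a second
definition.

Fractional volumes are relative to the supplied mask. Whether "lung"
excludes the target volume is the mask supplier's decision; the package
does not adjudicate.

## Synthetic cohorts

No clinical cohort ships with the package, so a generator emulates the
statistical structure the analysis assumes. Each patient's cumulative
curve is

cV(d) = A·(1+e^(−d50/s))/(1+e^((d−d50)/s)) + B/(1+e^((d−dB)/sB)),  d > 0,

pinned to 1 at d = 0. The first term is the familiar sigmoid lung DVH:
A ~ U(0.35, 0.55) is the fraction of lung receiving any appreciable
dose, d50 ~ N(24, 5) Gy the falloff midpoint, s ~ N(6, 1.5) Gy
(truncated above 1 Gy) the falloff width. The second term is a small
high-dose shoulder — the lung volume inside the dose shell around the
target — with B ~ U(0, 0.08), dB ~ U(35, 55) Gy, sB ~ U(1, 3) Gy. The
shoulder matters: with the three-parameter sigmoid alone the feature
table has essentially three degrees of freedom, the seven cumulative
sample points capture everything, and differential bins cannot carry
information beyond them even in principle; real cohorts show exactly
such mid/high-dose structure (elevated dV37–45Gy bins). Curves are
rejection-sampled (budget 1000 tries per patient, exceeding it is an
error, never a silent relaxation) until V5Gy < 65%, V20Gy < 35% and
MLD < 20 Gy — the planning constraints of thoracic protocols — which
puts the accepted cohort means near cV5 ≈ 45%, cV20 ≈ 27%, MLD ≈ 11 Gy.

Labels are Bernoulli with logit p = β₀ + Σ βⱼ zⱼ, where zⱼ are
cohort-level Z-scores (this is a generative definition, not an analysis
step) and β₀ is tuned by bisection until mean p matches the target
prevalence within 10⁻⁴ (0.01 required). The default prevalence is 0.268
and the default coefficients are 0.7 on dV37-41Gy and dV41-45Gy and 0.5
on cV60Gy — mid/high-dose bins and the high-dose cumulative point, a
plausible dose–toxicity pattern at effect sizes that give moderate
discriminability (mean test AUC around 0.8 on default cohorts) rather
than a ceiling. The cohort size default is 153; where source cohorts
report slightly inconsistent counts the size is simply a parameter.

A second generator, `make_recovery_cohort`, builds a stress-test table
whose signal paths are separable by construction: a strongly collinear
cumulative block driven by one latent severity factor (no outcome
signal), three planted differential bins independent of that factor
carrying the whole signal (|β| = 1.5 each), weakly background-linked
remaining bins, and pure-noise columns. It exists because feature
recovery is only decidable when the ground truth says which features are
truly null; in the curve-based cohort every feature is correlated with
every other through the latent curve parameters.

What the synthetic data do not emulate: 3D anatomy (cohort curves are
sampled directly, not computed from synthetic dose grids), fractionation
and clinical covariates, grade structure beyond a binary label, and
inter-feature noise that is not explained by the curve family. Passing
tests therefore demonstrate that the pipeline is correct and calibrated
under its stated assumptions, not that any particular AUC will be
attained on clinical data.

## Penalized model and solver

The model is logistic: the fitted objective is the mean binomial
deviance (2/m)Σ[log(1+e^η) − y·η] plus λ‖w‖₁, with an unpenalized
intercept, on features Z-scored with training statistics. (A printed
squared-error variant of this objective circulates in the applied
literature; the logistic deviance is the coherent choice for a binary
endpoint and is what "LASSO logistic regression" means here.)

The solver is the standard IRLS + coordinate-descent scheme with
covariance updates: each outer step replaces the deviance by its local
weighted least-squares model (weights p(1−p) floored at 10⁻⁵, working
response z = η + (y−p)/v), and the penalized quadratic is minimised by
cyclic soft-thresholding over a precomputed weighted Gram matrix, with
active-set iterations between full sweeps. Convergence is declared when
the largest curvature-weighted squared coefficient change in a sweep
falls below `tol` (default 10⁻⁸; single fits use 10⁻¹²). λ_max =
(2/m)·max|xⱼᵀ(y−ȳ)| follows from the KKT conditions at the
intercept-only model: starting from w = 0 and b = logit(ȳ), any λ ≥
λ_max leaves the model exactly there, which gives the solver two exact
anchors (all-zero coefficients, prevalence intercept) that the tests
assert without tolerance tricks. At λ = 0 the same iteration is
Newton's method and matches an independent unpenalized fit to ~10⁻⁹.
Paths are fitted from λ_max downward with warm starts; once the training
deviance is essentially zero (mean deviance < 0.01) the data are
separated and remaining grid values reuse the current solution — smaller
penalties only rescale a diverging solution and can never win held-out
selection.

The penalty grid is 100 log-spaced values from λ_max down to
λ_max·10⁻³, recomputed per training set so the full-shrinkage anchor is
always on-grid. Ties in mean held-out deviance resolve to the larger λ
(the more regularized model). Held-out loss is the mean binomial
deviance of the linear predictor on the validation fold.

## Cross-validation design

Each experiment runs `n_iterations` × `splits_per_iteration` stratified
shuffle splits (default 6 × 5 = 30) at 30% held out. The split sequence
is derived from the base seed and the labels alone, so experiments on
different feature sets share outer splits exactly — the precondition for
the paired comparison. An alternative "kfold" scheme (six iterations of
disjoint stratified fivefold partitions) is available behind a config
flag; the shuffle default honours both the 30-model count and a 70/30
inner/outer division simultaneously, which a strict fivefold outer
partition cannot. Standardization parameters and λ* are computed from
the inner 70% only; test rows are transformed with training parameters
and never influence selection. Constant training columns are dropped
with a warning. Stratification protects the ~27% minority class
everywhere. Sub-seeds for every randomized stage are derived by hashing
the base seed with a stage tag (SHA-256, truncated to 31 bits), so one
user-facing seed reproduces the entire experiment bit for bit.

AUC uses the Mann–Whitney rank formulation with ties counted ½. The 95%
interval on the mean AUC across the 30 models is normal-theory
(mean ± t₀.₉₇₅,₂₉·se); it describes the spread of the resampled models,
not an independent-replicates CI. "Top coefficient" per model means the
largest absolute standardized coefficient — magnitudes on the Z-scale
are the only comparable quantity, and sign conventions vary; models with
all-zero coefficients are counted in a reserved "none" bucket so counts
always sum to the model count.

The paired comparison is a Wilcoxon signed-rank test on the 30 per-split
test-AUC differences: zero differences dropped, mid-ranks for tied
magnitudes, exact sign-flip null (by subset-sum convolution over doubled
ranks) for ≤ 25 nonzero pairs, normal approximation with tie and
continuity corrections above. Two-sided p = 2·min(P(W ≤ w), P(W ≥ w)),
capped at 1; with no nonzero pair the test is degenerate and p = 1.

Two caveats about this comparison are worth knowing. First, the 30
paired differences come from overlapping resamples of one cohort, so
they are positively correlated and the test can be mildly
anti-conservative — an inherent property of comparing resampled model
sets, shared by the design this package implements. Second, feature
sets of very different dimensionality are not exchangeable under a
permutation null: within one dataset the spurious train-set association
a model chases is negatively related to the association left for the
held-out split (the label vector is fixed, so split sums are
constrained), richer feature sets chase more of it, and their held-out
AUC sits systematically a little below that of smaller sets. The effect
is about 0.01–0.02 AUC at 200 patients for 8 vs 22 features, real
enough for the signed-rank test to flag. Calibration statements about
the comparison therefore use equal-complexity null sets; comparisons of
differently sized sets on real (unpermuted) outcomes remain valid as
comparisons, but their null reference is not exactly uniform.

## Multicollinearity audit

Spearman's ρ with mid-ranks for ties (no p-values — the matrix is
descriptive); constant columns are an error naming the column. Group
summaries report the mean absolute off-diagonal ρ within a feature
family. Heat-map rendering orders features by ascending dose, cumulative
before differential, and is presentation-only.

## Pipeline and numerical conventions

`run_all` executes cohort → correlations → five experiments (baseline +
widths 2/4/6/8) → reports, in a fixed output layout with a manifest of
config, seed, version and SHA-256 checksums; reruns with the same config
are byte-identical. Input CSVs are validated (canonical names, volumes
in [0, 100], MLD ≥ 0, binary labels, missingness) with per-row/column
issue reports. The optional DICOM adapter reads RT-DOSE grids
(DoseGridScaling applied, spacing from PixelSpacing and the frame offset
vector) and rasterizes RT-STRUCT contours by even–odd polygon fill per
axial slice; it is isolated so the core never imports pydicom.

Default problem sizes used by the test-suite calibration checks: 200
patients × 30 replicates for null calibration (label permutation), 300
patients × 20 seeds for recovery, 153 for structural checks — sizes at
which the binomial noise on a prevalence of 0.268 and the variance of a
30-model AUC mean are small relative to the asserted margins.

## Known limitations

* The curve family is smooth and unimodal-plus-shoulder; cohorts with
  multimodal dose structure (multiple targets) are outside its range.
* The binary label ignores toxicity grade and time-to-event structure.
* The CI over cross-validated models and the paired Wilcoxon both treat
  the 30 resampled models as exchangeable draws; their dependence makes
  nominal levels approximate (see above).
* The DICOM adapter assumes uniform slice spacing and axial planar
  contours.
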