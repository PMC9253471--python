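# Methods

This note documents the models and procedures `disco` implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish.

## The disconnectome model

A subject's white-matter lesion is assumed to disconnect every fiber
trajectory passing through it. Because patient diffusion imaging is not
required, disconnection is inferred from a *normative* streamline set: N
control tractograms (default N = 10) registered to a common template
grid. For one lesion mask L and control c, the selected set is every
streamline of c whose voxelised path intersects L — the "seeded by the
lesion" criterion implemented as whole-brain filtering, which avoids a
tractography engine while applying the same membership test. The
selected streamlines are rasterised into a visitation count map
(streamlines per voxel, each streamline counted once per voxel) and
binarised. The disconnectome map is the voxelwise mean of the N binary
maps:

    prob(v) = (1/N) * #{controls with a lesion-crossing streamline through v}

so values lie on {0, 1/N, …, 1} and read as the fraction of the
normative population whose anatomy implies disconnection at v ("percentage
overlap"). Note the binarisation happens per control *before* averaging;
this is the only normalisation under which the cross-control average is a
probability.

Maps are thresholded at a cutoff of 0.5 before scoring, retaining voxels
where **more than** half the controls agree. The usual verbal
description of this rule is ambiguous between strict (">50 %") and
non-strict ("at least half") at exactly 0.5 — material for even N — so
both are supported (`strict=` flag) with strict as the default.

**White-matter mask.** The analysis mask is the union of nonzero support
across the cohort's own unthresholded maps, not an anatomical atlas: a
voxel belongs to the analysable white matter if any subject's lesion
could disconnect it.

**Global disconnectome (GD).** GD is the mean of the thresholded map
over the white-matter mask. Sub-threshold voxels contribute zeros to the
numerator but remain in the denominator, so GD mixes the *proportion* of
white matter affected with the *severity* (overlap fraction) at affected
voxels. GD is a dimensionless scalar in [0, 1] per subject and visit.

**Geometry.** Streamlines are polylines in world mm. Voxelisation
resamples each polyline so consecutive samples are at most a quarter of
the smallest voxel edge apart (each original vertex is kept, so the
resampled path lies exactly on the input), then assigns samples to the
voxel with the nearest center (rounding half away from zero — tie-stable
under sign changes). A step of at most half a voxel is enforced;
quarter-voxel sampling means a voxel can only be missed when the path
grazes it with a chord shorter than the step, which the tests bound
explicitly. Samples outside the grid are dropped and logged.

## Voxel-wise inference

The per-voxel GLM regresses the stack of baseline disconnectome maps on
z-scored serum NfL with z-scored age and disease duration, sex, and
joint diagnosis-by-treatment indicator columns (each observed
combination is one dummy column; the first observed combination is the
reference; combinations absent from the sample produce no column). NfL
outliers (> mean + 3 SD, one pass, one-sided) are removed before the
design is built. Rank deficiency raises an error naming the aliased
columns.

Both one-sided contrasts on the NfL column (+ and −) are tested. The
statistic map is enhanced with TFCE,

    TFCE(v) = Σ_{h = dh, 2dh, … ≤ t(v)}  e(h, v)^E · h^H · dh ,

with e(h, v) the size of the connected component containing v at
threshold h. Defaults H = 2, E = 0.5, dh = 0.1, 26-connectivity — the
standard 3-D parameterisation; all four are configurable. Negative
values are enhanced on the negated map separately, so each contrast gets
its own enhancement.

Family-wise error is controlled by the permutation max-statistic method
under the Freedman–Lane scheme: residuals of the nuisance-only
(reduced) model are row-permuted, added back to the reduced-model fit,
the full-model t-map is recomputed and enhanced, and the maximum
enhanced value inside the mask per permutation forms the null. P-values
use the (1 + exceedances)/(1 + n_perm) estimator, so they are positive
and valid at any permutation count; when n! ≤ n_perm the exact
exhaustive null is enumerated instead (and the +1 correction is dropped,
since the identity relabelling is included). Each contrast is reported
at the 0.05 FWER level; a Bonferroni factor of 2 across the two
contrasts can be applied by halving `alpha`.

## Longitudinal mixed models

The per-visit response (GD or T2 lesion volume) is modelled as

    y_it = β0 + β1·zNfL_it + β2·t + β3·zNfL_it·t + covariates
           + u_i (+ v_c) + ε_it

with timepoint t coded 0/1 (so β3 is the change of the NfL slope at
follow-up), a subject random intercept u_i always present, and center
entering as fixed dummy terms by default or as a second random intercept
(subjects nested within centers) on request. Continuous covariates are
z-scored across the analysed rows (n − 1 denominator). The response is
*not* re-standardised by default: the package's recovery loop plants
coefficients on the response's own scale, and per-fit rescaling would
change what the coefficient estimates. A caller who wants standardized
betas in the reporting sense can z-score the response column first.

Fitting is REML (statsmodels MixedLM) with an optimizer fallback chain;
inference is Wald with normal-approximation intervals (no finite-sample
df — two visits per subject give no reliable Satterthwaite correction
and the robust variant has no classical df in any case). Non-convergence
and boundary (zero) variance estimates are *flagged* on the returned
fit, never raised: a zero subject variance is a legitimate estimate on
degenerate data.

**Robust variant.** Extreme observations are handled by an iteratively
reweighted fit: residuals (including the predicted random intercepts)
are standardised by a MAD scale estimate, Huber weights
w = min(1, c/|r|) are formed, response, fixed-effect design and
random-intercept design rows are scaled by √w, and the model is refit
until the fixed effects move less than 1e-4 (absolute — well below any
standard error in this problem class; the weights jitter at smaller
amplitude, so a tighter tolerance would never be reached). This is a
pragmatic M-estimation scheme, not a replication of any specific robust
LMM estimator; its fidelity argument is behavioural: on clean data it
tracks the REML fit, under gross contamination it tracks the truth
better. The default Huber constant is c = 2.5: at that value ~1 % of
clean-normal residuals are downweighted, so the clean-data agreement
with REML stays within a few per cent per coefficient, while gross
outliers (tens of residual SDs) are still driven to near-zero weight.
The textbook c = 1.345 downweights ~18 % of clean observations and makes
the reweighted estimate wander ~0.3 SE from the REML fit — poor behaviour
when the estimator is meant to *agree* with REML absent contamination.
c → ∞ reproduces the conventional fit exactly.

## Cohort-level statistics

- **z-scoring**: mean 0, sample SD 1 (n − 1).
- **EDSS change**: worsening = increase ≥ 1.0 from baseline 0.0–5.0 or
  ≥ 0.5 from baseline ≥ 5.5; improving = decrease ≥ 1.0 from 0.0–5.0 or
  ≥ 0.5 from above 5.0; stable = baseline ≤ 5.0 with |Δ| ≤ 0.5. The
  rules leave grid cells uncovered (e.g. an unchanged 6.0); those return
  `unclassified` rather than being silently binned, because any binning
  would be an invention. The classifier is tested exhaustively over all
  21 × 21 half-point pairs.
- **NfL outliers**: values above mean + 3 SD of the full vector, one
  pass, one-sided. Deliberately *not* iterated: re-screening the kept
  values can flag more (the tests assert this non-property).
- **GD–T2LV association**: Pearson r plus a least-squares quadratic fit
  of GD on T2LV (GD saturates as lesion volume grows, so the relation
  is concave).
- **Cross-sectional models**: baseline OLS of GD or T2LV on z-scored
  NfL, disease duration and age, with sex, phenotype, treatment and
  center dummy-coded (references: male, CIS, no treatment, Barcelona).
  Two-sided t-tests per coefficient, no across-term multiplicity
  correction.

## The synthetic cohort generator

The generator emulates a two-visit, four-center MS cohort. Its defaults
are the study conditions the downstream checks run under:

| parameter | default | meaning |
|---|---|---|
| β_NfL | +0.03 | planted NfL→GD effect (per SD of NfL) |
| β_time | −0.04 | follow-up shift of GD |
| β_NfL×time | −0.01 | attenuation of the NfL slope at follow-up |
| β_age, β_duration | +0.18, +0.14 | covariate effects (per SD) |
| center offsets | 0, −0.06, −0.10, +0.08 | fixed intercept shifts vs the first center |
| subject SD | 0.16 | random-intercept scale |
| residual SD | 0.02 | within-subject noise |
| intercept | 0.30 | grand-mean GD |

Serum NfL is lognormal (median 10 pg/ml, σ_log = 0.5) with correlated
follow-up values; optional injected extremes (a multiple of the median)
exercise the outlier rule. T2LV is generated as a noisy monotone
companion of GD (GD ∝ √T2LV on average, lognormal noise with σ = 0.45),
giving the strong concave GD–volume association the quadratic fit
targets; the noise scale is set so the baseline Pearson correlation
between GD and T2LV sits near 0.8, the level reported for real
lesion-disconnection data. EDSS trajectories mix
worsening, stable and improving by construction. Lesion masks are
spheres centered on control-streamline points (radius growing with the
subject's T2LV rank), so every mask intersects the normative bundles.

Two deliberate non-realisms matter for interpretation. First, the
table's `gd` column is the generating linear model's response itself —
not the output of the imaging pipeline — and is not clipped to [0, 1]:
truncation would bias the coefficient-recovery loop that the generator
exists to close. Second, lesions are spheres and bundles are jittered
straight tubes; the phantoms exercise the geometry code's contracts, not
anatomical realism. Passing tests therefore demonstrate that the
*procedures* are implemented correctly and recover what was planted;
they say nothing about effect sizes in real cohorts.

The template is a 32³ voxel, 1 mm isotropic RAS grid by default. The
pipeline is resolution-agnostic; the small grid keeps a full synthetic
run (simulate → maps → GD → models → 500-permutation voxelwise) in the
seconds-to-minutes range on one CPU.

## Numerical and degenerate-input policy

- Thresholding an already-thresholded map, empty control lists, empty
  lesions, empty masks, off-grid EDSS values, zero-variance vectors and
  rank-deficient designs raise `ValueError` with a specific message.
- Voxels with numerically zero residual variance get t = 0 and a flag
  (not ±inf).
- All generators and the permutation engine are pure functions of their
  seed; reruns are byte-identical, which the pipeline manifest (SHA-256
  per output) makes checkable.
- Tractogram I/O uses the TRK and TCK containers via nibabel; volumes
  are NIfTI. Coordinates are world mm throughout; TRK headers carry the
  grid geometry when available.

## Known limitations

- The robust refit supports center as a fixed effect only; the nested
  random-center variant is available for the conventional fit.
- The permutation engine permutes subjects' residual rows; it assumes
  one map per subject (baseline analysis) and exchangeability under the
  reduced model.
- Only two visits are supported end-to-end; the cohort generator refuses
  more.
- Streamline voxelisation can miss a voxel grazed by a chord shorter
  than a quarter voxel; this is inherent to sampling-based traversal and
  bounded by the tests.
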