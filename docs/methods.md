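# Methods

## The analysis model

The package treats "response to gait rehabilitation" as the change score
(outcome − baseline) of three measures over a course of therapy: walking
speed (m/s, continuous), the Functional Ambulation Category (FAC, ordinal
0–5) and the Modified Rivermead Mobility Index (MRMI, ordinal 0–40).  Two
complementary views of lesion topography are computed on binary lesion
masks in a shared standard space, with right-sided lesions mirrored onto
the left hemisphere so the whole cohort can be pooled.

### Weighted tract lesion load

The load of a lesion against a canonical corticospinal tract is the
slice-weighted overlap Σ_z o(z)·A_max/A(z) (cm³), where o(z) is the
lesion∩tract volume on axial slice z, A(z) the tract cross-section there
and A_max its maximum.  Assumptions: the tract descends along the third
grid axis ("slice" = axial plane of the analysis grid); the tract is a
binarized volume, so A(z) is voxel count × in-plane voxel area, never a
continuous model.  Slices where A(z)=0 cannot contribute overlap and are
skipped, so no division by zero arises.  A lesion with no voxel in any
slice of the tract's z-support (e.g. a medullary lesion below a
supratentorial canonical tract) is flagged `outside_tract_support` and its
load reported missing rather than 0 — zero would assert "no tract damage"
on evidence the tract template cannot provide.  The load is exactly
monotone under lesion growth and additive over disjoint lesions; both are
enforced by tests against a per-voxel brute-force oracle.

Discretization: the weighted load is stable to grid coarsening only while
the tract's waist remains resolvable.  Rasterizing the same mm-space
anatomy at 2 mm and 4 mm changes the load by a few percent when the waist
is ≥ 1.5 coarse voxels wide; a waist below one coarse voxel makes the
weight A_max/A(z) blow up under quantization, which is a property of the
statistic, not of this implementation.

### Voxel-based lesion-symptom mapping

At every voxel lesioned in at least `min_lesioned` subjects (default 6)
and spared in at least two, the change score is regressed on the binary
lesion indicator plus nuisance covariates — age, Fazekas score, days from
stroke to baseline, and the measure's own baseline score — and the lesion
coefficient's t statistic is mapped, with its sign flipped so positive t
means damage lowers the adjusted score.  FAC and MRMI change scores enter
this mass-univariate model as numeric responses, as the classical VLSM
framework does; the ordinal machinery is reserved for the tabular battery.

Implementation: by the Frisch–Waugh decomposition, residualising the score
and each lesion column on the covariate block Z (intercept included)
reduces each voxel's t to a closed form in three cross-products.  The
per-voxel fits therefore vectorise into a handful of matrix products, and
the identity ‖M_Z y‖ = ‖(M_Z y)_π‖ under joint row permutation lets each
permutation reuse the observed residuals.  Tests verify exact (1e-8)
agreement with per-voxel normal-equations solves, and exact equality with
the pooled two-sample t when no covariates are supplied.  Voxels where the
lesion column is collinear with the covariates (or residual variance
vanishes) are flagged inestimable and removed from the search volume with
a log entry; the residual degrees of freedom n − (k+2) are constant over
the remaining voxels, so the cluster-forming p threshold (default 0.005,
one-sided) converts to a single t cutoff via the Student quantile.

Clusters are connected components of the supra-threshold map at a
configurable neighbourhood (26 by default, the most inclusive standard
choice; 6 and 18 available).  Cluster centre of mass is the unweighted
mean of member-voxel mm coordinates.

### Permutation family-wise-error correction

The null distribution is built by reshuffling behavioural rows — score and
covariates together, as one row — against the fixed lesion masks B times
(default 5000) and recording each permutation's maximum t over the whole
search volume (not merely over supra-threshold voxels, so the statistic is
well defined even when a permutation yields no cluster, and there is no
double-dipping).  An observed cluster with peak t* receives

    p = (1 + #{permutation max ≥ t*}) / (B + 1),

significant when p < α (default 0.05).  This max-statistic correction
controls the family-wise error rate by construction; the test suite
verifies calibration empirically (rate of any significant cluster on 200
null cohorts inside the binomial band around 0.05) and exactness against
full enumeration of all 720 assignments at n = 6.  A Freedman–Lane
variant — permuting reduced-model residuals while covariates stay attached
to their masks — is available behind `freedman_lane=True`; the plain
row-reshuffle is the default because it is the direct reading of
"permuting the measures between subjects", and with lesion-independent
covariate distributions the two agree closely.

Design choices left open by the source framework and fixed here, each
overridable in `VlsmConfig`: one-sided testing in the damage-direction
(two-sided available), connectivity 26, covariates permuted jointly with
scores.

### Behavioural battery

Kendall correlations use tau-b (ordinal scales guarantee ties, so the
tie-corrected variant is the only defensible one), with exact p by pair
enumeration for n ≤ 50 without ties and the normal approximation
otherwise.  Wilcoxon signed-rank effect sizes are r = |Z|/√N with zeros
dropped, average ranks, and N the pairs actually tested; Z's sign is fixed
so positive means improvement.  Multiple regression (walk speed, MRMI)
reports raw β, SE, standardized β = β·sd(x)/sd(y), two-sided p, the raw
Pearson r, and the partial correlation recovered from the coefficient t as
t/√(t²+df) — verified against direct residual-on-residual correlation.
Fazekas (0–3) and ordinal baselines enter as numeric scores, one
coefficient per predictor.  FAC change is modelled by a cumulative-logit
proportional-odds model (maximum likelihood via BFGS; OR = exp(β), Wald
χ² = (β/SE)², 95% CI = exp(β ± 1.96·SE)); the logit link is implied by
odds-ratio reporting.  Unstable standard errors (separation) raise instead
of printing garbage.  Quantiles use the linear-interpolation convention
throughout.  No multiplicity correction is applied to the descriptive
correlation table.

## The synthetic cohort

`SimulationConfig` defaults define the study conditions: 50 subjects on a
32³ grid of 2 mm isotropic voxels (the grid resolution implied by the
309-voxel ≙ 2.47 mL bookkeeping), lesion centres drawn from a 3-D Gaussian
(σ = 6 mm) around a striatocapsular hotspot, voxelized-sphere lesions of
radius 4–12 mm with jittered boundaries.  These values were chosen so the
per-voxel overlap map has a single spatial mode with peak overlap ≈ 24 of
50 and median lesion volume of a few cm³, matching what a mid-sized
rehabilitation cohort looks like.  Walk-speed change is generated as
0.70 − 0.8·(overlap mL) − 0.5·baseline − 0.002·age − 0.005·days + N(0, 0.08),
truncated so outcomes stay non-negative; the −0.8 m/s·mL⁻¹ effect over a
0.512 mL effect region yields up to ≈ 0.4 m/s of implanted deficit — a
strong effect against 0.08 m/s noise, appropriate for recovery testing.
FAC and MRMI outcomes come from latent logistic responses thresholded at
configured cutpoints, which is exactly a proportional-odds model, so
ordinal-regression recovery is testable by construction.  One global seed
drives per-subject substreams (`SeedSequence.spawn`), so growing the
cohort never perturbs existing subjects and identical seeds give
bit-identical cohorts.

What the simulator does not emulate: vascular-territory lesion shapes
(blobs suffice because none of the statistics under test depend on lesion
morphology), MRI signal, registration error, or longitudinal trajectories
beyond two timepoints.  Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated — not that real cohorts,
with territory-shaped lesions and registration noise, will localise
effects as cleanly.

## Problem sizes in the test and acceptance runs

The statistical experiments run at sizes chosen to give stable Monte-Carlo
estimates on a single CPU: family-wise-error calibration over 200 null
cohorts of n = 40 at B = 500; permutation exactness against all 720
assignments at n = 6 with B = 2000; effect recovery on the default
50-subject fixture at B = 1000–2000; linear recovery over ~50 noisy
replicates (replicates where outcome truncation binds are excluded, since
truncation biases the linear read-out by design); ordinal recovery at
n = 150–600 and level checks over 200 null fits of n = 80.  The
fully-specified analysis (B = 5000) is the library default.

## Known limitations

- Flipping requires an axis-aligned affine with the grid symmetric about
  x = 0 mm; oblique or asymmetric grids are rejected rather than silently
  resampled.
- The permutation engine assumes one shared analysis grid; per-subject
  native-space analysis is out of scope, as are multivariate
  lesion-symptom methods and probabilistic (non-binary) tract weighting.
- Atlas labelling reports raw percent overlap against whatever parcels the
  atlas defines; granularity caveats (e.g. a grey-matter label that also
  covers adjacent white matter) are the atlas's, not corrected here.
- `loo_stability` reruns the full permutation analysis per fold; at the
  default B = 5000 and n = 50 that is 50 full analyses and is priced
  accordingly.
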