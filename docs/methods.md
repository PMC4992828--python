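# Methods

This note documents the models and numerical choices behind
`alphaconvert`: what the synthetic-data generator emulates, how each
analysis stage is defined, and where design decisions were genuinely open.

## The synthetic cohort model

A cohort consists of three groups — healthy older adults (HO, n=26),
stable amnestic MCI (aMCI-s, n=18) and aMCI that converted to Alzheimer's
disease within a two-year follow-up (aMCI-c, n=16) — with subject records,
trial tables and per-subject 3D source-grid ERD maps.

**Demographics, volumes, cognition.** Age, education, MMSE, immediate and
delayed recall are drawn from per-group normal distributions; left/right
hippocampal and amygdala volumes from truncated normals (floor at 0 mm³,
which at the configured means is >10 SD away and therefore inert). The
per-group means and SDs are the packaged defaults in
`alphaconvert.config`. Total intracranial volume is not part of the
published group table; the default 1.45×10⁶ ± 1.4×10⁵ mm³ reflects typical
adult values, and ICV is enforced to exceed the summed regional volumes.
Cognitive scores are deliberately *not* truncated (e.g. MMSE may
occasionally exceed 30): any truncation would bias replicate-averaged
means away from the configured values, and the scores are synthetic
calibration fields, not clinical instruments.

**Recognition behavior.** Each subject carries a latent memory ability
`m`. The memory task has 18 intact and 18 rearranged face–location pairs
per congruence condition (72 trials); under an equal-variance
signal-detection model with unbiased criterion, the hit and
correct-rejection rate per condition is Φ(m_c/2) and the false-alarm rate
Φ(−m_c/2), with m_c = m ± benefit/2 for congruent/incongruent trials (the
congruency benefit is 0.35 d'-units for HO and aMCI-s and 0 for aMCI-c,
who do not profit from semantic congruence). Trial counts are the rounded
expected counts rather than Bernoulli draws: this keeps the retained-trial
calibration unbiased (a Bernoulli min-rule loses ~3 trials of expectation
at these SDs) while the rates themselves remain group-graded. Omissions
(rates 0.1% / 2.7% / 1.0%) are carved from miss trials only, so planted
hit/false-alarm counts — hence d' — are untouched. Encoding- and
priming-phase trials are generated descriptively (high accuracies, small
congruence RT advantage in priming).

**Retained-trial calibration.** The number of trials retained for the EEG
analysis equals T·Φ((m − benefit/2)/2) with T = 72 (the weaker condition
binds under the equal-trial rule). Writing E[Φ(c+dU)] = Φ(a) with
a = c/√(1+d²) and Var[Φ(c+dU)] = Φ₂(a,a; d²/(1+d²)) − Φ(a)², the group
mean/SD targets (55.7±12.8, 46.1±15.0, 38.8±12.5) reduce to a closed form
for `a` and a one-dimensional root for the variance, solved once per
configuration (`synthgen.ability_params`). Ability is truncated below at
the point where both conditions still yield ≥2 correct trials (≈4 SD out).

**Source-grid ERD maps.** A 12×14×12 grid of 5-mm voxels carries a toy
parcellation (left/right posterior cingulate, left cuneus/precuneus, left
anterior cingulate, right parahippocampal, left inferior parietal,
background cortex). Per band (alpha 8.5 Hz, beta ~16 Hz) and task
(encoding, memory/retrieval), each parcel has a per-group mean ERD depth
with the ordering HO ≤ aMCI-s ≤ aMCI-c (controls desynchronize most,
converters least; depths in percent change, negative = desynchronization).
A subject's map is: parcel mean + subject-level parcel factor (SD 9 for
the planted regions, SD 4 for background) + lightly smoothed voxel noise
(SD 7, Gaussian σ = 0.8 voxels). The magnitudes are package choices — the
source study reports significance maps, not ERD depths — set so that (a)
the stable-vs-converter contrast is cluster-detectable at n=34 in the
alpha-encoding map essentially always and in the secondary maps in a
realistic fraction of runs, and (b) the background parcel is only a weak
classifier (subject-level effect size ~0.4) so regional sources carry the
prediction, as in the original analysis. An early design with a large
shared background factor made the max-cluster-mass null heavy-tailed (a
global factor crossing the cluster-forming threshold floods the grid);
the final variance split restores a well-posed cluster test.

**The planted brain–behavior link.** Within aMCI-s only, the left-PCC
alpha-encoding parcel factor is z = −√R²·u + √(1−R²)·ε, where u is the
standardized ability and R² = 0.48 — deeper PCC alpha ERD goes with better
associative memory. Because observed d' is a nearly linear monotone
function of ability (count rounding and the log-linear correction
contribute <1% variance), the regression of associative d' on PCC alpha
ERD recovers R² ≈ 0.48 on average (with the usual small-sample upward bias
of R̂² at n=18). The other groups' ERD values are independent of ability.

**What the generator does not emulate.** Volume conduction and realistic
sensor covariance, artifacts, atlas geometry, nonstationary spectra,
longitudinal drift, or any correlation between volumetry and EEG beyond
the group structure. Passing tests therefore demonstrate the *analysis
chain's* correctness and calibration on data satisfying its assumptions,
not clinical performance on real recordings.

## Spectral analysis

Epochs are channels × samples × trials at 250 Hz (configurable), spanning
−2.8…+1.1 s around face onset for encoding and −1.3…+1.1 s for retrieval —
wide enough that the 6-cycle wavelet support at the analyzed frequencies
clears the baseline windows (−2100…−1600 ms encoding, −600…−100 ms
retrieval). Morlet power (via `mne.time_frequency.tfr_array_morlet`,
unit-normalized wavelets) is magnitude-squared per trial and averaged
across trials; bins within half the wavelet support (n_cycles/(2f)) of an
epoch edge are flagged invalid, and ERD computation refuses
edge-contaminated baselines. The frequency grid steps 0.25 Hz over
2–25 Hz so the analyzed bins (8.5, 15.75, 16.25 Hz) are exact grid points.
ERD is the percent change of trial-averaged power relative to the mean
baseline power per frequency × channel; normalizing the trial average
(rather than per-trial) is our resolution of an ambiguity in the source
description. Synthetic oscillations are planted with a stepped amplitude
envelope; an amplitude attenuation of 1 − 1/√2 inside the event window
yields an analytic ERD of −50%, which the acceptance suite checks to ±2
points (measuring at bins whose wavelet support lies inside the attenuated
interval).

## Map statistics

Task PLS mean-centers the group-by-element matrix of group means and
decomposes it by SVD; behavioral PLS stacks within-group element–behavior
correlations. Latent-vector p-values come from permuting group labels
(task) or behavior (behavioral); bootstrap ratios from resampling subjects
within groups with per-vector sign alignment. Defaults: 500 permutations,
200 bootstraps (configurable; the fast pipeline profile uses 200/200).

The cluster test thresholds the voxelwise statistic (pooled-variance
two-sample t, or Fisher r-to-z difference of within-group correlations for
the group-difference-in-correlation analyses) at two-sided p < 0.05,
labels face-connected (6-neighbor) components separately per sign, scores
them by mass Σ|t|, and compares against the permutation null of the
maximum cluster mass; p_cluster = (r+1)/(n_perm+1). Sphere features use
radius 3 (Euclidean, voxel units): centers are significant voxels that are
|t|-maximal within the radius (ties to the smallest linear index, for
determinism), members are the significant voxels within the radius
(non-significant voxels are excluded even when geometrically inside),
per-subject sphere means are averaged across spheres sharing an anatomical
label (majority label over members, ties to the center's label).

## Prediction

Candidate predictors are the clustered regional ERD features of each
band × task plus the four MTL volumes, with ICV as an always-retained
nuisance for volume models. Stepwise forward selection adds the candidate
with the smallest likelihood-ratio p below 0.05 and removes terms whose
removal p exceeds 0.10 (the defaults of the standard forward-LR
procedure). Logistic fits use an in-package IRLS Newton solver with a
Firth-penalized fallback on separation — routine at n=34 with strong
planted effects; likelihood-ratio χ² is then computed from the matching
(penalized) deviances with a logged warning.

Cross-validation holds out a stratified 10% (≥1 subject per class, i.e.
2+2 of 18/16) per round, refits the fixed predictor set on the remaining
90%, and pools the held-out linear predictors within the round for AUC,
the Youden-maximizing cutoff (ties toward the lower cutoff), accuracy,
sensitivity and specificity; 34 rounds are averaged and the AUC CI is the
2.5–97.5 percentile interval of per-round AUCs. The CV core is vectorized
(batched IRLS across rounds and permutations; label permutation is
realized as feature-row permutation, which is equivalent under
exchangeability) so the permutation test of the mean AUC runs the full 34
rounds even at 10⁴ permutations; the batched path omits the Firth
fallback because held-out metrics depend only on the score ranking, which
a separating direction already fixes. With 4-subject folds the mean AUC is
discrete; fewer rounds make the permutation test visibly conservative
through null ties, which is why the full 34 rounds are used everywhere,
including the calibration tests.

Relative importance uses Johnson's orthogonalization weights on the logit
scale: predictors are standardized, orthogonalized through R^{−1/2}, the
logistic coefficients on the orthogonal scores are standardized by the
latent-scale SD √(var(η) + π²/3), squared, and mapped back through the
squared loadings; shares are reported as percent of the summed weights.
General dominance analysis (all-subsets McFadden R²) is the independent
oracle in the tests. Confidence intervals are BCa over subject resampling
(bias correction from the bootstrap proportion below the point estimate,
acceleration from the jackknife skewness). Model comparison applies the
Friedman test across models with rounds as blocks and pairwise Wilcoxon
signed-rank tests, Bonferroni-corrected by the number of model pairs.

Open points resolved as package policy: the Youden cutoff is computed
within each round's held-out scores (not pooled); permutations re-run the
fixed-model CV, not the stepwise selection; associative d' pools
hit/false-alarm counts across conditions rather than averaging condition
d's.

## Pipeline and problem sizes

`alphaconvert run` executes generation → behavioral scoring (including the
mixed ANCOVAs: between = group, within = congruence or hemisphere via the
exact two-level summary-statistic split, age/ICV as covariates) → a
sensor-space ERD demonstration on a small subject subset (full epochs for
all 60 subjects would be ~1 GB and add nothing, since the prediction path
operates on source maps and source reconstruction is out of scope) → the
four cluster contrasts and sphere features → the model battery. Stage
seeds derive deterministically from the master seed; the manifest records
content hashes so identical configurations give identical artifacts.

The default fast profile uses 200 cluster/PLS/prediction permutations and
500 relative-weight bootstraps (a full run takes ~30 s on one CPU); the
published-scale counts (10⁴ permutations, 2000 bootstraps) are plain
configuration parameters. The packaged test suite uses 100 replicate
cohorts for moment calibration, 200 for the planted-link recovery, 200
replicates × 199 permutations × 34 rounds for the type-I calibration of
the permutation test, and 25 replicate cohorts for the end-to-end
combined-model check; all seeded, hence deterministic.

## Known limitations

- The atlas and spatial covariance are schematic; cluster-test behavior on
  real source reconstructions (smoothness, depth bias) is not represented.
- Firth-based likelihood-ratio χ² values under separation are penalized
  approximations, flagged by a warning.
- The relative-weight variant for binary outcomes is one of several in
  use; agreement with dominance analysis is demonstrated empirically, not
  guaranteed in pathological correlation structures (a singular predictor
  correlation matrix raises an explicit error).
- Secondary band × task contrasts are borderline-detectable at n=34 by
  design; runs in which they yield no feature simply omit the
  corresponding model row.
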