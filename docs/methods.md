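# Methods

`fetalkin` quantifies fetal limb movement from volumetric MRI time
series in three stages — keypoint tracking, kinematics, and a robust
mixed-effects contrast analysis — and ships a synthetic study generator
so that every stage can be validated end to end without scanner data.
This note records the models, the parameters that matter, and the
design choices made where the problem was genuinely open.

## Kinematics

For each of 12 fetal joints (left/right wrist, elbow, shoulder, ankle,
knee, hip) tracked at positions `p_i` (mm) on a uniform effective frame
interval `Δt`, the per-interval speed is the forward difference

    v_i = ‖p_{i+1} − p_i‖₂ / Δt ,

and the absolute movement time over a series of `n` frames is

    AMT = Δt · #{ i : v_i > v_th } ,

with threshold `v_th = 3 mm/s` (one 3 mm in-plane voxel per second).
The inequality is strict: an interval at exactly the threshold counts
as rest.  No trajectory smoothing is applied before thresholding.
`Δt` is treated as constant per scan (the acquisition TR of 5–8 s is
split into two sub-volumes, giving effective intervals of 2.5–4 s);
timestamps deviating more than 1% from uniform spacing are rejected.

Scans contain one normoxia epoch followed by one hyperoxia epoch
(5–10 min each).  Frames are assigned to the epoch containing their
timestamp and the single inter-frame interval straddling the boundary
is discarded rather than prorated, so no interval mixes conditions.
AMT is pooled over the whole epoch (no sub-windows); raw seconds are
modelled, with the epoch duration carried as a column so that
duration-normalised analyses remain possible.

## Statistical model

AMT distributions are right-skewed, so the response is `ln(AMT)`.
Zero-AMT rows (a joint never crossing the threshold in an epoch) are
substituted by `ln(Δt/2)` and flagged; a drop rule is available.  The
model is a mixed-effects ANOVA with fixed factors

* maternal: scan position (left/right lateral, supine, tilt), parity,
  oxygen condition;
* placental: placental position;
* fetal: sex, fetal position, gestational-age (GA) group (age rounded
  to the nearest week, entered as a categorical factor), joint distance
  class (proximal/middle/distal), extremity (upper/lower), body side;
* interactions GA × extremity and GA × side;

and two random intercepts: one per subject and one per repeated scan of
a subject in a given maternal position (grouping = subject × position
cell).  Variance components are estimated by REML via statsmodels
`MixedLM` (subject intercept via `exog_re`, the scan-within-position
component via a variance-component spec).  When a gradient optimizer
stalls on a zero-boundary variance component, the fit restarts with
Powell's derivative-free method.

### Robust reweighting

Outliers are downweighted with Tukey's bisquare: each row's marginal
residual `r` (response minus fixed-effect prediction) is scaled by the
normalized MAD `s`, weighted by `w = (1 − (r/(c·s))²)²` for
`|r| < c·s` and 0 beyond, with `c = 7.041` for 99% asymptotic Gaussian
efficiency (`c` is solved numerically from the efficiency, reproducing
the conventional 4.685 at 95%).  The fixed effects are then refit by
weighted GLS with the random-effect structure held fixed — a row with
weight `w` contributes residual variance `σ²/w`, zero-weight rows are
excluded — and the loop repeats until the largest weight change falls
below 1e−6 (cap 50 iterations; hitting the cap returns the last
iterate flagged non-converged).  With `robust=off` the weights are
identically 1.

### Contrasts, retransformation, inference, FDR

Reported effects are pairwise level contrasts per factor (labelled
`a-b`, levels ordered alphabetically) and, for the interactions,
per-week lower−upper and left−right slices.  A log-scale contrast `β`
with standard error `se` is retransformed to percent as

    estimate% = (exp(β) − 1)·100 ,  SE% = exp(β)·se·100 (delta method),

with Wald confidence limits retransformed endpoint-wise.  Inference
uses between-within denominator degrees of freedom: each contrast is
referred to a t distribution whose df reflect the finest grouping level
(subject, scan cell, or row) at which the involved design columns vary,
and each family-level test is a Wald F.  This choice keeps the
family-wise null calibration at the nominal rate for cohort-scale
sample sizes, where plain normal quantiles were measurably
anti-conservative for subject-level factors.

False discovery is controlled within families — one family per fixed
effect or interaction — by Benjamini–Hochberg at 5%.

Reference levels are the alphabetically first level of each factor;
because all results are reported as pairwise or slice contrasts, they
are invariant to that choice.  A rank-deficient design reports its
aliased columns and aborts by default; small exploratory runs can opt
into dropping aliased columns (which merges the affected level into
the reference).

## Keypoint tracking

Tracking follows the heatmap-regression recipe: the training target for
keypoint `k` is the unnormalized Gaussian
`exp(−‖x − truth_k‖²/(2σ²))` on the voxel grid (default
`σ = 6 mm` = 2 voxels; peak 1 at the voxel nearest the truth), the loss
is the MSE between predicted and target heatmaps, and the prediction is
the per-channel argmax voxel converted to mm (0-based indices,
voxel-center convention `mm = origin + index · spacing`).  Argmax ties
are broken by the lowest linear voxel index and flagged.

The desk-scale network combines, per output channel, a learnable
positional prior map, the input intensity gated by a learnable
positional attention map, and a residual from a small
fully-convolutional path (two 3×3×3 convolutions with ReLU; three
normalized coordinate channels appended to its input).  All parts are
trained jointly with Adam (default lr 2e−2, batch 4, 40 epochs) by
explicit backpropagation in numpy.  The gated-intensity term carries
keypoint identity through approximate anatomical position — each joint
occupies a distinct spatial zone when the fetal lie is roughly stable —
and its per-channel regression is convex and decoupled, which makes
toy-scale training fast and stable; pure conv-only variants of
equivalent size were found to collapse to the zero-heatmap plateau of
the sparse MSE objective.  Training is deterministic under the config
seed, and a non-finite loss aborts with the offending epoch.

Manual corrections are merged by exact (frame, keypoint) replacement,
with the corrected fraction reported (the study-scale reference value
for this fraction is about 2% of keypoints).

## Synthetic data generator

The generator defines the study conditions for all tests:

* **Design.**  One record per scan.  Subject-level covariates are drawn
  with the cohort frequencies of the observed 52-subject study
  (anterior placenta 26/52, male 31/52, etc.); roughly 19/52 of
  subjects are scanned in two maternal positions and 5/52 twice in the
  same position, matching the 76-scan structure.  GA is uniform on
  [24, 40] weeks by default (an empirical preset, normal 32.08 ± 2.71
  clipped, is available); each scan gets one normoxia and one hyperoxia
  epoch of 300–600 s and an effective `Δt` in [2.5, 4] s.
* **AMT tables.**  `ln AMT = baseline + Σ fixed + Σ interaction +
  u_subject + u_cell + ε`, with independent Gaussian random effects.
  Default SDs are 0.3 (subject), 0.2 (scan-within-position) and 0.5
  (residual); baseline is `ln 60 s`.  The planted-effect preset
  converts the fitted study contrasts from percent to log scale by
  `β = ln(1 + pct/100)` (oxygen +20.7%; distal−middle +20.6% and
  middle−proximal +23.8%, composed on the log scale for the distal
  level; per-week GA × extremity values from +94.4% at week 27 to
  −27.0% at week 38; GA × side −34.4% at week 30).  Generated AMT is
  continuous and not clipped to the epoch length; the trajectory mode
  below enforces physical bounds.
* **Trajectories.**  A bout process (alternating rest/move states with
  geometric dwell, mean move bout 3 intervals) adjusted to hit exactly
  `round(target/Δt)` moving intervals; moving steps are 15 mm in random
  directions (5 mm/s at `Δt = 3`), resting drift stays strictly below
  the threshold.  Composed per epoch on a single global Δt lattice, so
  the kinematics stage recovers each planted AMT within one Δt.
* **Volume phantoms.**  Each frame is Gaussian background noise plus
  one σ = 6 mm intensity blob per keypoint on the 3 mm grid; keypoints
  jitter (SD 4 mm) around fixed anatomical zone centres.

What the phantoms do *not* emulate: fetal anatomy and articulation,
BOLD physiology, maternal breathing, gross fetal repositioning, or
imaging artifacts.  Passing the tracking tests therefore demonstrates
the correctness of the heatmap/argmax machinery and the learnability of
position-plus-appearance gating at desk scale — not performance on
clinical data.  Likewise the parameter-recovery results validate the
estimation pipeline under its own generative model, not the biological
findings.

## Validation protocol and problem sizes

* Parameter recovery: 20 replicates of 300 subjects (≈420–440 scans,
  ≈10,500 analysis rows each), GA spread over groups 27–38 so every
  planted interaction week is populated; each replicate is analysed by
  the full robust pipeline and the mean retransformed contrast is
  compared to the planted percent within 3 Monte-Carlo SEs.
* Null calibration: 200 replicates of 40 subjects with all effects
  zero; the fraction of contrast families containing any BH-flagged
  discovery is compared to the nominal 5% with binomial tolerance.
* Kinematics: exact agreement with a brute-force interval-count oracle
  on 1,000 random trajectories; generator round-trip within one Δt on
  1,000 random targets.
* Tracking: target→argmax round trip within half a voxel diagonal;
  toy training (40 labelled noiseless frames, 24³ grid, 25 epochs)
  reaching mean held-out localization error under one voxel (3 mm).

## Known limitations

* The conv refinement path is far smaller than a clinical-scale 3D
  UNet; the positional-gating design trades capacity for stability and
  would need retraining (and a real encoder-decoder) for data where
  anatomy moves grossly within a scan.
* Robust weights act on marginal residuals; conditional (BLUP-based)
  residuals could separate outlying scans from outlying rows but the
  simpler scheme reproduces the intended behaviour and keeps the
  weighted refit convex.
* Between-within df are an approximation (exact only for balanced
  nested designs); Satterthwaite/Kenward-Roger adjustments are not
  implemented.
* `MixedLM` estimates variance components on the unweighted data; the
  robust loop deliberately does not re-estimate them under the current
  weights.
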