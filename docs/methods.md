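# Methods

`facekin` implements a video-derived facial-kinematics classifier for
at-risk mental states (ARMS): per-frame scalar signals are computed from
51 facial landmarks, collapsed into robust per-participant summary
features, expanded with pairwise interactions, filtered by
gradient-boosting importance, and classified by an AdaBoost ensemble of
small Random Forests under Monte Carlo cross-validation. This note
documents the model, its assumptions, the defaults and the design choices
made where the procedure was genuinely open.

## Input model

The pipeline starts at precomputed landmark trajectories: 51 of the 68
iBUG/300-W points (17..67; the jawline 0..16 is excluded), one row per
frame, pixel coordinates in image convention (origin top-left, y down).
Video decoding, face detection and landmark localisation are out of scope.
Frame rate is carried as metadata; no resampling is performed. Short
dropped-frame gaps (default <= 5 frames) may be filled by linear
interpolation; longer gaps are recorded as segment breaks rather than
fabricated, since the downstream features are dispersion summaries that
tolerate breaks but would be biased by long invented spans.

## Per-frame signals

* **EAR** (eye aspect ratio), per eye `(|p2-p6| + |p3-p5|) / (2 |p1-p4|)`
  over the six eye points; the per-frame value is the mean of both eyes.
* **MAR** (mouth aspect ratio) on the inner-lip points 60..67, defined by
  direct analogy to the EAR (three vertical distances over twice the
  corner distance). This matches the standard drowsiness-detection
  construction and preserves similarity invariance.
* **Head pose.** Pitch/yaw/roll of a rigid head under the decomposition
  `R = Rz(roll) Ry(yaw) Rx(pitch)`, estimated by fitting a shipped
  canonical 3-D face template (`src/facekin/data/face_template_v1.csv`,
  mm-like units) to six 2-D correspondences (nose base 33, nose bridge 27,
  outer eye corners 36/45, mouth corners 48/54) under a pinhole camera
  with focal length = image width and principal point = image centre.
  The fit is a batched Levenberg-damped Gauss-Newton minimisation of the
  reprojection error over (pitch, yaw, roll, tx, ty, tz), initialised from
  the interocular distance; it recovers noiseless synthetic poses to
  <1e-6 degrees and runs all frames of a recording simultaneously. Frames
  whose RMS reprojection error exceeds 10% of the observed interocular
  distance are marked undefined. No camera calibration data is required,
  which keeps the procedure reproducible; absolute angles are only
  meaningful up to the template's geometry, but the downstream features
  use within-recording dispersion, not absolute pose.
* **Nose-anchored angles**: `atan2(y_j - y_33, x_j - x_33)` in degrees for
  every other used point j, positive toward increasing y (downward).
  Angle series are unwrapped across the +/-180 boundary before
  summarisation so wrap-around jumps do not inflate dispersion.

Degenerate frames (zero eye width, coincident points, failed pose) yield
NaN and are carried as missing, never dropped, so every signal has one
value per frame.

## Summary features (default inventory: 649)

Recordings differ in length, so each signal is summarised by robust
statistics: IQR (type-7 linear-interpolation quantiles), unscaled MAD
(median absolute deviation — used as a dispersion summary, not a sigma
estimator, hence no 1.4826 factor), Tukey-fence outlier fraction
(outside Q1 -/+ 1.5 IQR), and lag-1 partial autocorrelation
(Levinson-Durbin on biased sample autocorrelations; lag 1 by default).
Spearman rank correlations link the 21 bilaterally symmetric landmark
pairs per axis. The EAR and MAR additionally carry the percentage of
frames strictly below a first-quartile reference.

The default manifest (649 named features) is:

| group | contents | count |
|---|---|---|
| G1 | 51 points x 2 axes x {IQR, MAD, outlier fraction, PACF1} | 408 |
| G2 | nose-anchored angles 33->j x {IQR, MAD, outlier fraction} | 150 |
| G3 | Spearman rho, 21 symmetric pairs x 2 axes | 42 |
| G4 | Euler angles x {IQR, MAD, outlier fraction} | 9 |
| G5 | EAR x {IQR, MAD, outliers, PACF1, below-Q1 %} | 5 |
| G6 | MAR x {same five} | 5 |
| G7 | inter-frame speed MAD, 30 expressive points (eyes 36-47, outer mouth 48-59, mid-eyebrows 19-24) | 30 |

This inventory is a reconstruction constrained to the published total and
to the feature names that appear in the published model (e.g.
`spearman_48_54_x`, `face_57_x_pacf`, `ear_below_q1_pct`,
`face_33_angle_face30_mad`, `face_19_x_outliers`, `spearman_40_47_y`);
the exact original composition is not public. The manifest is a plain
versioned CSV (`feature_manifest_v1.csv`), so an alternative inventory can
be swapped in without code changes.

The below-Q1 reference is the pooled first quartile of the *training*
participants' EAR (resp. MAR) frames — a per-video quartile would pin the
feature near 25% by construction; per-video mode remains available.
Residual missing cells are imputed with training-split column medians, the
smallest intervention compatible with split-wise evaluation.

## Interactions and selection

Inside every training split, a LightGBM classifier ranks the 649 base
features by importance ("gain" by default, "split" available); the top
m = 40 survivors are expanded with their m(m-1)/2 pairwise products
(named `"a * b"`); the combined set is re-ranked and the top k = 30 names
kept. Base features may survive without entering any product. The staging
and the sizes m, k are this package's choices, sized so the widened stage
(~820 columns) stays tractable at ~90 training rows; both are
configurable. Ties in importance break by column order, making selection
a pure function of (training rows, labels, config, seed). An optional
bootstrap stability filter drops features reselected in fewer than a
configurable fraction of bootstrap resamples (off by default). Selection
runs per split by default (no leakage); a deliberately leaky "global"
mode that selects once on all rows is kept for comparison because the
original procedure is ambiguous on this point.

## Classifier and evaluation

The classifier is discrete (SAMME) AdaBoost — training weights multiplied
by exp(+alpha) on misclassified and exp(-alpha) on correctly classified
samples, final prediction `G(x) = sign(sum_m alpha_m G_m(x))` — with
Random-Forest weak learners, via scikit-learn. Defaults mirror the
reference configuration: 900 estimators, learning rate 2 (unusually
large, kept as documented and configurable), 5 trees per forest, depth 1,
log2 feature subsampling. Scores are the ensemble's class-1 probability;
the decision threshold for sensitivity/specificity/F1 is 0.5 (the
original threshold is unstated).

Evaluation is Monte Carlo (leave-group-out) cross-validation: repeated
stratified 70/30 splits (per-class floor, preserving the 58:70 prevalence
in every split — stratification is our choice; 100 splits at full scale).
All data-dependent steps (below-Q1 references, imputation medians,
selection, fitting) are recomputed per split on training rows only;
mutation tests assert that perturbing held-out rows changes neither the
selection nor the fit. Five metrics are reported per split (F1,
specificity, sensitivity, balanced accuracy = (sens+spec)/2, trapezoidal
ROC-AUC; positive class = ARMS) and summarised as mean/SD/max/min. ROC
curves are vertically averaged on a fixed 101-point FPR grid. Permutation
feature importance is the mean F1 drop after within-column permutation of
held-out rows, summed across splits.

## Convergent validity

Participants are dichotomised per SIPS negative item (0-1 absent, >= 2
present) and each model feature compared between groups with a two-sided
Wilcoxon rank-sum test: exact null distribution when both groups have
<= 12 untied observations, otherwise the tie-corrected normal
approximation without continuity correction (so two identical samples
give p = 1 exactly). Per-group means carry t-based 95% confidence
intervals. No multiple-testing correction is applied by default, matching
per-feature reporting; Benjamini-Hochberg is available. The published
p-values (0.0003, 0.011) belong to the real cohort and are not
reproduction targets.

## Synthetic cohort generator

Because the study's videos are not deposited, a generator produces
landmark cohorts with the statistical structure the analysis assumes.
Defaults define the study conditions: 58 ARMS / 70 controls, 3000 frames
at 10 fps (a 5-minute interview; the real recordings were 5-10 min),
640x480 frames. Each participant is the canonical 3-D template animated
by:

* AR(1) head-pose processes (phi = 0.95 so PACF features are
  non-degenerate; marginal SDs 2.5/3.5/1.5 degrees pitch/yaw/roll) plus a
  constant orientation bias, projected through the same camera model the
  analysis uses;
* raised-cosine expression events — smiles (2/min, ~1.5 s, ~6 mm
  mouth-corner displacement), brow raises (3/min, ~4 mm) and a continuous
  lower-lip "speech" oscillation (~2 mm) — whose amplitudes are scaled by
  the participant's realised expressivity factor;
* blinks (15/min, ~0.3 s, eyelids meeting halfway), *not* attenuated,
  since blinking is largely involuntary;
* i.i.d. Gaussian pixel jitter (SD 0.5 px) standing in for landmark
  localisation noise.

The group effect mirrors the blunted-expressivity interpretation: ARMS
expression amplitudes are multiplied by `expressivity_attenuation`
(default 0.6) and ARMS head-motion SD by `motion_sd_ratio` (default 0.7),
each with lognormal between-participant heterogeneity (SD 0.25 on the log
scale) so groups overlap realistically. Setting both factors to 1 yields
an exchangeable null cohort. Synthetic SIPS items N2/N3 increase
stochastically with a participant's realised blunting
(score ~ round(6.0 x blunting + N(0, 0.8)) clipped to [0, 6]), enabling
convergent-validity tests; N1/N4-N6 carry a generic group shift.

What the generator does **not** emulate: landmark-localisation error that
correlates with pose or expression, identity differences in facial
geometry, camera motion, talking-head audio-visual coupling, or any
symptom structure beyond the single blunting axis. Passing calibration
on these cohorts therefore demonstrates that the pipeline detects
amplitude-attenuation effects of the configured size under this noise
model — not that the published accuracy would replicate on real videos.

## Calibration results the test suite recomputes

At a reduced evaluation scale chosen for desk-class hardware (50 CV
splits, 100 boosting estimators; cohort size, recording length and all
generator parameters at their defaults), the acceptance tests check:
mean ROC-AUC within [0.4, 0.6] on the null cohort; mean ROC-AUC above
0.75 at the default effect; and AUC non-decreasing along the effect grid
(1.0/1.0 -> 0.6/0.7 -> 0.4/0.5 attenuation/motion), within Monte Carlo
error. These are calibration bands of the synthetic construction, not
reproductions of the published Table-2 metrics, which required the real
128-participant cohort.

## Numerical choices and degenerate inputs

* Quantiles: NumPy default linear interpolation (type 7) throughout.
* Angle unwrapping precedes dispersion summaries; raw per-frame angles
  stay in (-180, 180].
* PACF needs length > lag+1 and non-zero variance, Spearman >= 3 complete
  pairs with non-degenerate ranks, outlier fraction >= 4 values; anything
  less yields a missing value that table assembly imputes.
* All-identical training rows raise a fit error rather than fitting a
  degenerate model; single-class truth yields NaN AUC.
* Every stochastic stage is keyed to one master seed via
  `numpy.random.SeedSequence([master, split, salt])`, so partial reruns
  reproduce exactly.

## Known limitations

* The 649-feature inventory, the selection staging (m = 40, k = 30) and
  the 0.5 decision threshold are reconstructions of under-specified steps;
  all are configurable rather than hard-coded.
* The pose estimator assumes an orthodox pinhole camera with focal length
  = image width; absolute Euler angles inherit any mismatch between the
  template and the true face, though dispersion features are insensitive
  to a constant offset.
* Rank-sum p-values on features from a single cohort are strongly
  mutually dependent (all features share the head-motion process);
  uniformity checks must pool across independent cohorts.
* AdaBoost's learning rate of 2 frequently saturates the per-split score
  distribution; threshold-based metrics (sensitivity/specificity/F1) are
  accordingly high-variance across splits even when AUC is stable.
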