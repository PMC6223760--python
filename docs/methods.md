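# Methods

## Registration models

**Single-landmark registration (SLRM).** The image-to-patient map is a
rigid transform `T = (R, t)` from the preoperative image frame to the
tracking reference frame (the rigid body fixed to the operating table).
The rotation is not estimated from point correspondences: it is read off
a tracked tool that the operator lays along the patient's longitudinal
axis, parallel to the coronal plane. The package's axis convention —
rotation column 1 = longitudinal (cranial→caudal), column 2 = left–right,
column 3 = anterior "up" — is applied identically to the image volume and
to the tool's local frame, so the tool rotation is used directly as `R`.
Which local tool axis is "longitudinal" is a convention the tracker
vendor does not fix; we document local x = longitudinal, local z =
anterior. Because the tool is held facing upwards for both supine and
prone patients (its reflective markers must stay visible), the prone case
pre-composes a 180° rotation about the longitudinal image axis. Applying
the flip to the acquired orientation rather than to the image volume is
an equivalent, documented choice.

The translation makes one landmark exact: `t = p_patient − R · p_image`.
Re-registration at a new pair replaces `t` by the same formula and keeps
`R` bitwise unchanged; only the newest point is retained, no history is
blended. When several orientation samples are supplied, their chordal
mean is used by default (`orientation_mode="last"` keeps the final
sample); the chordal mean — sign-align quaternions to the first sample,
average, normalize — is adequate for the tightly clustered samples of a
held tool and is a documented limitation for widely spread inputs.

Error model: if the acquired orientation is wrong by an angle `θ` about
an axis through the registered point, a target at distance `d`
perpendicular to that axis is displaced by the chord `2 d sin(θ/2)`.
Accuracy is perfect at the registered point and grows linearly (for small
`θ`) with distance — the reason the method is paired with intraoperative
ultrasound re-registration at the lesion itself.

**Fiducial registration (FLRM).** The classical least-squares rigid fit:
subtract centroids, SVD the cross-covariance `H = Pcᵀ Qc`, take
`R = V diag(1,1,det(VUᵀ)) Uᵀ` (the determinant factor corrects a
reflection when the best orthogonal matrix is improper), then
`t = q̄ − R p̄`. FRE is the RMS fiducial residual. Fiducials are
unweighted. Configurations whose image-side points are (near-)collinear
are rejected when the ratio of the second-largest to largest singular
value of the centered point matrix falls below 1e-6 — far below the
physical spread of case-mounted fiducials, so only genuinely degenerate
inputs are refused.

## Pivot calibration

Pivoting a pointed tool about a fixed physical point gives, per tracked
pose, `R_i p_tip + t_i = p_pivot` with `p_tip` in the tool frame and
`p_pivot` in the reference frame. Stacking all poses yields a linear
3n×6 least-squares system solved directly; it is exact in the noiseless
case and returns both unknowns at once, which is why it is preferred over
sphere fitting. Pose sets whose rotations are (nearly) identical make the
system rank-deficient and are rejected (smallest singular value < 1e-8).
No sample-validity filtering is emulated: vendor tools discard "invalid"
samples by undocumented criteria, so the calibration here uses every
pose.

## Ultrasound click localization

A click `(u, v)` on a tracked 2-D slice maps through
`pose ∘ calibration ∘ (u·s_u, v·s_v, 0)`. Pixels are 0-based, `u` indexes
columns (lateral) and `v` rows (axial depth), points sit at pixel
centers, and fractional coordinates are allowed — zooming the display
refines the click but cannot change the mapping (tested as zoom
invariance). The geometry assumes a linear transducer; no scan conversion
or image content enters the computation. The probe pose is taken
synchronously at click time; no interpolation between tracking frames is
modelled.

## The virtual phantom and the displacement protocol

The phantom reduces an abdominal ultrasound phantom to labeled points in
the image frame: a liver reference landmark (standing for the meeting
point of the round and falciform ligaments), a lesion placed **exactly
60 mm** away in a random direction, and five fiducials jittered around
distinct corners of a 300×240×160 mm rigid case (well-spread,
non-collinear by construction; every seed's configuration is verified
against the fiducial-fit degeneracy check). Its placement on the table is
a ground-truth rigid transform, initially the identity; table
displacements translate it along the frontal (reference x) or
longitudinal (reference y) grid axis — the grid axes are a labeling
choice.

The protocol follows the evaluation design: the first image-to-patient
registration is performed **once**, on the undisplaced phantom — the
orientation is sampled there and reused for the whole run, because pure
translations never invalidate it — and after each displacement the model
is re-registered at the same reference point (translation-only
correction). The fiducial method instead refits all five fiducials after
every displacement. Each trial then localizes the lesion through the
simulated ultrasound chain and records
`TRE = ‖T̂(lesion_image) − lesion_clicked‖`. The default grid
(10 repetitions × {10, 50, 100} mm × {frontal, longitudinal} × 2 methods)
gives 120 trials, 60 TRE samples per method.

**Noise model.** Three independent sources, all configurable:

| parameter | default | unit | emulates |
|---|---|---|---|
| `sigma_tool_pos` | 0.3 | mm | per-axis tracked-position jitter (order of the tools' optical calibration errors) |
| `sigma_tool_angle` | 1.0 | degree | orientation error, magnitude half-normal about a uniformly random axis |
| `sigma_click` | 0.5 | mm | in-plane user click error on the slice |

The ultrasound probe is modelled as rigidly attached to the phantom case,
so its true pose follows the ground truth exactly; the tracker measures
it with the position/orientation noise above, and the lesion lies in the
image plane at a fixed pixel by construction.

**Determinism.** One root seed; each trial draws from a counter-derived
`SeedSequence` substream (the experiment-level initial registration uses
a dedicated substream key `2³⁰`, outside the trial counter range), so
trial records are independent of grid iteration order.

**What the simulator does and does not emulate.** It reproduces the
*structural* properties of the two methods — exactness of the zero-noise
chain, the chord law of orientation error and its absence from the
fiducial method, invariance to table translations — and realistic
relative behaviour under the default noise. It does not model respiratory
or pneumoperitoneum deformation, B-mode image content, human reaction
time, or the specific hardware noise of any tracker, so its absolute TRE
magnitudes are not claims about any physical phantom experiment; passing
tests certify the algorithms and the chain, not millimetre accuracy on
real hardware.

## Evaluation and statistics

Group summaries follow the standard report shape: mean, sample sd (n−1),
min, max, and repeatability defined as the standard error of the mean,
`sd/√n`, computed from unrounded sds (rounded table cells would not
regenerate it exactly). Tabular output rounds mean/sd/min/max to one
decimal and repeatability to two.

The one-way ANOVA is the classical balanced fixed-effects decomposition
(`F = MSB/MSW`, df `(k−1, N−k)`); with balanced groups the
sums-of-squares type question does not arise. Welch's test reports the
`t` statistic with Welch–Satterthwaite fractional degrees of freedom and
a two-sided p-value. Both are implemented from their textbook formulas
and cross-checked in the test suite against scipy's independent
implementations (`f_oneway`, `ttest_ind(equal_var=False)`); Welch's null
calibration (empirical type-I error ≈ α on resampled null data) is
verified end to end. Levene's test and Tukey/Scheffé post-hoc comparisons
are deliberately not implemented.

The displacement-invariance check compares the six single-landmark group
means pairwise: `|m_i − m_j| < 3·√(se_i² + se_j²)`, i.e. within three
standard errors of the difference — the standard reading of "within
three standard errors of each other".

## Numerical choices

* Rotations are stored as matrices (SVD-friendly); quaternions
  (scalar-first `w,x,y,z`) appear only at file boundaries.
* Orthonormality is validated to 1e-9; drift above 1e-12 (e.g. long
  composition chains) is repaired by SVD projection to the nearest proper
  rotation.
* Frame construction from measured axes uses Gram–Schmidt with the
  longitudinal axis as the first column; axes closer than ~1e-6 rad to
  (anti)parallel are rejected.
* Degenerate-input thresholds: fiducial collinearity 1e-6
  (singular-value ratio), pivot rank deficiency 1e-8 (smallest singular
  value).
* The brute-force oracles in the test suite (multi-start
  Levenberg–Marquardt over rotation-vector + translation parameters, and
  direct minimization of the pivot residual) are independent of the
  closed-form code paths they verify.

## Problem sizes

The shipped defaults are the study conditions themselves: 120 trials per
protocol run, 600 poses for the noisy pivot study, 100 random instances
per fiducial-oracle comparison (noiseless and noisy), and 1000 resamples
for the Welch null calibration. The whole test suite and the acceptance
script each complete in well under a minute.

## Known limitations

* Rigid registration only: no deformable, surface/ICP or vessel-based
  refinement; anatomical deformation is outside the model.
* The chordal rotation mean degrades for widely spread orientation
  samples.
* The displacement-invariance property is a statistical statement about
  group means; any single seeded run of 10 repetitions per group has a
  small false-alarm probability inherent to comparing 15 pairs.
* The simulator's noise magnitudes are plausible defaults, not a
  calibrated model of any specific tracking hardware.
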