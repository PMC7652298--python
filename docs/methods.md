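# Methods

This note documents the models, numerical choices, and open design
decisions behind `roboreplay`, and what the synthetic study conditions do
and do not establish about real data.

## Coordinate conventions and units

All internal quantities are SI (m, s, rad); degrees appear only at the CLI
and in robot configuration files. Frames are right-handed. By data
contract, gravity points along −Z of both the motion-capture frame and the
robot base frame; this shared vertical is what makes a yaw-plus-translation
relocation of a trajectory "gravity-consistent" (gravitational load
directions relative to the motion are preserved, and speeds are unchanged
because the relocation is an isometry). The humeral anatomical frame has
its origin at the glenohumeral rotation center with +Y superior (the
humeral long axis, from the epicondyle midpoint to the head center), +X
anterior (perpendicular to the plane of the superior axis and the
epicondyle line), and +Z completing the right-handed triad. No
Euler/Cardan convention is needed anywhere: all pipeline math is
matrix-based, and reported orientations use the rotation-vector form.

Rotation-vector conversions return angles in [0, π]; at exactly π the
antipodal representative with a non-negative largest component is chosen
for standalone conversions, while trajectory code resolves the branch by
continuity with the previous sample (raising if consecutive samples still
differ by more than π, which indicates under-sampling rather than a branch
artefact).

## Robot model

The manipulator is six revolute joints described by standard
Denavit–Hartenberg rows plus per-joint position and velocity limits, all
loaded from YAML. The packaged `m20ia_class.yaml` approximates a ~1.8 m
reach, 20 kg payload industrial arm from vendor-published reach and axis
speed figures (195/175/180/360/360/550 deg/s); it is not factory
calibration data, and every pipeline property is defined with respect to
the configured model, never hard-coded geometry. A planar two-link model
(`planar_test.yaml`) exists for hand-verifiable kinematics.

Inverse kinematics is numeric: Levenberg–Marquardt on the 6-D pose error
(position difference stacked with the rotation vector of the orientation
error), with accept/reject damping adaptation, a 0.5 rad trust-region cap
on step length near singularities, and a 1e-9 convergence tolerance.
Seeding each timepoint with the previous solution selects the IK branch
nearest in joint space, which makes the joint trajectory unique given
q(0) and keeps it continuous. Joint velocities are central finite
differences at the native rate (one-sided at the ends).

## Trajectory processing

Derivatives follow the verification convention: orientations are converted
to unwrapped rotation vectors; positions and rotation-vector components are
low-pass filtered once with a zero-phase (bidirectional) 4th-order
Butterworth filter — 8 Hz for verification, so the effective cascaded
response is |H|² = 1/(1+(f/8)⁸) — then differentiated by central
differences, and a second time for accelerations. Filtering happens once,
before the first differentiation. The filter pads with several filter
time-constants (≥ 3·rate/cutoff samples) so edge transients and slow
trends (jogging's forward travel) are not distorted. Differentiating
rotation-vector components is not identical to the exact body
angular-velocity map; for the smooth, band-limited trajectories in scope
the difference is second-order, and wherever true angular velocity matters
(inverse dynamics) the exact rate-to-angular-velocity map is applied.

Ramp-up and slow-down segments joining rest to a moving junction are
per-component quartics with five boundary conditions (zero velocity and
acceleration at the rest end; position, velocity, and acceleration matched
at the junction), 30 samples at 200 Hz (0.15 s) by default. A quartic's
jerk is linear rather than constant; the quartic-with-matched-endpoint
interpretation is the one consistent with the stated boundary behavior and
is what ships here.

## Frame identification

The session calibration solves A·X = Z·B over pose pairs — A robot flange
poses from the controller (treated as exact; industrial repeatability is
±0.03 mm, an order below tracker noise), B tracked rigid-body poses, X the
end-effector-to-rigid-body transform, Z the robot-to-tracker embedding.
Rotations come from the homogeneous linear system
`(I ⊗ RA_i)·vec(RX) = (RBᵢᵀ ⊗ I)·vec(RZ)` via the smallest singular
vector, projected to SO(3) (polar decomposition), with the sign fixed by
the determinant; translations then solve a linear least-squares problem;
a Levenberg–Marquardt pass jointly refines all twelve parameters. The
translation of Z is estimated and discarded — verification metrics are
translation-normalized, so only the tracker-to-robot *rotation* is used.
Identifiability requires the relative rotation axes of the robot poses to
span at least two independent directions; this is checked and violated
configurations raise. Conformance is defined by precision, not algorithmic
identity: under 0.1 mm simulated tracker noise with 20 poses the recovered
rotation and translation are accurate to well under 1° and 1 mm (the
acceptance script measures ~0.02° and ~0.05 mm medians).

The sphere fit for the glenohumeral center is the algebraic least-squares
formulation (linear in the center and in r² − ‖c‖²), with a rank/condition
check that rejects coplanar point sets.

## Mapping optimization

Both optimizers minimize joint-velocity utilization subject to joint and
velocity limits, differing in parameterization:

* **Derivative-free (COBYLA) over q(0).** Each candidate q(0) implies a
  candidate transform `K(q0)·ᴱᴱT_H·(ᴹᶜT_H⁰)⁻¹`, reduced to the
  gravity-consistent form by extracting the yaw component of its rotation
  (the Frobenius-closest rotation about +Z). Because of this projection the
  *used* mapping is exactly gravity-consistent for every candidate, so the
  tilt of the unprojected candidate is reported as a diagnostic rather than
  enforced as a constraint — re-parameterizing any solution by its own
  first joint vector drives the tilt to the IK residual (~1e-11). The
  objective is the max-over-time-and-joints normalized |q̇| (minimax,
  matching "utilization" semantics); constraints are joint position limits
  and utilization ≤ 1. COBYLA is local, so a small set of deterministic
  multi-starts (workspace-center postures) recovers from bad basins; the
  best feasible candidate seen anywhere is returned. Infeasibility — no
  candidate satisfying the robot limits — is a valid scientific outcome
  and is returned as a report, not an exception.

* **Gradient-based NLP over the full trajectory.** Decision variables are
  all q(k) plus (θ, t); equality constraints enforce the kinematic chain at
  every retained timepoint; joint limits are bounds and velocity limits
  sparse linear constraints; the objective is the smooth surrogate
  Σ (q̇ᵢ(k)/q̇ᵢᵐᵃˣ)². The solver is scipy's trust-region interior-point
  method with analytic sparse constraint Jacobians assembled from the
  geometric Jacobian (first-order in the orientation error, exact at the
  solution). After the NLP returns, the refined (θ, t) are re-projected to
  exact kinematic feasibility by sequential IK, so the FK residual never
  worsens; if the refinement does not improve a feasible warm start, the
  warm start is returned (descent guarantee). This is the fast path for
  the virtual-to-physical tool-frame substitution: a solution optimal for
  one tool frame warm-starts the solve for a slightly different one.

Tolerances: FK residual 1e-6 m / 1e-6 rad defines feasibility (sequential
IK typically achieves ~1e-10); optimizer stopping 1e-8 relative.

36 tool frames (physical + 35 virtual) enumerate 3 clamp positions along
the humeral shaft (as-clamped ~1″ distal to the head, midshaft, ~1″
proximal to the epicondyle midpoint) × 12 rotations in 30° increments
about the humeral long axis; the physical frame is position 1 at rotation
0, and the 30° set at each clamp includes 0° — the enumeration consistent
with the 35+1 count.

## Program generation and the virtual controller

Subsampling keeps exactly round(f·N) indices including both endpoints
(default f = 0.2: at 200 Hz this spaces waypoints ~25 ms apart on average,
matching controller-vendor guidance of ~24 ms between programmed points).
The algorithm is greedy maximum-deviation insertion — adaptive
Ramer–Douglas–Peucker with the combined pose metric
d = ‖Δp‖ + ρ·angle(ΔR), ρ = 0.3 m (a characteristic humeral length
converting radians to meters), against linear-position/slerp-orientation
interpolation of the kept path. Greedy insertion lands the exact budget
directly, so no tolerance search is needed; on zero-curvature stretches
ties are split in whole multiples of the uniform spacing, so straight
segments come out near-uniform. By construction the result's maximum
deviation is no worse than uniform subsampling at equal count, and kept
points concentrate at corners.

The program dialect is a minimal line-oriented text format (index, six
joint angles in degrees, waypoint time, segment speed in mm/s, smoothness
0–100) standing in for vendor languages; a vendor-specific emitter is an
extension point. The virtual controller exists to exercise the
verification pipeline end-to-end and deliberately models no proprietary
look-ahead: joint motion is piecewise linear at the programmed timing,
stretched where a segment would exceed a joint speed limit (the robot
saturates and arrives late); corners are blended by a moving-average
window proportional to smoothness (the box filter of a piecewise-linear
profile is exactly a trapezoidal velocity transition); endpoints are
fine-positioned. Default smoothness is 100 (maximum blending); per-activity
values are configuration, as no canonical settings exist.

## Inverse dynamics

The prosthesis chain is rigid with the humerus (the elbow is fixed per
activity: 90° flexion for jogging and internal rotation, 135° for jumping
jacks, 180° extension for jug lifts). Segments are uniform solid cylinders:
the prosthetic connection (length 0.75 × arm length, Ø 60 mm, mass
0.50823 kg/m × length + 0.3 kg) runs along the shaft from the 25%
amputation level to the elbow; the forearm (254 mm, Ø 76.2 mm, 1.013 kg)
folds from the shaft direction toward anterior by (180° − elbow angle) in
the sagittal construction plane; the hand (152.4 mm, Ø 54 mm, 0.416 kg)
continues collinear; the jug (250 mm, Ø 150 mm, 3.8 kg; jug-lift trials
only) is centered at the hand's distal end. These geometric placements are
package conventions, documented here because no canonical ones exist.

Given the humeral pose trajectory and its filtered derivatives, the body
angular velocity is obtained from the rotation-vector rates by the exact
map ω = v̇ + (1−cos a)/a² (v×v̇) + (a−sin a)/a³ v×(v×v̇) (a = ‖v‖), and the
angular acceleration by central-differencing ω. A distal-to-proximal
Newton–Euler recursion accumulates each segment's Newton force m(a_c − g)
and Euler moment I_w·α + ω×(I_w·ω), transported to the interface point at
the 25% amputation level; the result is the wrench the residual bone
exerts on the prosthesis. Projections against the current humeral axis
(the body-frame superior axis rotated by the pose) give axial force,
torsional moment, and bending moment (the norm of the moment component
orthogonal to the axis). Gravity defaults to (0, 0, −9.81) m/s².

The gravitational share of a load runs the recursion twice — full, and
with all velocity/acceleration terms zeroed — and divides. For slow jug
lifts (peak angular speed ≤ 30°/s) the gravitational share of the peak
bending moment computes to ~99%, comfortably above the 90% level expected
for this activity: the jug's weight, not inertia, owns the bending load.

## Verification metrics

Both trajectories are re-expressed in the initial-thorax frame before any
scoring — this is the reference frame for all metrics, and it also keeps
rotation vectors near the origin, where span normalization is meaningful
(raw robot-frame rotation vectors have large norms with tiny spans, which
would degenerate the normalized magnitude error). Translations are then
normalized to the first waypoint (kinetically neutral), and the trajectories
are temporally aligned by the integer offset maximizing the summed Pearson
correlation of the six pose channels over the overlap window. Per-window
correlation (rather than a global z-score) matters: sub-window means bias a
raw cross-correlation by several samples. Ties break toward the smallest
|offset|; flat signals raise an alignment-undefined error.

The normalized MAE is MAE ÷ (max − min of the desired signal), per thorax
axis (ML/AP/IS) and for the Euclidean magnitude; the magnitude variant is
normalized by the span of the magnitude *time series* (the literal reading
of the procedure; the alternative — the magnitude of per-axis spans — was
not adopted). Axes whose desired span is below numerical floor are
reported as undefined (NaN) rather than divided by a floor: span-induced
inflation on secondary axes is a property of the metric, not a replication
failure, and masking it with a floor would hide that. The error-at-peak
for loads is |desired(t*) − achieved(t*)| / span(desired) at
t* = argmax |desired|, with no mean-centering.

The full virtual replication includes an optical-tracking measurement
stage: the simulated achieved trajectory is passed through the tracker
noise model (0.1 mm point accuracy) before comparison, since in a real
session the achieved kinematics are only available through the tracker.
This stage is what reproduces the characteristic error growth with
differentiation order (pose < velocity < acceleration MAE).

## Synthetic study conditions

The generator emulates the *statistical shape* of skin-marker humeral
kinematics as sums of a dominant sinusoid plus two weaker harmonics per
axis with randomized phases, under a smooth envelope taking every channel
to rest at both ends. Per-activity defaults (amplitudes, frequencies,
durations) encode the activities' signatures: jumping jack — large
elevation oscillation (~110° span) in a compact volume; jogging — ~0.45 m
anterior travel with 1.3 Hz oscillation, ML position span inside the
24–681 mm range reported for such trials; jug lift — slow large
bending-plane rotation with peak angular speed at or below 30°/s (verified
across seeds); internal rotation — fast axial twist (~130° span, peak
~800°/s) with millimeter-level translation. Trials are deterministic given
a seed.

Tracker noise adds isotropic Gaussian position noise of SD σ (default
0.1 mm, the stated tracker accuracy) directly to translations, and derives
orientation noise by re-fitting each pose from a virtual centered 16-marker
hemispherical constellation (50 mm radius) whose markers are perturbed by
the same σ — so angular noise scales as σ/(radius·√n), halving when the
constellation radius doubles. Calibration fixtures build pose pairs from
known ground-truth transforms with robot poses treated as exact.

What passing on these conditions shows: the pipeline's algebra, optimizers,
controllers and metrics are mutually consistent and meet the stated
precision/accuracy bars under realistic spans, rates, smoothness and
measurement noise. What it does not show: robustness to soft-tissue
artefact (same frequency band as bone motion, subject/task-specific —
explicitly out of scope), to controller look-ahead behavior of real
vendors, or to non-band-limited motion content.

## Problem sizes

Defaults mirror the study conditions: 200 Hz native rate, full-duration
activities, 20% subsampling, 8 Hz verification filter, 30-point ramps,
100-repeat Monte-Carlo for calibration precision. Optimization-heavy tests
and examples run shortened trials at reduced rates (e.g. 3–4 s at 25–50 Hz),
chosen as the smallest sizes at which the contracts under test are
non-trivial; all thresholds are identical at full scale.

## Known limitations

* The shipped industrial-arm geometry is approximate; results that depend
  on exact reach or wrist geometry require a calibrated config.
* The gradient-based NLP scales to a few hundred timepoints in reasonable
  time; for dense 200 Hz captures it is intended to refine retained
  (subsampled) timepoints or warm-started solutions, not to solve cold.
* The virtual controller is deliberately idealized (no look-ahead, no
  acceleration limits); achieved-vs-desired errors on real hardware will
  be larger, particularly for velocity and acceleration.
* Joint acceleration/torque limits are not modeled (unknown for the target
  platform); the optimizer accepts additional constraints structurally but
  none are configured.
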