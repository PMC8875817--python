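# Methods

## Problem setting

`gaitfit` tracks the feet of a walking person from a depth camera mounted low
(10 cm above the floor) *behind* the walker — the viewpoint of overground
gait-assistive robots that follow their user.  From this viewpoint only the
backs of the shanks and the heels are reliably visible; the forefeet are
mostly hidden.  The tracker therefore fits simple rigid geometric models to
the visible surfaces rather than attempting full shape reconstruction, and
derives spatio-temporal gait parameters (step length, step width, cycle,
stance and swing times) from the fitted poses.

## The foot–shank model

Each lower limb is two rigid primitives sharing an origin at the ankle (the
center of the plane where shank meets foot):

* **Foot** — a U-shaped prism: a rear half-cylindrical heel wall of radius
  `r`, two planar side walls running forward to the toe edge (total outer
  length `l`), and a flat sole at depth `h` below the ankle.  The top and
  front faces are removed — they are never visible from behind and would
  attract wrong correspondences.  The calcaneus is modeled as a radial bulge
  of the rear heel arc, growing linearly from zero to `d` over the top 40 %
  of the foot height.  The exact vertical extent and shape of this bulge are
  a modeling choice (any monotone rear bulge is equally defensible); the
  radial form was chosen because it keeps every point-to-surface distance
  closed-form.
* **Shank** — the rear half of a tapered cylinder (radius `r1` at the ankle,
  `r2` at the top, length `s`), without end caps.

Model frame: `x` lateral, `y` forward (toe direction), `z` up along the
neutral shank axis; millimetres throughout.  The shank orientation is
parameterized as `Rx(θx)·Ry(θy)` — rotation about its own long axis is
unobservable for a surface of revolution and is dropped.  Foot orientation is
a full quaternion.  Both models share one translation (the ankle position in
the camera frame).

All four surface-patch distances (bulged heel wall, side-wall rectangles,
sole region, shank frustum wall) are exact closed forms built from
point-to-segment and point-to-region distances; points outside a patch's
angular range measure distance to the patch boundary edges.  The test suite
checks these against an independent dense-sampling oracle with a quantified
resolution bound (grid spacing/√2).

## Per-frame pipeline

1. **Preprocessing.**  The depth map is deprojected through the pinhole
   model (camera frame: x right, y down, z forward); points beyond 1.0 m are
   cut.  The ground plane is found by RANSAC over near-horizontal candidate
   planes with an SVD refinement on the inliers; only points above the plane
   survive.  The plane is estimated once on the first frame and reused (the
   camera is static relative to the floor in the intended mounting);
   re-estimation per frame is available via `reestimate_ground`.
2. **Clustering.**  Connected-component labeling on the pixel grid, where
   4-adjacent pixels connect iff their depths differ by less than 20 mm;
   components under 50 px are dropped as speckle.  Component centroids are
   split into two groups by 1-D k-means on the horizontal pixel coordinate,
   ordered into left/right.  One surviving component — or both k-means
   centroids mapping to the same previous-frame limb, the signature of a
   lone fragmented limb — flags a *single group*.
3. **Foot/shank labeling.**
   * *Expansion-segmentation* (two groups): a horizontal separation line
     starts `r_initial = 10` rows above the group's lowest pixel and moves up
     one row at a time.  At each line, pixels below are foot and above are
     shank; the pose optimizer runs (with reduced iteration and point caps)
     and the candidate line is scored by the total cost evaluated over the
     *full* observation — the subsampled optimizer objective itself jitters
     as the pixel sets change.  The sweep stops at the first strict cost
     increase, returning the previous line (no patience).
   * *Contour-segmentation* (single group): the posed models from the
     previous frame are projected into the image; one convex hull is built
     per model from dense surface samples, and in-hull pixels whose 3-D
     points lie within 15 mm of that model's surface are labeled.  Pixels in
     both hulls go to the nearer surface.
4. **Cost optimization.**  The total cost is

   `E = E_foot + E_shank + E_additional`, with
   `E_foot = E_dist,foot + w1·E_silhouette,foot + w2·E_ground`,
   `E_shank = E_dist,shank + w3·E_silhouette,shank + w4·E_orientation`,
   `E_additional = w5·E_limit + w6·E_temporal,rot + w7·E_temporal,trans`.

   The distance terms sum point-to-model distances of the observed points in
   the model frame; the silhouette terms sum, over projected model key
   points, the Euclidean pixel distance to the nearest observed pixel of the
   same part (13 foot key points on the sole perimeter, wall top rim and
   heel arc; 16 shank key points on the two rim half-circles); the ground
   term sums the penetration depth of key points below the floor; the
   orientation term is `1 − axis·n_ground`; the limit term is the sum of the
   two dot products between the shank long axis and the foot forward and
   lateral axes (zero in neutral stance; an absolute-value variant sits
   behind `limit_abs`); the temporal terms are the geodesic rotation angles
   and the translation distance to the previous frame's *raw* (unsmoothed)
   pose.

   Minimization is a hand-rolled Levenberg–Marquardt over the eight
   incremental parameters (foot rotation vector, shared translation, two
   shank angle increments).  Every non-negative term enters the residual
   vector as `sqrt(term + 1)`, so the sum of squared residuals equals the
   total cost plus a constant while the square-root gradient stays bounded
   at a perfect fit; the two signed limit dot products enter as plain
   residuals (a symmetric squared penalty — a signed scalar cannot be a
   Gauss–Newton residual of a linear sum).  The Jacobian is forward finite
   differences (1 mrad rotation, 0.5 mm translation steps).  Each accepted
   step is integrated into the pose (`R̃ ← R̃·ΔRᵀ`, `t̃ ← t̃ + Δt`) and the
   increment reset; steps that do not decrease the objective are rejected
   with increased damping, so the objective never rises.  Termination: the
   objective, its relative change (10⁻³), or the step norm (10⁻³, mm/rad
   mixed) falls below threshold, or 30 iterations.  Observations are capped
   at 400 points per part by uniform stride (200 inside the expansion sweep,
   with 8 inner iterations).
5. **Kalman smoothing.**  A constant-velocity linear filter on
   [translation, foot rotation vector relative to the neutral alignment,
   θx, θy] with white-acceleration process noise (4 m/s², 40 rad/s² — loose
   enough to follow swing-phase accelerations at 50 fps) and a Mahalanobis
   innovation gate (χ² = 40 on the 8-dim innovation) that holds the
   prediction on outliers.  A limb with no usable observation coasts on the
   prediction, which keeps the model moving with its last velocity through
   short occlusions instead of freezing behind the limb.

Limbs are optimized independently — no cost term couples them.

### Weights

The cost structure defines seven weights without canonical values; the defaults
(`w1 = 10, w2 = 10, w3 = 4, w4 = 2000, w5 = 200, w6 = 200, w7 = 0.5`) were
calibrated once on the synthetic suite so that each weighted term contributes
comparably at a 5° / 20 mm perturbation of a standing pose, with the foot
silhouette weight raised until the weakly observed yaw mode (see
*Limitations*) is held by the toe key points.  All are exposed in the config
file.

## Gait analysis

Heel-strike (HS) and toe-off (TO) are local maxima and minima of the
anterior–posterior (AP) distance — the projection of the foot translation on
the walking direction `v_dir` (default: straight away from the camera).  An
extremum is accepted when it is the strict extremum of a centered 19-frame
window (ties resolved toward the earlier frame).  Candidates are filtered in
time order: a same-kind candidate replaces the previous event only if more
extreme, and a candidate closer than `Δd_min = 5` frames (100 ms at 50 fps)
to the last opposite-kind event is rejected as noise.

Consecutive same-side HS pairs with at least one interior TO form a cycle;
among several TOs the one whose stance-to-cycle ratio is closest to the
ideal 60 % is kept.  At each cycle-terminating HS, the displacement between
the two feet's (Kalman-smoothed) origins gives
`step_length = |d_step·v_dir|` and the Pythagorean residual
`step_width = √(‖d_step‖² − step_length²)` (clamped at zero).

## Evaluation

A reference stream (e.g. motion capture) lives in its own frame; the rigid
calibration transform is estimated from the first `n_calib = 50` static
frames: the rotation as the eigenvector quaternion average (principal
eigenvector of the 4×4 accumulation matrix Q·Qᵀ) of the per-frame relative
rotations, the translation as the arithmetic mean of the per-frame offsets.
Pose error is split into the minimum rotation angle (degrees) and the
Euclidean translation distance (mm).  Gait-cycle detection is scored by
greedy one-to-one matching of terminating heel-strikes (tolerance: half the
median reference cycle time), yielding precision, recall and an F1 defined
as the *arithmetic* mean `0.5·(P + R)`; the conventional harmonic F1 is
provided separately as `f1_harmonic`.

## Synthetic scenes

The generator animates the same rigid models through a scripted
treadmill-style gait and renders back-view depth maps, so every pipeline
stage can be validated by parameter recovery:

* **Kinematics.**  Stance feet translate backward at belt speed
  `2·step_length/cycle_time`; swing feet return along a smooth monotone
  profile with a sinusoidal clearance arc (30 mm) and a plantarflexion pulse
  (15°) in early swing; the shank oscillates sagittally (±12°); the feet are
  yawed outward by a foot-progression angle (default 7°, the population
  norm).  Left and right are half a cycle out of phase and laterally offset
  by the step width, so at every heel-strike the inter-foot displacement
  equals the scripted step length and width *exactly* — these are the
  analytic per-cycle truths, and HS/TO times fall on exact frame boundaries
  when `fps·cycle_time` is an integer.  Each sequence starts with a static
  standing lead-in (0.6 s) in a wider calibration stance (≥170 mm) that
  blends into the first step — the tracker initializes from this stance, as
  the experimental protocol prescribes.
* **Rendering.**  Z-buffer rasterization of surface samples (1.2 mm spacing,
  ≥1 sample per pixel at the near range for the half-resolution intrinsics)
  over an analytic floor, with back-face *and* grazing-incidence culling
  (surfaces beyond ≈81° incidence return nothing, as with real active-stereo
  depth cameras).  Optional per-pixel Gaussian depth noise, random dropout,
  and near-range row fragmentation emulate sensor artifacts.  Per-pixel
  truth masks partition limb pixels exactly into foot/shank per side.

What the generator does **not** emulate: clothing and soft-tissue
deformation, depth-dependent noise models, motion blur, multi-path and edge
artifacts, turning motion, or any deviation of the walker's true shape from
the rigid model.  Passing recovery tests therefore demonstrates the
correctness and conditioning of the algorithm, not its accuracy on real
recordings, where model mismatch (shoe shape, clothing) and sensor effects
dominate the error budget.

## Numerical choices and degenerate inputs

* Distance functions are total: any finite point yields a finite
  non-negative distance; both are 1-Lipschitz.
* An empty foot (or shank) observation zeroes that part's distance and
  silhouette terms and flags the breakdown; a fully empty observation skips
  optimization and the Kalman filter coasts.
* A first frame without two separated limb groups aborts with a clear error
  — tracking must start from the standing calibration stance.
* The quaternion average fixes its sign to a non-negative scalar part;
  `angular_distance` clips the trace argument against rounding.
* Step width is clamped at zero when rounding makes
  `‖d_step‖ < step_length`.
* K-means left/right ties break by previous-frame proximity, else input
  order — deterministic either way.

## Problem sizes

The test suite and the acceptance script run at half the default camera
resolution (320×180, fx = fy = 230) with sequences of 90–210 frames at
50 fps: the smallest scale at which limb surfaces are dense enough for the
clustering defaults while a full synth→track→gait experiment completes in a
couple of minutes.  Results at full resolution are qualitatively identical
(the renderer guarantees ≥1 sample per pixel at either scale).

## Known limitations

* **Yaw observability.**  Viewed exactly from behind, the heel wall is
  rotationally symmetric about the vertical axis, so the foot's yaw is
  informed only by the silhouette key points — it is the weakest pose
  component, drifting several degrees during swing.  A foot-progression
  (toe-out) angle turns a side wall into view and restores observability;
  this is why the calibration stance of the underlying experimental design
  splays the feet.  Large toe-out also creates a mirror-symmetric local
  minimum (the U-channel is laterally symmetric) that the silhouette term
  must break.
* Turning motion (left/right swap in the image) is out of scope; limbs are
  identified purely by horizontal image position.
* The expansion sweep's one-pass stopping rule can stop below the true ankle
  row when the foot is strongly plantarflexed (toe-off), as the cost is not
  monotone along the line there.
* Runtime is ~0.3 s per frame at test scale in pure Python/NumPy; the design
  favors clarity over the real-time budget of an embedded tracker.
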