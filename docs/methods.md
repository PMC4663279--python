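# Methods

This note documents the models, conventions, numerical choices and
limitations behind `echogate`.

## Coordinate frames and conventions

Four frames: ultrasound image plane **US** (z = 0), optical marker tool
**T** rigidly mounted on the probe, optical sensor **S**, and world **W**
(the treatment-room / scanner frame; z_W along the bore, x_W horizontal
transverse, y_W vertical). A pixel (u, v) is lifted to
(s·u, s·v, 0) mm with the isotropic scale s (mm/px — identical for both
image axes, as a phased-array sector geometry implies) and chained through
`T_{US→T}`, the streamed pose `T_{T→S}`, and `T_{S→W}`. Internally all
lengths are mm, times ms, angles radians. The image origin is the
transducer apex at pixel (0, 0); u is lateral, v is depth. The 60° sector
angle is simulator metadata only.

Rigid transforms are stored as orthonormal matrices (validated at
construction, re-projected onto SO(3) via SVD when numerical drift is
detected, rejected above 1e-6) and parameterized for optimization as
axis-angle vectors, avoiding gimbal degeneracies in Levenberg–Marquardt.
Pose streams are interpolated linearly in translation and by slerp in
rotation; for a probe oscillating at respiratory rates sampled at 10 Hz the
interpolation error is ≲0.03 mm, below the optical tracker's own noise.

## Freehand wire-phantom calibration

The forward model intersects each phantom wire (a 3D segment in world
coordinates) with the image plane under the current chain; detections are
bright wire cross-sections in pixels. Residuals are computed in world
space as the perpendicular component of (lifted detection − wire line).
A wire constrains a point only up to sliding along itself, so the
point-to-line distance carries exactly the two equations a detection
provides without inventing an in-plane correspondence.

The joint solve estimates 13 parameters (6 of `T_{US→T}` + log-scale + 6 of
`T_{S→W}`) with `scipy.optimize.least_squares(method="lm")`, convergence
tolerance 1e-10 and a 200-iteration budget. The scale is optimized as its
logarithm to keep it positive. The problem is non-convex in the
image-plane orientation: a single identity start can converge to a local
minimum for strongly rotated mounting geometries. The solver therefore
runs a deterministic coarse grid of 14 initial orientations (identity,
±90°/180° about each axis, three compound rotations), scale seeded from
the nominal imaging depth (140 mm / image height), keeping the lowest-cost
solution; with noiseless data the grid search stops as soon as a start
reaches a numerically zero cost. An explicit user seed replaces the grid.
`T_{S→W}` may alternatively be fixed from the table-position calibration
(`fix_t_s_w`), reducing the solve to 7 parameters.

Degeneracy guards: poses must exercise rotations about at least two axes
(second singular value of the relative rotation vectors > 1e-4 rad),
otherwise the solve is refused; the closed-form absolute-orientation fit
(Kabsch SVD) refuses <3 pairs or collinear configurations. Unlabeled
detections are assigned to the nearest wire after a coarse fit, iterated at
most 5 times.

Evaluation follows the standard protocols: *accuracy* is the mean (± SD)
distance of reconstructed point-phantom positions from truth; *precision*
projects fixed test pixels through each of the repeated calibrations and
averages the per-point scatter about the centroid. The synthetic sessions
verify the estimators, not any hardware-specific printed value: real
accuracy figures bundle probe geometry and speed-of-sound effects that a
geometric simulation cannot reproduce.

## Condensation contour tracker

The initial contour snaps M points (default 32) to the strongest radial
brightness-gradient locus along rays from a seed, failing on featureless
images. The tracker state is a 5-parameter similarity (tx, ty, θ, sx, sy)
applied about the base contour centroid. The measurement likelihood is
`exp(λ · mean |∇I · n̂|)` sampled at K = 32 points along the transformed
contour with outward normals n̂; it is zero when the contour lies fully
outside the frame, and being gradient-based it is invariant to global
additive brightness offsets. λ (default 30) sets the sharpness of the
posterior: the default is chosen so that, for images with order-unity edge
contrast, a 1-pixel contour offset changes the weight by a few e-folds;
for other intensity scales λ should be scaled inversely with the edge
gradient magnitude. Per step: systematic resampling (stable particle
order at ties), Gaussian diffusion with configurable SDs (defaults
1.5 px / 1.5 px / 0.01 rad / 0.005 / 0.005), re-weighting, normalization;
the effective sample size is reported per frame. The dynamics are pure
diffusion — there is no velocity model — so a small systematic lag
proportional to target speed and to 1/λ is expected and observed.

## Gating pipeline

* **Peak detection.** Prominence-based candidate maxima (default threshold
  25% of the signal range), each refined by fitting a Gaussian-plus-baseline
  to the samples within ±25% of the median cycle length and taking the
  fitted mean; fits that wander outside their window fall back to the raw
  sample maximum.
* **Clock offset** between the motion-monitoring computer and the scanner
  is the mean of (a − b) over nearest-neighbour peak pairs matched within
  half the median period, reported with its SD.
* **Gate tags** are the offset-corrected peaks clipped to the event span;
  events are never modified.
* **Phase sorting** divides each inter-tag interval into `n_phases` equal
  half-open bins `[g_i + kΔ, g_i + (k+1)Δ)`. Events before the first or at/
  after the last tag are discarded and counted, never wrapped.
* **Reconstruction** is a direct 3D histogram of event positions (default
  2 mm voxels on a ±60 mm grid). The scanner's point-spread function is
  applied at event-generation time, so the histogram plays the role of the
  tomographic image for the axial-profile question; sinogram-domain
  reconstruction, attenuation, scatter and randoms are out of scope.
* **Registration** fits each phase's axial profile with a 1D Gaussian and
  shifts phases along z by (reference mean − phase mean). The default path
  shifts the *event* z-coordinates before the final histogram (sub-voxel
  exact); an image-space variant with linear interpolation serves
  already-gridded data. The reference is the first phase after the
  maximum inhale peak; because phases are pooled across cycles before
  registration, this is pooled phase 0.
* **FWHM** comes from an unweighted least-squares Gaussian fit
  (moment-initialized, tolerance 1e-10) of the z-profile at the transverse
  voxel of maximum summed activity; FWHM = 2√(2 ln 2)·σ. Fitting
  voxel-sampled profiles carries the usual binning variance Δ²/12 on σ²
  (a 5.2 mm profile reads ≈5.38 mm at Δ = 2 mm) — the same estimator
  behaviour as fitting reconstructed scanner images, which is the
  procedure this pipeline mirrors. The ungated profile is additionally
  summarized by its full width at 10% of maximum, the relevant measure for
  motion smearing, whose plateau-like profile a Gaussian does not describe.

## Simulators and study conditions

The generators emulate an in-bore bench: a point source on a respiratory
motion platform, a rubber ball rigidly attached to it in a water tank, a
probe (optionally riding a second platform), a pressure-belt surrogate and
an optical tracker.

* Trajectories: Lujan-type `z(t) = A cos⁴(πt/T)` (peak-to-peak A, heavy
  end-exhale dwell, inhale = maximum) and sinusoid `(A/2)cos(2πt/T)`;
  `kind="table"` interpolates any recorded trace. Patient-like inputs can
  be emulated by a jittered cos⁴ table; no claim is made that this matches
  any particular recorded patient trajectory.
* List-mode events: homogeneous Poisson times (source half-life ≫
  acquisition), position = trajectory + isotropic Gaussian with the static
  resolution (default 5.2 mm FWHM). Default conditions for gated runs:
  1000 events/s, ≥600 s, 8 phases — at these sizes the FWHM estimate's
  seed-to-seed scatter is ≈0.02 mm and a full run takes well under a
  minute. The moving-probe scenario uses the bench geometry: target
  40 mm peak-to-peak along z_W at T = 3 s, probe 20 mm peak-to-peak along
  x_W at T = 4 s, 12 min, poses at 10 Hz with 0.25 mm / 1 mrad noise.
  The surrogate in gated runs carries noise at 5% of the motion amplitude,
  representative of a belt signal; peak-time jitter then stays well below
  the ~100 ms agreement window typical between independent monitoring
  systems.
* Calibration sessions: 64 frames (10 repeat sessions for precision
  studies), probe poses drawn with broad polar/azimuthal spread about the
  phantom, labeled detections from the forward model plus Gaussian pixel
  noise. Pose sampling and detection noise use independent RNG substreams
  so the noise level can be varied at fixed geometry.
* All generators are seed-deterministic: identical configuration and seed
  give identical bytes.

What the simulators do *not* model: ultrasound wave physics (frames are
speckled backgrounds with a bright rim, sufficient for an edge-based
tracker), scanner dead time, randoms/scatter, attenuation, and the
hardware effects (probe geometry, speed-of-sound error) that dominate real
calibration accuracy. Passing tests therefore validate the estimators and
the geometry chain, not any scanner-specific absolute accuracy.

## Known limitations

* The histogram reconstruction slightly *under*-reports the gated width
  compared with filtered back-projection plus manual phase registration
  (no reconstruction ringing, registration exact to the fitted centroid);
  gated widths land a few percent below values measured on a real
  scanner's images for the same motion.
* Phase sorting is strictly phase-based; amplitude-based sorting and the
  use of all 10 tracking parameters of a two-plane probe are not
  implemented.
* The tracker has no velocity model and a single image plane; out-of-plane
  target motion appears only as scale/brightness changes.
* The image-space registration path uses linear interpolation and may lose
  a sub-percent of counts at grid borders; the default event-space path
  conserves counts exactly (off-grid events are counted and reported).
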