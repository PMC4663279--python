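"""Synthetic generators for every input the pipeline consumes.

The generators emulate the bench setups the toolkit targets: a radioactive
point source on a respiratory motion platform inside a PET bore (static
point-source resolution 5.2 mm FWHM), a rubber ball imaged by a tracked
ultrasound probe, a pressure-belt surrogate, an optical tracker streaming
probe poses at ~10 Hz, and freehand calibration sessions of a multi-cross
wire phantom imaged from 64 diverse poses.

Respiratory trajectories follow the Lujan-type convention: the cosine^4
pattern is z(t) = A cos^4(pi (t - t0) / T) with peak-to-peak amplitude A and
period T, dwelling at end-exhale (z = 0); inhale is the maximum.  The
sinusoid is z(t) = (A/2) cos(2 pi (t - t0) / T), again peak-to-peak A with
inhale peaks at t0 + k T.

All generators are seed-deterministic: same configuration + seed, same
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import (CalibrationObservation, WirePhantom,
                          expected_wire_points)
from .gating import ListModeStream, TrackingSignal
from .tracking import TrackState, USFrame
from .transforms import (ImageToProbeTransform, PoseStream, RigidTransform3D,
                         world_to_image)

__all__ = [
    "MotionTrajectory",
    "SimConfig",
    "position",
    "simulate_listmode",
    "simulate_surrogate",
    "simulate_probe_poses",
    "simulate_us_frames",
    "simulate_calibration_session",
    "occupancy_density",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class MotionTrajectory:
    """1D respiratory trajectory along a world axis.

    ``amplitude_mm`` is peak-to-peak.  ``kind`` is one of ``sinusoid``,
    ``cos4`` or ``table`` (piecewise-linear interpolation of a recorded
    (t, z) trace).  Inhale peaks sit at ``phase_offset_ms + k * period_ms``
    for the analytic kinds.
    """

    kind: str = "cos4"
    amplitude_mm: float = 30.0
    period_ms: float = 4000.0
    axis: tuple = (0.0, 0.0, 1.0)
    phase_offset_ms: float = 0.0
    table_t_ms: np.ndarray | None = None
    table_z_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "cos4", "table"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.amplitude_mm < 0 or self.period_ms <= 0:
            raise ValueError("need amplitude >= 0 and period > 0")
        a = np.asarray(self.axis, float)
        object.__setattr__(self, "axis", tuple(a / np.linalg.norm(a)))
        if self.kind == "table":
            t = np.asarray(self.table_t_ms, float)
            z = np.asarray(self.table_z_mm, float)
            if t.ndim != 1 or t.shape != z.shape or len(t) < 2:
                raise ValueError("table trajectory needs matching t/z arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError("table times must be strictly increasing")
            object.__setattr__(self, "table_t_ms", t)
            object.__setattr__(self, "table_z_mm", z)

    def displacement(self, t_ms) -> np.ndarray:
        """Scalar axial displacement z(t) in mm."""
        t = np.asarray(t_ms, float)
        tau = t - self.phase_offset_ms
        if self.kind == "cos4":
            return self.amplitude_mm * np.cos(np.pi * tau / self.period_ms) ** 4
        if self.kind == "sinusoid":
            return (self.amplitude_mm / 2.0) * np.cos(
                2.0 * np.pi * tau / self.period_ms)
        lo, hi = self.table_t_ms[0], self.table_t_ms[-1]
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError("table trajectory queried outside its span")
        return np.interp(t, self.table_t_ms, self.table_z_mm)

    def position(self, t_ms) -> np.ndarray:
        """3D world displacement vector(s) at time(s) t (mm)."""
        z = self.displacement(t_ms)
        ax = np.asarray(self.axis)
        return np.multiply.outer(z, ax) if np.ndim(z) else z * ax


def position(traj: MotionTrajectory, t_ms):
    return traj.position(t_ms)


def occupancy_density(traj: MotionTrajectory, z_grid_mm: np.ndarray,
                      n_time: int = 200_001) -> np.ndarray:
    """Time-occupancy density of the axial position over one period.

    Numerically accumulates time-at-position on ``z_grid_mm`` (uniform
    grid); for cos4 this shows the characteristic heavy end-exhale dwell.
    Normalized to integrate to 1 over the grid.
    """
    t = np.linspace(0.0, traj.period_ms, n_time, endpoint=False)
    z = traj.displacement(t)
    dz = z_grid_mm[1] - z_grid_mm[0]
    edges = np.concatenate([z_grid_mm - dz / 2, [z_grid_mm[-1] + dz / 2]])
    h, _ = np.histogram(z, edges)
    return h / (h.sum() * dz)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition conditions for the list-mode generator.

    ``psf_fwhm_mm`` is the scanner's static point-source resolution applied
    as an isotropic Gaussian smearing of each event position.
    """

    event_rate_hz: float = 1000.0
    psf_fwhm_mm: float = 5.2
    duration_ms: float = 600_000.0
    seed: int = 0
    source_center_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.event_rate_hz <= 0:
            raise ValueError("event rate must be > 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_listmode(traj: MotionTrajectory, cfg: SimConfig) -> ListModeStream:
    """Point-source list-mode acquisition.

    Event times follow a homogeneous Poisson process (the source half-life
    vastly exceeds the acquisition, so the rate is constant); each event
    position is the instantaneous source position plus an isotropic Gaussian
    displacement with the configured PSF width.  No gate tags are attached.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.poisson(cfg.event_rate_hz * cfg.duration_ms / 1000.0))
    t = np.sort(rng.uniform(0.0, cfg.duration_ms, n))
    sigma = cfg.psf_fwhm_mm * FWHM_TO_SIGMA
    xyz = (np.asarray(cfg.source_center_mm, float)
           + traj.position(t)
           + rng.normal(0.0, sigma, (n, 3)))
    return ListModeStream(times_ms=t, positions_mm=xyz,
                          gate_tags_ms=np.empty(0))


def simulate_surrogate(
    traj: MotionTrajectory,
    sample_rate_hz: float = 25.0,
    duration_ms: float | None = None,
    noise_sd: float = 0.0,
    lag_ms: float = 0.0,
    seed: int = 0,
    gain: float = 1.0,
    offset: float = 0.0,
) -> TrackingSignal:
    """Pressure-belt-like 1D surrogate: a monotone (affine) function of the
    axial displacement, in arbitrary units, with additive noise and a fixed
    acquisition lag."""
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be > 0")
    if duration_ms is None:
        duration_ms = 5 * traj.period_ms
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sample_rate_hz
    t = np.arange(0.0, duration_ms, dt)
    v = gain * traj.displacement(t - lag_ms) + offset
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, len(t))
    return TrackingSignal(times_ms=t, values=v)


def simulate_probe_poses(
    probe_traj: MotionTrajectory,
    duration_ms: float,
    base_pose: RigidTransform3D | None = None,
    rate_hz: float = 10.0,
    translation_noise_sd_mm: float = 0.0,
    rotation_noise_sd_rad: float = 0.0,
    displacement_rotation: np.ndarray | None = None,
    seed: int = 0,
) -> PoseStream:
    """Optical-tracker pose stream of a probe riding a motion platform.

    The probe translates along ``probe_traj`` relative to ``base_pose``;
    isotropic Gaussian noise perturbs the reported translation and rotation
    (axis-angle), emulating the optical system's finite accuracy.

    ``displacement_rotation`` rotates the trajectory displacement into the
    frame the poses are reported in (pass the world-to-sensor rotation when
    the trajectory is specified along a world axis but poses are streamed
    in sensor coordinates); identity by default.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    base = base_pose or RigidTransform3D.identity()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms, 1000.0 / rate_hz)
    disp = probe_traj.position(t)
    if displacement_rotation is not None:
        disp = disp @ np.asarray(displacement_rotation, float).T
    poses = []
    for i, ti in enumerate(t):
        tr = base.translation + disp[i]
        R = base.rotation
        if translation_noise_sd_mm > 0:
            tr = tr + rng.normal(0.0, translation_noise_sd_mm, 3)
        if rotation_noise_sd_rad > 0:
            R = Rotation.from_rotvec(
                rng.normal(0.0, rotation_noise_sd_rad, 3)).as_matrix() @ R
        poses.append(RigidTransform3D(R, tr))
    return PoseStream(times_ms=t, poses=poses)


@dataclass(frozen=True)
class ImageSpec:
    """Pixel geometry of the simulated ultrasound frames.

    The sector angle (60 degrees for the phased array emulated here) is
    metadata used to bound plausible wire detections; frames themselves are
    rectangular grids with the transducer apex at pixel (0, 0) of the top
    row center.
    """

    width_px: int = 96
    height_px: int = 96
    scale_mm_per_px: float = 1.5
    sector_angle_deg: float = 60.0

    @property
    def depth_mm(self) -> float:
        return self.height_px * self.scale_mm_per_px


def simulate_us_frames(
    traj: MotionTrajectory,
    probe_poses: PoseStream,
    calib_truth: tuple,
    frame_rate_hz: float = 15.0,
    duration_ms: float | None = None,
    image: ImageSpec = ImageSpec(),
    ball_radius_px: float = 14.0,
    rim_width_px: float = 2.0,
    rim_brightness: float = 1.0,
    speckle_sigma: float = 0.0,
    background: float = 0.12,
    target_offset_mm=(0.0, 0.0, 0.0),
    seed: int = 0,
):
    """Render ball-in-water-tank frames as seen by a (possibly moving) probe.

    The target ball center in world coordinates is ``target_offset_mm`` plus
    the trajectory displacement; it is mapped into the image plane through
    the inverted calibration chain at each frame time.  Frames consist of a
    speckled background (multiplicative gamma noise) and a bright Gaussian
    rim at the ball radius — the brightness-edge structure a contour tracker
    locks onto.

    Returns ``(frames, truth_states, truth_centers_px)`` where
    ``truth_states`` hold the image-plane translation of the ball relative
    to the first frame.
    """
    t_us_t, t_s_w = calib_truth
    if duration_ms is None:
        duration_ms = probe_poses.span_ms[1]
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_ms, 1000.0 / frame_rate_hz)
    uu, vv = np.meshgrid(np.arange(image.width_px), np.arange(image.height_px),
                         indexing="xy")
    frames, states, centers = [], [], []
    c0 = None
    for ti in times:
        pose = probe_poses.interpolate(ti)
        world = np.asarray(target_offset_mm, float) + traj.position(ti)
        u, v, z_off = world_to_image(world, t_us_t, pose, t_s_w)
        if not (0 <= u < image.width_px and 0 <= v < image.height_px):
            raise ValueError(
                f"ball center left the image sector at t={ti:.0f} ms "
                f"(u={u:.1f}, v={v:.1f})")
        r = np.hypot(uu - u, vv - v)
        img = background + rim_brightness * np.exp(
            -0.5 * ((r - ball_radius_px) / rim_width_px) ** 2)
        if speckle_sigma > 0:
            # multiplicative speckle: unit-mean gamma field
            k = 1.0 / speckle_sigma**2
            img = img * rng.gamma(k, 1.0 / k, img.shape)
        frames.append(USFrame(image=img.astype(np.float32), timestamp_ms=ti))
        if c0 is None:
            c0 = (u, v)
        states.append(TrackState(tx=u - c0[0], ty=v - c0[1],
                                 theta=0.0, sx=1.0, sy=1.0))
        centers.append((u, v))
    return frames, states, np.asarray(centers)


# ---------------------------------------------------------------------------
# composed bench scenario: moving probe, moving target


def perturb_calibration(
    t_us_t: ImageToProbeTransform,
    rng,
    translation_sd_mm: float = 0.7,
    rotation_sd_rad: float = 0.004,
    scale_rel_sd: float = 0.005,
) -> ImageToProbeTransform:
    """Perturb an image-to-probe transform at the scale of a realistic
    calibration reproducibility (~1 mm point scatter at depth)."""
    rv = Rotation.from_matrix(t_us_t.rigid.rotation).as_rotvec()
    rigid = RigidTransform3D.from_rotvec(
        rv + rng.normal(0.0, rotation_sd_rad, 3),
        t_us_t.rigid.translation + rng.normal(0.0, translation_sd_mm, 3))
    return ImageToProbeTransform(rigid,
                                 t_us_t.scale * (1 + rng.normal(0, scale_rel_sd)))


def moving_probe_scenario(
    duration_ms: float = 720_000.0,
    target_pp_mm: float = 40.0,
    target_period_ms: float = 3000.0,
    probe_pp_mm: float = 20.0,
    probe_period_ms: float = 4000.0,
    frame_rate_hz: float = 15.0,
    pose_rate_hz: float = 10.0,
    pose_translation_noise_mm: float = 0.25,
    pose_rotation_noise_rad: float = 0.001,
    image: ImageSpec | None = None,
    truth: tuple | None = None,
    seed: int = 0,
):
    """In-bore bench with the probe riding its own motion platform.

    The target oscillates along the scanner axis (z_W, peak-to-peak
    ``target_pp_mm``); the probe is translated sinusoidally along the
    horizontal x_W axis, orthogonal to the target motion.  The base probe
    pose is constructed so the target sits mid-sector, and the optical
    stream carries realistic pose noise.

    Returns a dict with the trajectories, pose stream, exact per-frame
    contour states (image-plane translation of the target), the anchor
    pixel, and the ground-truth calibration.
    """
    if truth is None:
        truth = default_calibration_truth()
    t_us_t, t_s_w = truth
    if image is None:
        image = ImageSpec(width_px=128, height_px=467,
                          scale_mm_per_px=t_us_t.scale)
    target = MotionTrajectory(kind="sinusoid", amplitude_mm=target_pp_mm,
                              period_ms=target_period_ms, axis=(0, 0, 1))
    probe = MotionTrajectory(kind="sinusoid", amplitude_mm=probe_pp_mm,
                             period_ms=probe_period_ms, axis=(1, 0, 0))
    # base pose: plane mid-sector anchored on the target's mid position,
    # image depth axis looking along the world z so axial motion stays
    # in-plane
    R = Rotation.from_euler("x", np.pi / 2).as_matrix()
    anchor_plane = np.array([image.width_px / 2 * image.scale_mm_per_px,
                             image.depth_mm * 0.5, 0.0])
    target_mid = np.array([0.0, 0.0, target_pp_mm / 2])
    plane_to_world = RigidTransform3D(R, target_mid - R @ anchor_plane)
    base_pose = t_s_w.invert() @ plane_to_world @ t_us_t.rigid.invert()

    w2s = t_s_w.invert().rotation  # probe platform moves along world axes
    poses = simulate_probe_poses(
        probe, duration_ms + 2000.0 / pose_rate_hz, base_pose=base_pose,
        rate_hz=pose_rate_hz,
        translation_noise_sd_mm=pose_translation_noise_mm,
        rotation_noise_sd_rad=pose_rotation_noise_rad,
        displacement_rotation=w2s, seed=seed)

    # exact per-frame image position of the target (what an ideal contour
    # tracker would report)
    times = np.arange(0.0, duration_ms, 1000.0 / frame_rate_hz)
    centers = []
    for ti in times:
        pose_exact = RigidTransform3D(base_pose.rotation,
                                      base_pose.translation
                                      + w2s @ probe.position(ti))
        u, v, _ = world_to_image(target.position(ti), t_us_t, pose_exact,
                                 t_s_w)
        centers.append((u, v))
    centers = np.asarray(centers)
    anchor = centers[0]
    states = [TrackState(tx=u - anchor[0], ty=v - anchor[1])
              for u, v in centers]
    return {
        "target": target,
        "probe": probe,
        "poses": poses,
        "base_pose": base_pose,
        "times_ms": times,
        "states": states,
        "anchor_px": anchor,
        "truth": truth,
        "image": image,
    }


# ---------------------------------------------------------------------------
# calibration sessions


def _session_pose(rng, phantom_center, t_us_t, t_s_w, image: ImageSpec,
                  polar_range_rad=(np.radians(-25), np.radians(25)),
                  azim_range_rad=(-np.pi, np.pi)):
    """Draw one probe pose whose image plane cuts through the phantom.

    The desired placement of the image plane in the world is sampled first
    (plane mid-depth anchored near the phantom center with a broad polar and
    azimuthal spread), then converted to the tool pose the optical tracker
    would have reported, T_{T->S} = T_{S->W}^-1 . P . T_{US->T,rigid}^-1.
    """
    polar = rng.uniform(*polar_range_rad)
    azim = rng.uniform(*azim_range_rad)
    roll = rng.uniform(-np.pi / 6, np.pi / 6)
    R = Rotation.from_euler("zyx", [azim, polar, roll]).as_matrix()
    anchor_plane = np.array([image.width_px / 2 * image.scale_mm_per_px,
                             image.depth_mm * 0.5, 0.0])
    jitter = rng.uniform(-12.0, 12.0, 3)
    t = phantom_center + jitter - R @ anchor_plane
    plane_to_world = RigidTransform3D(R, t)
    return t_s_w.invert() @ plane_to_world @ t_us_t.rigid.invert()


def default_calibration_truth() -> tuple:
    """A representative ground-truth transform pair for synthetic sessions:
    0.30 mm/px scale, offset probe mounting, non-trivial rotations."""
    t_us_t = ImageToProbeTransform(
        RigidTransform3D.from_rotvec([0.3, -0.2, 0.5], [10.0, -5.0, 20.0]),
        0.30)
    t_s_w = RigidTransform3D.from_rotvec([0.1, 0.4, -0.25],
                                         [120.0, -40.0, 350.0])
    return t_us_t, t_s_w


def simulate_calibration_session(
    phantom: WirePhantom,
    truth: tuple | None = None,
    n_frames: int = 64,
    detection_noise_px: float = 0.0,
    image: ImageSpec | None = None,
    seed: int = 0,
    max_retries: int = 200,
):
    """Generate one freehand calibration session: 64 frames by default, each
    a probe pose plus labeled wire detections with Gaussian pixel noise.

    Returns ``(observations, truth)``; frames with no wire crossing the
    imaged sector are redrawn up to ``max_retries`` times.
    """
    if truth is None:
        truth = default_calibration_truth()
    t_us_t, t_s_w = truth
    if image is None:
        image = ImageSpec(width_px=128, height_px=467,
                          scale_mm_per_px=t_us_t.scale)
    # independent substreams so detection noise never perturbs the poses
    rng, rng_noise = [np.random.default_rng(s)
                      for s in np.random.SeedSequence(seed).spawn(2)]
    center = phantom.wires.mean(axis=(0, 1))
    bounds = (0.0, image.width_px, 0.0, image.height_px)
    observations = []
    for fid in range(n_frames):
        for attempt in range(max_retries):
            pose = _session_pose(rng, center, t_us_t, t_s_w, image)
            uv, ids = expected_wire_points(phantom, pose, (t_us_t, t_s_w),
                                           image_bounds=bounds)
            if len(uv) >= 1:
                break
        else:
            raise RuntimeError("could not find a pose intersecting the phantom")
        if detection_noise_px > 0:
            uv = uv + rng_noise.normal(0.0, detection_noise_px, uv.shape)
        observations.append(
            CalibrationObservation(frame_id=fid, pose=pose,
                                   points=uv, wire_ids=ids))
    return observations, truth
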