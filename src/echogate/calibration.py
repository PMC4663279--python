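"""Freehand ultrasound probe calibration against a multi-cross wire phantom.

Two transforms of the image-to-world chain are unknown and must be solved
for: the image-plane-to-marker transform ``T_{US->T}`` (including the
mm-per-pixel scale) and the sensor-to-room transform ``T_{S->W}``.  The
phantom is a set of thin nylon wires with precisely known world geometry;
each bright wire cross-section detected in an ultrasound image constrains
the chain, and imaging the phantom from many probe positions and
orientations (all six degrees of freedom exercised) makes the joint
13-parameter problem identifiable.

Residuals are formulated in world space as the perpendicular displacement of
each lifted detection from its wire line.  This is deliberate: a wire
constrains a point only up to sliding along the wire, so a point-to-line
distance captures exactly the information a detection carries (two
equations per bright point) without inventing a correspondence along the
wire.  The joint solve uses Levenberg-Marquardt on a minimal axis-angle
parameterization of the two rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .transforms import ImageToProbeTransform, RigidTransform3D, image_to_world

__all__ = [
    "WirePhantom",
    "CalibrationObservation",
    "CalibrationResult",
    "DegenerateConfigurationError",
    "RankDeficiencyError",
    "ConvergenceError",
    "fit_rigid_from_correspondences",
    "expected_wire_points",
    "calibrate_freehand",
    "reconstruction_accuracy",
    "calibration_precision",
]


class DegenerateConfigurationError(ValueError):
    """Too few or geometrically degenerate correspondences."""


class RankDeficiencyError(ValueError):
    """Probe poses lack the rotational diversity needed for a unique solve."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the requested tolerance."""


# ---------------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class WirePhantom:
    """Wires clamped between two parallel plates, in world coordinates.

    ``wires`` is an (n, 2, 3) array of segment endpoints in mm.  The default
    geometry has 29 wires spanning plates 80 mm apart, arranged in a crossing
    pattern so that an image plane cutting the phantom sees an identifiable
    constellation of bright points.
    """

    wires: np.ndarray
    plate_separation_mm: float = 80.0

    def __post_init__(self) -> None:
        w = np.asarray(self.wires, float)
        if w.ndim != 3 or w.shape[1:] != (2, 3):
            raise ValueError("wires must be (n, 2, 3)")
        if np.any(np.linalg.norm(w[:, 0] - w[:, 1], axis=1) < 1e-9):
            raise ValueError("wire endpoints must be distinct")
        object.__setattr__(self, "wires", w)

    @property
    def n_wires(self) -> int:
        return len(self.wires)

    @classmethod
    def default_cross_wire(cls, center=(0.0, 0.0, 0.0)) -> "WirePhantom":
        """29-wire crossing pattern between plates 80 mm apart.

        Wires run between plates at x = +/-40 mm.  Straight wires are
        parallel to the x-axis at staggered depth/height positions;
        interleaved diagonal wires tilt in y and z so that neighbouring
        wires cross, which is what breaks the sliding ambiguity of a single
        straight wire.
        """
        c = np.asarray(center, float)
        half = 40.0
        wires = []
        # five depth levels, alternating straight / diagonal groups
        levels = np.linspace(-30.0, 30.0, 5)
        for i, z in enumerate(levels):
            for j, y in enumerate(np.linspace(-25.0, 25.0, 6)):
                k = len(wires)
                if k >= 29:
                    break
                if (i + j) % 2 == 0:
                    p0 = np.array([-half, y, z])
                    p1 = np.array([half, y, z])
                else:  # diagonal: shear in y and z across the plates
                    dy = 8.0 if j % 2 == 0 else -8.0
                    dz = 6.0 if i % 2 == 0 else -6.0
                    p0 = np.array([-half, y - dy / 2, z - dz / 2])
                    p1 = np.array([half, y + dy / 2, z + dz / 2])
                wires.append(np.stack([p0 + c, p1 + c]))
        # cap to exactly 29 with a long diagonal brace
        wires = wires[:28]
        wires.append(np.stack([c + np.array([-half, -20.0, -28.0]),
                               c + np.array([half, 20.0, 28.0])]))
        return cls(np.stack(wires))

    def transformed(self, g: RigidTransform3D) -> "WirePhantom":
        """Phantom with all wire endpoints moved by the rigid transform g."""
        w = g.apply(self.wires.reshape(-1, 3)).reshape(self.wires.shape)
        return WirePhantom(w, self.plate_separation_mm)


@dataclass
class CalibrationObservation:
    """One ultrasound frame of the phantom with the simultaneous probe pose.

    ``points`` are the detected bright wire cross-sections in pixels,
    ``wire_ids`` their phantom-wire labels (or -1 when unlabeled).
    """

    frame_id: int
    pose: RigidTransform3D  # recorded T_{T->S}
    points: np.ndarray      # (k, 2) pixels
    wire_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ValueError("observation needs >=1 detected (u, v) point")
        if self.wire_ids is None:
            self.wire_ids = np.full(len(self.points), -1, dtype=int)
        else:
            self.wire_ids = np.asarray(self.wire_ids, dtype=int).reshape(-1)
            if len(self.wire_ids) != len(self.points):
                raise ValueError("one wire id per detected point")


@dataclass
class CalibrationResult:
    t_us_t: ImageToProbeTransform
    t_s_w: RigidTransform3D
    rms_mm: float
    residuals_mm: np.ndarray
    n_iterations: int = 0
    final_cost: float = 0.0
    converged: bool = True


# ---------------------------------------------------------------------------
# absolute orientation (sensor-to-room calibration)


def fit_rigid_from_correspondences(pairs) -> RigidTransform3D:
    """Least-squares rigid transform from (source, target) point pairs.

    Solves min_R,t sum ||R s_i + t - g_i||^2 with the closed-form
    SVD (Kabsch) solution.  Used for the sensor-to-room calibration, where
    a marker tool is placed at known table positions and observed at rest.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 3 pairs, or all sources (near-)collinear.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise DegenerateConfigurationError("need at least 3 point pairs")
    src = np.asarray([p[0] for p in pairs], float)
    tgt = np.asarray([p[1] for p in pairs], float)
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    s0, t0 = src - sc, tgt - tc
    # collinearity check on the source cloud
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateConfigurationError(
            "source points are collinear; rotation about the line is free")
    H = s0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform3D(R, tc - R @ sc)


# ---------------------------------------------------------------------------
# forward model


def _plane_crossings(wires_img: np.ndarray) -> tuple:
    """Parameters s in [0,1] where each segment crosses z = 0, or NaN."""
    z0, z1 = wires_img[:, 0, 2], wires_img[:, 1, 2]
    dz = z1 - z0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.abs(dz) > 1e-12, -z0 / dz, np.nan)
    ok = np.isfinite(s) & (s >= 0.0) & (s <= 1.0)
    return s, ok


def expected_wire_points(
    phantom: WirePhantom,
    probe_pose: RigidTransform3D,
    calib,
    image_bounds=None,
):
    """Predict the pixel positions of the wire cross-sections for one frame.

    Intersects each wire segment with the image plane z_US = 0 under the
    current chain and converts to pixels.  Wires not crossing the plane (or
    crossing outside ``image_bounds`` = (u_min, u_max, v_min, v_max), if
    given) are omitted.

    Returns ``(points, wire_ids)``: (k, 2) pixels and the phantom indices.
    """
    t_us_t = calib.t_us_t if isinstance(calib, CalibrationResult) else calib[0]
    t_s_w = calib.t_s_w if isinstance(calib, CalibrationResult) else calib[1]
    world_to_plane = (t_s_w @ probe_pose @ t_us_t.rigid).invert()
    w_img = world_to_plane.apply(phantom.wires.reshape(-1, 3)).reshape(-1, 2, 3)
    s, ok = _plane_crossings(w_img)
    ids = np.flatnonzero(ok)
    pts = (w_img[ids, 0] + s[ids, None] * (w_img[ids, 1] - w_img[ids, 0]))
    uv = pts[:, :2] / t_us_t.scale
    if image_bounds is not None:
        u0, u1, v0, v1 = image_bounds
        keep = (uv[:, 0] >= u0) & (uv[:, 0] <= u1) & \
               (uv[:, 1] >= v0) & (uv[:, 1] <= v1)
        uv, ids = uv[keep], ids[keep]
    return uv, ids


# ---------------------------------------------------------------------------
# joint freehand solve


def _pack(t_us_t: ImageToProbeTransform, t_s_w: RigidTransform3D,
          fixed: bool = False) -> np.ndarray:
    head = np.concatenate([
        t_us_t.rigid.as_rotvec(), t_us_t.rigid.translation,
        [np.log(t_us_t.scale)],
    ])
    if fixed:
        return head
    return np.concatenate([head, t_s_w.as_rotvec(), t_s_w.translation])


def _unpack(x: np.ndarray, fixed_t_s_w: RigidTransform3D | None = None):
    t_us_t = ImageToProbeTransform(
        RigidTransform3D.from_rotvec(x[0:3], x[3:6]), float(np.exp(x[6])))
    if fixed_t_s_w is not None:
        return t_us_t, fixed_t_s_w
    t_s_w = RigidTransform3D.from_rotvec(x[7:10], x[10:13])
    return t_us_t, t_s_w


def _pose_diversity(observations) -> float:
    """Second singular value of the relative-rotation vectors (rad)."""
    r0 = Rotation.from_matrix(observations[0].pose.rotation)
    rel = np.array([
        (Rotation.from_matrix(o.pose.rotation) * r0.inv()).as_rotvec()
        for o in observations
    ])
    if np.abs(rel).max() < 1e-9:
        return 0.0
    sv = np.linalg.svd(rel - rel.mean(axis=0), compute_uv=False)
    return float(sv[1]) if len(sv) > 1 else 0.0


def _wire_lines(phantom: WirePhantom):
    p0 = phantom.wires[:, 0]
    d = phantom.wires[:, 1] - phantom.wires[:, 0]
    return p0, d / np.linalg.norm(d, axis=1, keepdims=True)


def _residual_vectors(x, observations, p0, dhat, fixed_t_s_w):
    t_us_t, t_s_w = _unpack(x, fixed_t_s_w)
    out = []
    for obs in observations:
        pw = image_to_world(obs.points, t_us_t, obs.pose, t_s_w)
        a = p0[obs.wire_ids]
        n = dhat[obs.wire_ids]
        v = pw - a
        out.append(v - (v * n).sum(axis=1, keepdims=True) * n)
    return np.concatenate(out).ravel()


# deterministic multi-start grid: identity plus a coarse net of rotations of
# the image plane in the tool frame (the solve is non-convex in that block)
_INIT_ROTVECS = [np.zeros(3)]
for _ax in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])):
    for _ang in (np.pi / 2, np.pi, -np.pi / 2):
        _INIT_ROTVECS.append(_ax * _ang)
_INIT_ROTVECS += [
    np.array([np.pi / 2, np.pi / 2, 0.0]),
    np.array([0.0, np.pi / 2, np.pi / 2]),
    np.array([np.pi / 2, 0.0, np.pi / 2]),
]


def _assign_nearest_wires(observations, phantom, t_us_t, t_s_w):
    """Nearest-wire correspondence for unlabeled detections."""
    p0, dhat = _wire_lines(phantom)
    assigned = []
    for obs in observations:
        pw = image_to_world(obs.points, t_us_t, obs.pose, t_s_w)
        v = pw[:, None, :] - p0[None, :, :]
        proj = (v * dhat[None, :, :]).sum(axis=2, keepdims=True) * dhat[None, :, :]
        dist = np.linalg.norm(v - proj, axis=2)
        assigned.append(dist.argmin(axis=1))
    return assigned


def calibrate_freehand(
    observations,
    phantom: WirePhantom,
    init=None,
    fix_t_s_w: RigidTransform3D | None = None,
    nominal_depth_mm: float = 140.0,
    image_height_px: float | None = None,
    max_iterations: int = 200,
    tol: float = 1e-10,
    max_label_rounds: int = 5,
) -> CalibrationResult:
    """Jointly solve ``T_{US->T}`` (6 + scale) and ``T_{S->W}`` (6).

    Minimizes, by Levenberg-Marquardt, the summed squared point-to-wire
    distance of every detection lifted to world coordinates through the
    chain.  With ``fix_t_s_w`` the sensor-to-room transform is held at the
    value from the table-position calibration and only the 7 image-to-probe
    parameters are estimated.

    Parameters
    ----------
    observations
        Frames with recorded probe poses and detected wire points; poses
        must exercise rotations about at least two axes.
    init
        Optional ``(ImageToProbeTransform, RigidTransform3D)`` seed.  By
        default the scale is seeded from the nominal imaging depth
        (``nominal_depth_mm / image_height_px``, 140 mm depth) and the rigid
        blocks from a deterministic coarse grid of orientations, keeping the
        best converged start.
    """
    observations = list(observations)
    if len(observations) < 2:
        raise RankDeficiencyError("need >=2 observations with distinct poses")
    if _pose_diversity(observations) < 1e-4:
        raise RankDeficiencyError(
            "probe poses lack rotational diversity about a second axis; "
            "all six degrees of freedom of the probe must be exercised")

    labeled = all((o.wire_ids >= 0).all() for o in observations)
    p0, dhat = _wire_lines(phantom)

    scale0 = 0.3
    if image_height_px:
        scale0 = nominal_depth_mm / float(image_height_px)

    fixed = fix_t_s_w is not None
    if init is not None:
        starts = [_pack(init[0], init[1], fixed)]
    else:
        t0 = phantom.wires.mean(axis=(0, 1))
        starts = []
        for rv in _INIT_ROTVECS:
            t_us_t0 = ImageToProbeTransform(
                RigidTransform3D.from_rotvec(rv, np.zeros(3)), scale0)
            starts.append(_pack(t_us_t0, RigidTransform3D.identity(), fixed))
        # one extra start centring the chain on the phantom
        starts.append(_pack(ImageToProbeTransform.identity(scale0),
                            RigidTransform3D(np.eye(3), t0), fixed))

    def solve_from(x0, obs):
        return least_squares(
            _residual_vectors, x0, method="lm",
            args=(obs, p0, dhat, fix_t_s_w),
            xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iterations * 20)

    best = None
    for x0 in starts:
        obs = observations
        if not labeled:
            t_us_t0, t_s_w0 = _unpack(x0, fix_t_s_w)
            for _ in range(max_label_rounds):
                ids = _assign_nearest_wires(observations, phantom, t_us_t0,
                                            t_s_w0)
                obs = [CalibrationObservation(o.frame_id, o.pose, o.points, i)
                       for o, i in zip(observations, ids)]
                sol = solve_from(x0, obs)
                t_us_t0, t_s_w0 = _unpack(sol.x, fix_t_s_w)
                x0 = sol.x
        sol = solve_from(x0, obs)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16 * max(1, sum(len(o.points) for o in observations)):
            break

    if best is None or not best.success:
        raise ConvergenceError(
            f"Levenberg-Marquardt did not converge: "
            f"{getattr(best, 'message', 'no solution')}")

    t_us_t, t_s_w = _unpack(best.x, fix_t_s_w)
    res3 = best.fun.reshape(-1, 3)
    per_point = np.linalg.norm(res3, axis=1)
    return CalibrationResult(
        t_us_t=t_us_t, t_s_w=t_s_w,
        rms_mm=float(np.sqrt(np.mean(per_point**2))) if len(per_point) else 0.0,
        residuals_mm=per_point,
        n_iterations=int(best.nfev),
        final_cost=float(best.cost),
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# evaluation protocols


def reconstruction_accuracy(calib: CalibrationResult, test) -> tuple:
    """Mean (and SD) distance of reconstructed test points from truth, mm.

    ``test`` is a list of (CalibrationObservation, known world point); each
    observation's detections are lifted to world via the calibrated chain
    and compared with the known point-phantom position.
    """
    test = list(test)
    if not test:
        raise ValueError("empty test set")
    errs = []
    for obs, truth in test:
        pw = image_to_world(obs.points, calib.t_us_t, obs.pose, calib.t_s_w)
        errs.extend(np.linalg.norm(pw - np.asarray(truth, float), axis=1))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=0))


def calibration_precision(calibs, probe_points) -> float:
    """Reproducibility of repeated calibrations, mm.

    Projects each probe-frame test pixel through every calibration's
    ``T_{US->T}`` and returns the average (over points) of the mean
    deviation from the per-point centroid.
    """
    calibs = list(calibs)
    if len(calibs) < 2:
        raise ValueError("need at least 2 calibration results")
    pts = np.atleast_2d(np.asarray(probe_points, float))
    proj = np.stack([c.t_us_t.apply(pts) for c in calibs])  # (n_cal, n_pt, 3)
    centroid = proj.mean(axis=0)
    dev = np.linalg.norm(proj - centroid[None], axis=2)  # (n_cal, n_pt)
    return float(dev.mean())
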