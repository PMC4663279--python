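"""Contour tracking of a target in 2D ultrasound-like image sequences.

A closed contour is snapped to the brightness edge of the target once, then
propagated through the sequence by a condensation (conditional density
propagation) particle filter over a 5-parameter similarity state:
translation (tx, ty), in-plane rotation theta, and per-axis scale (sx, sy).
The measurement model scores a hypothesised state by the image gradient
along the transformed contour's outward normals: a contour sitting on the
target edge collects strong directional gradients, an off-target contour
does not.  The per-frame posterior mean of the state stream is the motion
signal handed to the gating stage (its axial displacement column after
transformation to world coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .calibration import CalibrationResult
from .gating import TrackingSignal
from .transforms import PoseStream, image_to_world

__all__ = [
    "USFrame",
    "Contour",
    "TrackState",
    "ParticleSet",
    "TrackerConfig",
    "TrackingLostError",
    "InitializationError",
    "initialize_contour",
    "measurement_weight",
    "condensation_step",
    "estimate_state",
    "track_sequence",
    "tracked_point_to_world",
]


class TrackingLostError(RuntimeError):
    """All particle weights vanished: the target was lost."""


class InitializationError(ValueError):
    """No usable brightness edge around the seed."""


@dataclass
class USFrame:
    """One 2D brightness frame (arbitrary units, non-negative)."""

    image: np.ndarray
    timestamp_ms: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, float)
        if self.image.ndim != 2:
            raise ValueError("frame must be a 2D array")
        if np.any(self.image < 0):
            raise ValueError("brightness must be non-negative")


@dataclass
class Contour:
    """Closed polyline of ordered control points in pixels, (M, 2) as (u, v)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 2)
        if len(self.points) < 8:
            raise ValueError("contour needs at least 8 control points")

    @property
    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def normals(self) -> np.ndarray:
        """Outward unit normals at each control point (closed polyline)."""
        p = self.points
        tang = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
        n = np.column_stack([tang[:, 1], -tang[:, 0]])
        n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)
        # orient outward (away from the centroid)
        out = p - self.center
        flip = (n * out).sum(axis=1) < 0
        n[flip] *= -1
        return n


@dataclass(frozen=True)
class TrackState:
    """Similarity state: translation px, rotation rad, per-axis scale."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    sx: float = 1.0
    sy: float = 1.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.theta, self.sx, self.sy])

    @classmethod
    def from_array(cls, a) -> "TrackState":
        return cls(*[float(x) for x in a])

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Transform pixel points: scale and rotate about ``center``, then
        translate."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        q = (np.asarray(points, float) - center) * [self.sx, self.sy]
        return q @ R.T + center + [self.tx, self.ty]


def _apply_states(states: np.ndarray, points: np.ndarray,
                  center: np.ndarray) -> np.ndarray:
    """Vectorized TrackState.apply for an (N, 5) state array -> (N, M, 2)."""
    c = np.cos(states[:, 2])[:, None]
    s = np.sin(states[:, 2])[:, None]
    q = points[None, :, :] - center  # (1, M, 2)
    qx = q[..., 0] * states[:, 3][:, None]
    qy = q[..., 1] * states[:, 4][:, None]
    x = c * qx - s * qy + center[0] + states[:, 0][:, None]
    y = s * qx + c * qy + center[1] + states[:, 1][:, None]
    return np.stack([x, y], axis=-1)


@dataclass
class ParticleSet:
    """States (N, 5) with normalized non-negative weights."""

    states: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, float))
        self.weights = np.asarray(self.weights, float).reshape(-1)
        if self.states.shape[0] != len(self.weights) or self.states.shape[1] != 5:
            raise ValueError("states must be (N, 5) with N weights")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        tot = self.weights.sum()
        if not np.isclose(tot, 1.0, atol=1e-9):
            if tot <= 0:
                raise ValueError("weights must sum to a positive value")
            self.weights = self.weights / tot

    @classmethod
    def around(cls, state: TrackState, n: int, spread, rng) -> "ParticleSet":
        base = state.as_array()
        states = base + rng.normal(0.0, np.asarray(spread, float), (n, 5))
        states[:, 3:] = np.clip(states[:, 3:], 1e-3, None)
        return cls(states, np.full(n, 1.0 / n))

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


@dataclass(frozen=True)
class TrackerConfig:
    """Condensation parameters.

    ``dynamics_sd`` are the per-step diffusion SDs for (tx, ty, theta, sx,
    sy); ``lam`` maps the mean directional-gradient score to a likelihood
    via exp(lam * score); ``n_samples`` is the number of contour samples at
    which the edge response is probed.
    """

    n_particles: int = 200
    dynamics_sd: tuple = (1.5, 1.5, 0.01, 0.005, 0.005)
    lam: float = 30.0
    n_samples: int = 32
    seed: int = 0
    gradient_sigma_px: float = 1.0


# ---------------------------------------------------------------------------
# contour initialization


def initialize_contour(
    frame: USFrame,
    center,
    radius: float,
    n_points: int = 32,
    search: tuple = (0.4, 1.8),
    min_edge_fraction: float = 0.05,
) -> Contour:
    """Snap a contour to the strongest radial brightness edge around a seed.

    Rays are cast from the seed center; along each ray the radial gradient
    magnitude of the (lightly smoothed) image is sampled between
    ``search[0] * radius`` and ``search[1] * radius`` and the contour point
    is placed at the maximum.  Fails when the best edge response is not
    clearly above the image's noise floor.
    """
    img = gaussian_filter(frame.image, 1.0)
    h, w = img.shape
    cu, cv = float(center[0]), float(center[1])
    if not (0 <= cu < w and 0 <= cv < h):
        raise InitializationError("seed center outside frame")
    gv, gu = np.gradient(img)
    angles = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    radii = np.linspace(search[0] * radius, search[1] * radius, 64)
    du, dv = np.cos(angles), np.sin(angles)
    uu = cu + radii[None, :] * du[:, None]
    vv = cv + radii[None, :] * dv[:, None]
    samp_gu = map_coordinates(gu, [vv, uu], order=1, mode="constant")
    samp_gv = map_coordinates(gv, [vv, uu], order=1, mode="constant")
    # radial component of the gradient (edge crossing the ray)
    radial = np.abs(samp_gu * du[:, None] + samp_gv * dv[:, None])
    best = radial.argmax(axis=1)
    strength = radial[np.arange(n_points), best]
    scale = img.max() - img.min()
    if scale <= 0 or strength.max() < min_edge_fraction * scale:
        raise InitializationError("no brightness edge found around the seed")
    r_best = radii[best]
    pts = np.column_stack([cu + r_best * du, cv + r_best * dv])
    return Contour(pts)


# ---------------------------------------------------------------------------
# measurement model


def _gradient_fields(frame: USFrame, sigma: float):
    img = gaussian_filter(frame.image, sigma)
    gv, gu = np.gradient(img)
    return gu, gv


def _weights_for_states(states, base: Contour, grads, shape, lam, n_samples):
    gu, gv = grads
    h, w = shape
    m = len(base.points)
    if n_samples != m:
        sel = np.linspace(0, m, n_samples, endpoint=False).astype(int)
        pts = base.points[sel]
    else:
        pts = base.points
    sub = Contour(pts) if len(pts) >= 8 else base
    normals = sub.normals()
    center = base.center
    tp = _apply_states(states, sub.points, center)  # (N, K, 2)
    c = np.cos(states[:, 2])[:, None]
    s = np.sin(states[:, 2])[:, None]
    nx = c * normals[None, :, 0] - s * normals[None, :, 1]
    ny = s * normals[None, :, 0] + c * normals[None, :, 1]
    u, v = tp[..., 0], tp[..., 1]
    inside = (u >= 0) & (u <= w - 1) & (v >= 0) & (v <= h - 1)
    su = map_coordinates(gu, [v.ravel(), u.ravel()], order=1,
                         mode="constant").reshape(u.shape)
    sv = map_coordinates(gv, [v.ravel(), u.ravel()], order=1,
                         mode="constant").reshape(u.shape)
    score = np.abs(su * nx + sv * ny) * inside
    mean_score = score.sum(axis=1) / score.shape[1]
    any_inside = inside.any(axis=1)
    return np.where(any_inside, np.exp(lam * mean_score), 0.0)


def measurement_weight(frame: USFrame, base: Contour, state: TrackState,
                       lam: float = 30.0, n_samples: int = 32,
                       gradient_sigma_px: float = 1.0) -> float:
    """Likelihood weight of one state: exp(lam * mean |grad . normal|)
    sampled along the transformed contour; 0 if the contour lies fully
    outside the frame.  Gradient-based, hence invariant to global additive
    brightness offsets."""
    grads = _gradient_fields(frame, gradient_sigma_px)
    w = _weights_for_states(state.as_array()[None, :], base, grads,
                            frame.image.shape, lam, n_samples)
    return float(w[0])


def _systematic_resample(weights: np.ndarray, rng) -> np.ndarray:
    n = len(weights)
    positions = (rng.uniform() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def condensation_step(
    particles: ParticleSet,
    frame: USFrame,
    base: Contour,
    config: TrackerConfig,
    rng,
) -> ParticleSet:
    """One predict-diffuse-weigh cycle of the condensation filter.

    Systematic resampling proportional to the incoming weights (stable
    ordering at ties), Gaussian diffusion with the configured dynamics SDs,
    re-weighting by the edge-likelihood measurement, renormalization.
    """
    idx = _systematic_resample(particles.weights, rng)
    states = particles.states[idx].copy()
    states += rng.normal(0.0, np.asarray(config.dynamics_sd, float),
                         states.shape)
    states[:, 3:] = np.clip(states[:, 3:], 1e-3, None)
    grads = _gradient_fields(frame, config.gradient_sigma_px)
    w = _weights_for_states(states, base, grads, frame.image.shape,
                            config.lam, config.n_samples)
    tot = w.sum()
    if tot <= 0 or not np.isfinite(tot):
        raise TrackingLostError("all particle weights vanished")
    return ParticleSet(states, w / tot)


def estimate_state(particles: ParticleSet) -> TrackState:
    """Posterior mean of each parameter (circular mean for theta)."""
    w = particles.weights
    s = particles.states
    mean = (w[:, None] * s).sum(axis=0)
    theta = float(np.arctan2((w * np.sin(s[:, 2])).sum(),
                             (w * np.cos(s[:, 2])).sum()))
    return TrackState(tx=float(mean[0]), ty=float(mean[1]), theta=theta,
                      sx=float(mean[3]), sy=float(mean[4]))


def track_sequence(frames, init_contour: Contour, config: TrackerConfig,
                   axial_column: str = "ty") -> TrackingSignal:
    """Track a contour through a frame sequence.

    Returns a :class:`TrackingSignal` whose primary ``values`` column is the
    displacement parameter aligned with the scanner axis (``axial_column``,
    in pixels of image motion) — the column used as the gating signal — and
    whose extras carry all five state parameters plus the effective sample
    size per frame.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(config.seed)
    particles = ParticleSet.around(
        TrackState(), config.n_particles,
        spread=np.asarray(config.dynamics_sd), rng=rng)
    cols = {k: [] for k in ("tx", "ty", "theta", "sx", "sy", "ess")}
    times = []
    for fr in frames:
        particles = condensation_step(particles, fr, init_contour, config, rng)
        st = estimate_state(particles)
        for k in ("tx", "ty", "theta", "sx", "sy"):
            cols[k].append(getattr(st, k))
        cols["ess"].append(particles.effective_sample_size)
        times.append(fr.timestamp_ms)
    values = np.asarray(cols[axial_column])
    return TrackingSignal(times_ms=np.asarray(times), values=values,
                          extras={k: np.asarray(v) for k, v in cols.items()})


def tracked_point_to_world(
    state: TrackState,
    anchor,
    pose_stream: PoseStream,
    calib: CalibrationResult,
    t_ms: float,
    contour_center=None,
) -> np.ndarray:
    """Map a tracked image point to world coordinates at time ``t_ms``.

    The state is applied to the anchor pixel (about ``contour_center``,
    default the anchor itself), the probe pose is interpolated from the
    optical stream at ``t_ms`` and the full image-to-world chain is applied.
    Raises :class:`~echogate.transforms.PoseExtrapolationError` outside the
    pose-stream span.
    """
    anchor = np.asarray(anchor, float)
    center = anchor if contour_center is None else np.asarray(contour_center,
                                                              float)
    uv = state.apply(anchor[None, :], center)[0]
    pose = pose_stream.interpolate(t_ms)
    return image_to_world(uv, calib.t_us_t, pose, calib.t_s_w)
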