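"""Rigid 3D coordinate transforms and the ultrasound-to-world chain.

Four coordinate frames are involved when a tracked ultrasound probe observes
a moving target: the 2D ultrasound image plane (``US``, with an implicit
z = 0), the optical marker tool rigidly mounted on the probe (``T``), the
optical sensor (``S``) and the treatment-room/world frame (``W``).  A pixel
``p_US`` maps to world coordinates through the chain

    p_W = T_{S->W} . T_{T->S} . T_{US->T} . p_US

where ``T_{T->S}`` is streamed by the optical tracker and the outer two
transforms are found by calibration.  ``T_{US->T}`` additionally carries the
isotropic mm-per-pixel scale of the image (the sector geometry makes it
identical for both image axes).

Conventions: lengths in mm, times in ms, angles in radians.  The image
origin is the transducer apex at pixel (0, 0), ``u`` is the lateral axis and
``v`` the depth axis.  World axes: ``z_W`` along the scanner bore, ``x_W``
horizontal transverse, ``y_W`` vertical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "RigidTransform3D",
    "ImageToProbeTransform",
    "PoseStream",
    "compose",
    "invert",
    "apply",
    "image_to_world",
]

_ORTHO_TOL = 1e-6


def _check_rotation(R: np.ndarray) -> np.ndarray:
    """Validate (and, for tiny drift, re-orthonormalize) a rotation matrix."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    drift = np.abs(R.T @ R - np.eye(3)).max()
    if drift > _ORTHO_TOL:
        raise ValueError(f"matrix is not orthonormal (drift {drift:.2e})")
    if drift > 1e-12:
        # project back onto SO(3) via SVD
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
    if np.linalg.det(R) < 0:
        raise ValueError("rotation has determinant -1 (reflection)")
    return R


@dataclass(frozen=True)
class RigidTransform3D:
    """Proper rigid transform: ``p -> rotation @ p + translation``.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1.
    translation
        3-vector in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidTransform3D":
        """Build from an axis-angle rotation vector (radians) and translation."""
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   translation)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform3D":
        """Build from a 4x4 homogeneous matrix."""
        m = np.asarray(m, float)
        return cls(m[:3, :3], m[:3, 3])

    # -- core algebra ------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def as_rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one 3-vector or an (n, 3) array of points (mm)."""
        p = np.asarray(points, float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return RigidTransform3D(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform3D") -> "RigidTransform3D":
        return self.compose(other)

    def invert(self) -> "RigidTransform3D":
        Rt = self.rotation.T
        return RigidTransform3D(Rt, -Rt @ self.translation)

    def isclose(self, other: "RigidTransform3D", atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, other.rotation, atol=atol)
                and np.allclose(self.translation, other.translation, atol=atol))

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation_mm": [float(x) for x in self.translation],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform3D":
        return cls(np.asarray(d["rotation"], float).reshape(3, 3),
                   d["translation_mm"])


@dataclass(frozen=True)
class ImageToProbeTransform:
    """Image-plane-to-marker-tool transform ``T_{US->T}``.

    Carries the rigid pose of the image plane in the tool frame plus the
    isotropic mm-per-pixel scale.  A pixel (u, v) is first lifted to the
    plane point (scale*u, scale*v, 0) in mm and then moved rigidly.
    """

    rigid: RigidTransform3D
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scale (mm/px) must be strictly positive")
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls, scale: float = 1.0) -> "ImageToProbeTransform":
        return cls(RigidTransform3D.identity(), scale)

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """Lift pixel coordinates (u, v) to 3D plane points in mm (z = 0)."""
        uv = np.atleast_2d(np.asarray(uv, float))
        p = np.zeros((uv.shape[0], 3))
        p[:, :2] = uv * self.scale
        return p

    def apply(self, uv: np.ndarray) -> np.ndarray:
        """Map pixels into the tool frame (mm)."""
        out = self.rigid.apply(self.lift(uv))
        return out[0] if np.asarray(uv).ndim == 1 else out

    def project(self, points_t: np.ndarray) -> np.ndarray:
        """Inverse map: tool-frame points (mm) to (u, v, z_plane_mm).

        z_plane is the out-of-plane distance; points on the image plane
        have z_plane = 0.
        """
        p = self.rigid.invert().apply(np.atleast_2d(np.asarray(points_t, float)))
        out = np.column_stack([p[:, 0] / self.scale, p[:, 1] / self.scale, p[:, 2]])
        return out[0] if np.asarray(points_t).ndim == 1 else out

    def to_json_dict(self) -> dict:
        d = self.rigid.to_json_dict()
        d["scale_mm_per_px"] = self.scale
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ImageToProbeTransform":
        return cls(RigidTransform3D.from_json_dict(d), d["scale_mm_per_px"])


# ---------------------------------------------------------------------------
# functional aliases matching the operation-style API


def compose(a: RigidTransform3D, b: RigidTransform3D) -> RigidTransform3D:
    """Return a∘b (b applied first)."""
    return a.compose(b)


def invert(t: RigidTransform3D) -> RigidTransform3D:
    return t.invert()


def apply(t: RigidTransform3D, p) -> np.ndarray:
    return t.apply(p)


def image_to_world(
    p_us,
    t_us_t: ImageToProbeTransform,
    t_t_s: RigidTransform3D,
    t_s_w: RigidTransform3D,
) -> np.ndarray:
    """Chain a pixel (u, v) through ``T_{S->W} . T_{T->S} . T_{US->T}``.

    Accepts a single (u, v) pair or an (n, 2) array; returns world mm.
    """
    chain = t_s_w @ t_t_s @ t_us_t.rigid
    lifted = t_us_t.lift(p_us)
    out = chain.apply(lifted)
    return out[0] if np.asarray(p_us).ndim == 1 else out


def world_to_image(
    p_w,
    t_us_t: ImageToProbeTransform,
    t_t_s: RigidTransform3D,
    t_s_w: RigidTransform3D,
) -> np.ndarray:
    """Inverse chain: world mm to (u, v, out-of-plane mm)."""
    chain = (t_s_w @ t_t_s).invert()
    return t_us_t.project(chain.apply(p_w))


# ---------------------------------------------------------------------------


class PoseExtrapolationError(ValueError):
    """Query time outside the recorded pose-stream span."""


@dataclass
class PoseStream:
    """Timestamped rigid poses, e.g. the ~10 Hz optical-tracker output.

    Interpolation between bracketing samples is linear for the translation
    and spherical-linear (slerp) for the rotation, which is adequate for the
    slow, smooth probe motion the stream records.
    """

    times_ms: np.ndarray
    poses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, float).reshape(-1)
        if len(self.times_ms) != len(self.poses):
            raise ValueError("times and poses must have equal length")
        if len(self.times_ms) == 0:
            raise ValueError("empty pose stream")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("pose timestamps must be strictly increasing")
        self._rots = Rotation.from_matrix(
            np.stack([p.rotation for p in self.poses]))
        self._trans = np.stack([p.translation for p in self.poses])
        self._slerp = Slerp(self.times_ms, self._rots) if len(self.poses) > 1 else None

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def span_ms(self) -> tuple:
        return float(self.times_ms[0]), float(self.times_ms[-1])

    def interpolate(self, t_ms: float) -> RigidTransform3D:
        """Pose at time ``t_ms``; raises outside the recorded span."""
        t0, t1 = self.span_ms
        if not (t0 <= t_ms <= t1):
            raise PoseExtrapolationError(
                f"t={t_ms} ms outside pose stream span [{t0}, {t1}] ms")
        if self._slerp is None:
            return self.poses[0]
        R = self._slerp([t_ms]).as_matrix()[0]
        tr = np.array([np.interp(t_ms, self.times_ms, self._trans[:, k])
                       for k in range(3)])
        return RigidTransform3D(R, tr)
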