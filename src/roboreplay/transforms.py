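"""Rigid-body transform algebra and rotation representations.

All quantities are SI (meters, radians). Frames are right-handed; by data
contract, gravity points along -Z of both the motion-capture frame and the
robot base frame, which is what makes a gravity-axis (yaw) mapping between
the two physically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "rotation_about_axis",
    "matrix_to_rotvec",
    "rotvec_to_matrix",
    "unwrap_rotvecs",
    "orthonormalize",
]

_ORTHO_TOL = 1e-6


class TransformValidationError(ValueError):
    """Raised when a rotation matrix is not orthonormal with det +1."""


def _check_rotation(r: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if r.shape != (3, 3):
        raise TransformValidationError(f"rotation must be 3x3, got {r.shape}")
    if not np.all(np.isfinite(r)):
        raise TransformValidationError("rotation contains non-finite entries")
    err = np.abs(r @ r.T - np.eye(3)).max()
    if err > tol:
        raise TransformValidationError(f"rotation not orthonormal (|RR^T - I| = {err:.3g})")
    if np.linalg.det(r) < 0:
        raise TransformValidationError("rotation has det -1 (improper)")


def orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via polar decomposition (SVD)."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """Pose of one frame expressed in another: x_parent = R x_child + t."""

    rotation: np.ndarray
    translation: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if self.validate:
            _check_rotation(r)
            if not np.all(np.isfinite(t)):
                raise TransformValidationError("translation contains non-finite entries")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray, validate: bool = True) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise TransformValidationError(f"homogeneous matrix must be 4x4, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3], validate=validate)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            validate=False,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, validate=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from the child frame into the parent frame."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis.

    Raises on a zero-length or non-unit axis (tolerance 1e-9).
    """
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis has zero length")
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"rotation axis must be unit length (norm = {n:.12g})")
    return Rotation.from_rotvec(axis * theta).as_matrix()


def matrix_to_rotvec(r: np.ndarray) -> np.ndarray:
    """Rotation matrix -> rotation vector with norm in [0, pi].

    At exactly pi the two antipodal representatives are equivalent; the one
    whose largest-magnitude component is non-negative is returned, so the
    standalone conversion is deterministic. Trajectory code resolves the
    ambiguity by continuity instead (see :func:`unwrap_rotvecs`).
    """
    r = np.asarray(r, dtype=float)
    _check_rotation(r)
    v = Rotation.from_matrix(r).as_rotvec()
    ang = np.linalg.norm(v)
    if ang > np.pi - 1e-9 and v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(v, dtype=float).reshape(3)).as_matrix()


def unwrap_rotvecs(vecs: np.ndarray) -> np.ndarray:
    """Make a rotation-vector time series continuous.

    Each sample may be replaced by an equivalent representative
    ``v * (1 - 2*pi/|v|)`` (the antipodal branch) whenever that is closer to
    the previous sample. Raises if consecutive samples still differ by more
    than pi afterwards, which indicates a sampling-rate violation rather than
    a branch artefact.
    """
    vecs = np.asarray(vecs, dtype=float)
    out = vecs.copy()
    for k in range(1, len(out)):
        v = out[k]
        ang = np.linalg.norm(v)
        if ang > 1e-12:
            alt = v * (1.0 - 2.0 * np.pi / ang)
            if np.linalg.norm(alt - out[k - 1]) < np.linalg.norm(v - out[k - 1]):
                out[k] = alt
        if np.linalg.norm(out[k] - out[k - 1]) > np.pi:
            raise ValueError(
                f"rotation-vector discontinuity > pi between samples {k - 1} and {k}"
            )
    return out


def rotvec_rate_to_angular_velocity(v: np.ndarray, v_dot: np.ndarray) -> np.ndarray:
    """Exact map from rotation-vector rate to spatial angular velocity.

    omega = v_dot + (1 - cos a)/a^2 (v x v_dot) + (a - sin a)/a^3 v x (v x v_dot)
    with a = |v|; the limit a -> 0 gives omega = v_dot.
    """
    v = np.asarray(v, dtype=float)
    v_dot = np.asarray(v_dot, dtype=float)
    a = np.linalg.norm(v, axis=-1, keepdims=True)
    small = a < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(small, 0.5, (1.0 - np.cos(a)) / np.maximum(a, 1e-300) ** 2)
        c2 = np.where(small, 1.0 / 6.0, (a - np.sin(a)) / np.maximum(a, 1e-300) ** 3)
    cross1 = np.cross(v, v_dot)
    cross2 = np.cross(v, cross1)
    return v_dot + c1 * cross1 + c2 * cross2
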