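"""Anatomical and robot frame identification.

Covers three tasks performed once per experimental session:

* least-squares sphere fit of digitized humeral-head surface points (the
  centroid defines the glenohumeral rotation center);
* construction of the humeral anatomical coordinate system from the head
  center and the medial/lateral epicondyles (ISB-style: superior axis from
  the epicondyle midpoint to the head center);
* simultaneous identification of the tracker-to-robot rotation and the
  end-effector-to-rigid-body transform from paired robot/tracker poses — an
  AX = ZB hand-eye calibration solved by a separable linear least-squares
  estimate (Kronecker formulation on rotations, then translations) followed
  by nonlinear joint refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform, matrix_to_rotvec, orthonormalize

__all__ = [
    "LandmarkSet",
    "CalibrationSet",
    "IdentificationResult",
    "fit_sphere",
    "build_humeral_frame",
    "identify_frames",
    "compose_tool_frame",
]


class DegenerateGeometryError(ValueError):
    """Input geometry does not determine the requested quantity."""


@dataclass
class LandmarkSet:
    """Digitized humeral landmarks in the digitizer/tracker frame (m)."""

    head_surface_points: np.ndarray  # (n >= 4, 3)
    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray

    def __post_init__(self) -> None:
        self.head_surface_points = np.asarray(self.head_surface_points, dtype=float)
        self.medial_epicondyle = np.asarray(self.medial_epicondyle, dtype=float).reshape(3)
        self.lateral_epicondyle = np.asarray(self.lateral_epicondyle, dtype=float).reshape(3)
        if self.head_surface_points.shape[0] < 4:
            raise ValueError("sphere fit needs at least 4 surface points")


@dataclass
class CalibrationSet:
    """Paired robot flange poses (controller readout) and tracked poses."""

    robot_poses: list[RigidTransform]  # R_T_EE^i
    tracked_poses: list[RigidTransform]  # OT_T_HS^i

    def __post_init__(self) -> None:
        if len(self.robot_poses) != len(self.tracked_poses):
            raise ValueError("pose lists must have equal length")
        if len(self.robot_poses) < 3:
            raise ValueError("need at least 3 pose pairs")

    def __len__(self) -> int:
        return len(self.robot_poses)


@dataclass
class IdentificationResult:
    R_OT: np.ndarray  # 3x3 tracker-to-robot rotation (R_R_OT)
    EE_T_HS: RigidTransform  # rigid body in end-effector frame
    rotation_rms: float  # rad, pose-consistency residual
    translation_rms: float  # m


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Solves ``|x|^2 = 2 c.x + (r^2 - |c|^2)`` in the linear parameters
    ``(c, r^2 - |c|^2)``. Returns (center, radius, rms residual of the
    point-to-surface distances). Raises on (near-)coplanar configurations,
    for which the normal direction of the center is unobservable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need an (n >= 4, 3) point array")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise DegenerateGeometryError("surface points are coplanar or degenerate")
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    residuals = np.linalg.norm(pts - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(residuals**2)))


def build_humeral_frame(
    head_center: np.ndarray,
    medial_epicondyle: np.ndarray,
    lateral_epicondyle: np.ndarray,
) -> RigidTransform:
    """Humeral anatomical frame (ISB-style) from three landmarks.

    Origin at the glenohumeral (head) center. Columns: the superior (Y) axis
    points from the epicondyle midpoint to the head center; the anterior (X)
    axis is perpendicular to the plane spanned by the superior axis and the
    medial-to-lateral epicondyle line (so that line has zero anterior
    component); the lateral (Z) axis completes the right-handed triad.
    """
    head = np.asarray(head_center, dtype=float).reshape(3)
    med = np.asarray(medial_epicondyle, dtype=float).reshape(3)
    lat = np.asarray(lateral_epicondyle, dtype=float).reshape(3)
    mid = 0.5 * (med + lat)
    y = head - mid
    ny = np.linalg.norm(y)
    ml = lat - med
    if ny < 1e-9 or np.linalg.norm(np.cross(y, ml)) < 1e-9 * max(ny, 1e-9):
        raise DegenerateGeometryError("landmarks are collinear or coincident")
    y = y / ny
    x = np.cross(y, ml)
    x = x / np.linalg.norm(x)
    z = np.cross(x, y)
    return RigidTransform(np.column_stack([x, y, z]), head)


def _axes_span(rotations: list[np.ndarray]) -> int:
    """Rank of the span of relative-rotation axes (identifiability check)."""
    axes = []
    for i in range(1, len(rotations)):
        v = matrix_to_rotvec(rotations[0].T @ rotations[i])
        if np.linalg.norm(v) > 1e-6:
            axes.append(v / np.linalg.norm(v))
    if not axes:
        return 0
    return int(np.linalg.matrix_rank(np.stack(axes), tol=1e-3))


def identify_frames(calib: CalibrationSet, refine: bool = True) -> IdentificationResult:
    """AX = ZB calibration: A_i X = Z B_i for all pose pairs i.

    ``A_i`` are robot flange poses, ``B_i`` tracked rigid-body poses,
    ``X = EE_T_HS`` and ``Z = R_T_OT``. Rotations are estimated by the
    homogeneous linear system ``(I (x) RA_i) vec(RX) = (RB_i^T (x) I) vec(RZ)``
    via SVD, projected onto SO(3); translations then follow from linear least
    squares; an optional Levenberg-Marquardt pass jointly refines all 12
    parameters. The translation of Z is estimated internally but discarded —
    only the tracker-to-robot *rotation* is needed downstream.
    """
    RA = [p.rotation for p in calib.robot_poses]
    RB = [p.rotation for p in calib.tracked_poses]
    if _axes_span(RA) < 2:
        raise DegenerateGeometryError(
            "calibration poses do not span two independent rotation axes"
        )
    # homogeneous system M [vec RX; vec RZ] = 0
    rows = []
    for ra, rb in zip(RA, RB):
        rows.append(np.hstack([np.kron(np.eye(3), ra), -np.kron(rb.T, np.eye(3))]))
    M = np.vstack(rows)
    _, _, vt = np.linalg.svd(M)
    v = vt[-1]
    RX = orthonormalize(v[:9].reshape(3, 3, order="F"))
    RZ = orthonormalize(v[9:].reshape(3, 3, order="F"))
    # the SVD null vector is sign-ambiguous; both blocks share the sign
    if np.linalg.det(v[:9].reshape(3, 3, order="F")) < 0:
        RX = orthonormalize(-v[:9].reshape(3, 3, order="F"))
        RZ = orthonormalize(-v[9:].reshape(3, 3, order="F"))
    # translations: RA_i tX - tZ = RZ tB_i - tA_i  (linear in tX, tZ)
    Amat = np.vstack([np.hstack([ra, -np.eye(3)]) for ra in RA])
    bvec = np.concatenate(
        [RZ @ p_b.translation - p_a.translation
         for p_a, p_b in zip(calib.robot_poses, calib.tracked_poses)]
    )
    sol, *_ = np.linalg.lstsq(Amat, bvec, rcond=None)
    tX, tZ = sol[:3], sol[3:]

    def pack(rx, tx, rz, tz):
        return np.concatenate(
            [Rotation.from_matrix(rx).as_rotvec(), tx, Rotation.from_matrix(rz).as_rotvec(), tz]
        )

    def residuals(p):
        rx = Rotation.from_rotvec(p[:3]).as_matrix()
        tx = p[3:6]
        rz = Rotation.from_rotvec(p[6:9]).as_matrix()
        tz = p[9:12]
        out = []
        for p_a, p_b in zip(calib.robot_poses, calib.tracked_poses):
            lhs_r = p_a.rotation @ rx
            lhs_t = p_a.rotation @ tx + p_a.translation
            rhs_r = rz @ p_b.rotation
            rhs_t = rz @ p_b.translation + tz
            out.append(matrix_to_rotvec(lhs_r @ rhs_r.T))
            out.append(lhs_t - rhs_t)
        return np.concatenate(out)

    if refine:
        fit = least_squares(residuals, pack(RX, tX, RZ, tZ), method="lm")
        p = fit.x
        RX = Rotation.from_rotvec(p[:3]).as_matrix()
        tX = p[3:6]
        RZ = Rotation.from_rotvec(p[6:9]).as_matrix()
        tZ = p[9:12]
    res = residuals(pack(RX, tX, RZ, tZ)).reshape(-1, 3)
    rot_rms = float(np.sqrt(np.mean(np.linalg.norm(res[0::2], axis=1) ** 2)))
    trans_rms = float(np.sqrt(np.mean(np.linalg.norm(res[1::2], axis=1) ** 2)))
    return IdentificationResult(
        R_OT=RZ,
        EE_T_HS=RigidTransform(RX, tX),
        rotation_rms=rot_rms,
        translation_rms=trans_rms,
    )


def compose_tool_frame(EE_T_HS: RigidTransform, HS_T_H: RigidTransform) -> RigidTransform:
    """EE_T_H = EE_T_HS . HS_T_H (humerus pose in the end-effector frame)."""
    return EE_T_HS.compose(HS_T_H)
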