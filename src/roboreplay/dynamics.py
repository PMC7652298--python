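"""Bone-implant interface loads via recursive Newton-Euler inverse dynamics.

The prosthesis is modeled as a chain of uniform solid cylinders rigidly
attached to the residual humerus: the prosthetic connection (residual bone to
elbow), the forearm, the hand, and — for jug-lift trials — a jug held in the
hand. The elbow is fixed per activity (90 deg flexion for jogging and
internal rotation, 135 deg for jumping jacks, 180 deg extension for jug
lifts), so the whole chain moves rigidly with the humerus and the interface
wrench follows from a distal-to-proximal Newton-Euler recursion driven by the
humeral pose, velocity and acceleration.

Loads are reported at the 25% amputation level — the cross-section 25% of
arm length distal to the glenohumeral center — where the moment arm to the
distal masses, and hence the interface load, is largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import KinematicDerivatives, PoseTrajectory
from .transforms import rotvec_rate_to_angular_velocity

__all__ = [
    "CylinderSegment",
    "ProsthesisModel",
    "LoadTrajectory",
    "build_prosthesis_model",
    "rnea_loads",
    "project_loads",
    "gravitational_fraction",
]

GRAVITY = np.array([0.0, 0.0, -9.81])  # m/s^2 in the analysis frame

# Fixed segment dimensions/masses (length m, diameter m, mass kg); the
# prosthetic connection is anthropometric: length 0.75 * arm length, mass
# 0.50823 kg/m * 0.75 * arm length + 0.3 kg.
_FOREARM = (0.2540, 0.0762, 1.013)
_HAND = (0.1524, 0.0540, 0.416)
_JUG = (0.2500, 0.1500, 3.800)
_CONNECTION_DIAMETER = 0.060
_CONNECTION_LINEAR_DENSITY = 0.50823  # kg/m
_CONNECTION_BASE_MASS = 0.3  # kg

ELBOW_ANGLE_DEG = {
    "jogging": 90.0,
    "internal_rotation": 90.0,
    "jumping_jack": 135.0,
    "jug_lift": 180.0,
}


@dataclass(frozen=True)
class CylinderSegment:
    """Uniform solid cylinder: centroid and axis in the humeral body frame."""

    name: str
    length: float
    diameter: float
    mass: float
    centroid: np.ndarray  # (3,) m, humeral frame (origin at GH center)
    axis: np.ndarray  # unit vector along the cylinder axis, humeral frame

    def inertia_centroidal(self) -> np.ndarray:
        """Centroidal inertia tensor in the humeral body frame."""
        r = self.diameter / 2.0
        i_axial = 0.5 * self.mass * r**2
        i_perp = self.mass * (3.0 * r**2 + self.length**2) / 12.0
        a = np.asarray(self.axis, dtype=float)
        outer = np.outer(a, a)
        return i_axial * outer + i_perp * (np.eye(3) - outer)


@dataclass
class ProsthesisModel:
    """Rigid cylinder-segment chain distal to the residual humerus."""

    segments: list[CylinderSegment]
    elbow_angle_deg: float
    arm_length: float
    interface_point: np.ndarray  # humeral frame, 25% amputation level

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments)


def build_prosthesis_model(arm_length: float, activity: str) -> ProsthesisModel:
    """Assemble the per-activity prosthesis chain.

    Humeral body frame: origin at the glenohumeral center, +Y superior (the
    humeral long axis), +X anterior. The shaft extends along -Y; the elbow
    sits at -Y * arm_length; the forearm folds from the shaft direction
    toward anterior by (180 deg - elbow angle) in the sagittal plane; the
    hand continues collinear with the forearm; the jug (jug-lift trials
    only) is centered at the hand's distal end.
    """
    if arm_length <= 0:
        raise ValueError("arm length must be positive")
    if activity not in ELBOW_ANGLE_DEG:
        raise ValueError(
            f"unknown activity {activity!r}; expected one of {sorted(ELBOW_ANGLE_DEG)}"
        )
    elbow_deg = ELBOW_ANGLE_DEG[activity]
    L = arm_length
    interface = np.array([0.0, -0.25 * L, 0.0])
    shaft_dir = np.array([0.0, -1.0, 0.0])

    conn_len = 0.75 * L
    conn_mass = _CONNECTION_LINEAR_DENSITY * conn_len + _CONNECTION_BASE_MASS
    segments = [
        CylinderSegment(
            "connection",
            conn_len,
            _CONNECTION_DIAMETER,
            conn_mass,
            centroid=interface + shaft_dir * conn_len / 2.0,
            axis=shaft_dir.copy(),
        )
    ]

    elbow = np.array([0.0, -L, 0.0])
    fold = np.deg2rad(180.0 - elbow_deg)  # 0 at full extension
    forearm_dir = np.array([np.sin(fold), -np.cos(fold), 0.0])
    fl, fd, fm = _FOREARM
    segments.append(
        CylinderSegment(
            "forearm", fl, fd, fm,
            centroid=elbow + forearm_dir * fl / 2.0,
            axis=forearm_dir.copy(),
        )
    )
    wrist = elbow + forearm_dir * fl
    hl, hd, hm = _HAND
    segments.append(
        CylinderSegment(
            "hand", hl, hd, hm,
            centroid=wrist + forearm_dir * hl / 2.0,
            axis=forearm_dir.copy(),
        )
    )
    if activity == "jug_lift":
        jl, jd, jm = _JUG
        segments.append(
            CylinderSegment(
                "jug", jl, jd, jm,
                centroid=wrist + forearm_dir * hl,  # centered at hand's distal end
                axis=forearm_dir.copy(),
            )
        )
    return ProsthesisModel(segments, elbow_deg, L, interface)


@dataclass
class LoadTrajectory:
    """Interface wrench time series plus humeral-axis projections."""

    rate: float
    force: np.ndarray  # (n, 3) N, bone-on-prosthesis at the interface
    moment: np.ndarray  # (n, 3) N*m about the interface point
    axial_force: np.ndarray  # (n,) N, signed along the humeral axis
    torsional_moment: np.ndarray  # (n,) N*m, signed along the humeral axis
    bending_moment: np.ndarray  # (n,) N*m, magnitude orthogonal to the axis

    def __len__(self) -> int:
        return self.force.shape[0]


def project_loads(
    force: np.ndarray, moment: np.ndarray, humeral_axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axial / torsion / bending decomposition against the humeral axis.

    axial = f . a ; torsion = m . a ; bending = |m - (m . a) a|. Broadcasts
    over leading dimensions; ``humeral_axis`` rows must be unit vectors.
    """
    force = np.atleast_2d(np.asarray(force, dtype=float))
    moment = np.atleast_2d(np.asarray(moment, dtype=float))
    axis = np.atleast_2d(np.asarray(humeral_axis, dtype=float))
    norms = np.linalg.norm(axis, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError("humeral axis rows must be unit vectors")
    axial = np.sum(force * axis, axis=-1)
    torsion = np.sum(moment * axis, axis=-1)
    bending = np.linalg.norm(moment - torsion[..., None] * axis, axis=-1)
    return axial, torsion, bending


def _angular_state(kin: KinematicDerivatives) -> tuple[np.ndarray, np.ndarray]:
    """Exact spatial angular velocity from rotation-vector rates, and its
    central-difference derivative as angular acceleration."""
    omega = rotvec_rate_to_angular_velocity(kin.rotvec, kin.angular_velocity)
    alpha = np.gradient(omega, 1.0 / kin.rate, axis=0)
    return omega, alpha


def rnea_loads(
    model: ProsthesisModel,
    traj: PoseTrajectory,
    kin: KinematicDerivatives,
    gravity: np.ndarray = GRAVITY,
    zero_motion: bool = False,
) -> LoadTrajectory:
    """Interface wrench by distal-to-proximal Newton-Euler recursion.

    For every timepoint the humeral pose (R, p) and its derivatives define
    the motion of each rigidly attached segment; each segment contributes
    its Newton force ``m (a_c - g)`` and Euler moment
    ``I_w alpha + w x (I_w w)`` and the recursion accumulates the wrench the
    residual bone must exert on the prosthesis at the 25% amputation level.
    With ``zero_motion`` the velocity and acceleration terms are dropped,
    leaving the purely gravitational (static) loads.
    """
    if len(traj) != len(kin.position):
        raise ValueError("trajectory and derivatives have different lengths")
    gravity = np.asarray(gravity, dtype=float).reshape(3)
    n = len(traj)
    omega, alpha = _angular_state(kin)
    if zero_motion:
        omega = np.zeros_like(omega)
        alpha = np.zeros_like(alpha)
        acc_p = np.zeros_like(kin.linear_acceleration)
    else:
        acc_p = kin.linear_acceleration

    R = traj.rotations
    axis_world = R[:, :, 1]  # humeral +Y (superior) axis in the world frame

    force = np.zeros((n, 3))
    moment = np.zeros((n, 3))
    for k in range(n):
        r = R[k]
        w = omega[k]
        al = alpha[k]
        p_int = kin.position[k] + r @ model.interface_point
        f_total = np.zeros(3)
        m_total = np.zeros(3)
        # distal-to-proximal: accumulate from the far end of the chain
        for seg in reversed(model.segments):
            c_rel = r @ seg.centroid
            c_world = kin.position[k] + c_rel
            # centroid acceleration of a point rigid with the humerus
            a_c = acc_p[k] + np.cross(al, c_rel) + np.cross(w, np.cross(w, c_rel))
            f_seg = seg.mass * (a_c - gravity)
            i_world = r @ seg.inertia_centroidal() @ r.T
            m_seg = i_world @ al + np.cross(w, i_world @ w)
            f_total += f_seg
            m_total += m_seg + np.cross(c_world - p_int, f_seg)
        force[k] = f_total
        moment[k] = m_total
    axial, torsion, bending = project_loads(force, moment, axis_world)
    return LoadTrajectory(traj.rate, force, moment, axial, torsion, bending)


def gravitational_fraction(
    model: ProsthesisModel,
    traj: PoseTrajectory,
    kin: KinematicDerivatives,
    gravity: np.ndarray = GRAVITY,
    floor: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """Share of the bending moment attributable to gravity alone.

    Runs the recursion twice — full, and with all velocities/accelerations
    zeroed — and reports gravity-only bending divided by full bending per
    timepoint, plus the fraction at the timepoint of peak full bending.
    Timepoints whose full bending is below ``floor`` are NaN (undefined).
    """
    full = rnea_loads(model, traj, kin, gravity)
    static = rnea_loads(model, traj, kin, gravity, zero_motion=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(full.bending_moment > floor,
                        static.bending_moment / full.bending_moment, np.nan)
    k_peak = int(np.argmax(full.bending_moment))
    at_peak = float(frac[k_peak]) if full.bending_moment[k_peak] > floor else float("nan")
    return frac, at_peak
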