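"""6-DOF serial manipulator: DH kinematics, Jacobian, numeric IK, limit checks.

The robot is fully configuration-driven (standard Denavit-Hartenberg rows plus
joint position/velocity limits, loaded from YAML with lengths in meters and
angles in degrees). Two configurations ship with the package: an approximate
M20iA-class industrial arm (~1.8 m reach, vendor-published joint speed limits)
and a simple planar analytic test model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .transforms import RigidTransform, matrix_to_rotvec

__all__ = [
    "DHJoint",
    "RobotModel",
    "JointTrajectory",
    "LimitReport",
    "UnreachableError",
    "forward_kinematics",
    "geometric_jacobian",
    "inverse_kinematics",
    "check_limits",
    "load_robot",
    "default_robot",
    "planar_test_robot",
]


class UnreachableError(RuntimeError):
    """IK failed to converge; carries the best residual found."""

    def __init__(self, message: str, best_residual: float, q_best: np.ndarray):
        super().__init__(message)
        self.best_residual = best_residual
        self.q_best = q_best


@dataclass(frozen=True)
class DHJoint:
    """Standard DH row: a (m), alpha (rad), d (m), theta_offset (rad)."""

    a: float
    alpha: float
    d: float
    theta_offset: float = 0.0

    def transform(self, q: float) -> np.ndarray:
        th = q + self.theta_offset
        ct, st = np.cos(th), np.sin(th)
        ca, sa = np.cos(self.alpha), np.sin(self.alpha)
        return np.array(
            [
                [ct, -st * ca, st * sa, self.a * ct],
                [st, ct * ca, -ct * sa, self.a * st],
                [0.0, sa, ca, self.d],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )


@dataclass
class RobotModel:
    """Six-revolute-joint serial arm with joint and joint-velocity limits."""

    joints: list[DHJoint]
    joint_limits: np.ndarray  # (6, 2) rad
    velocity_limits: np.ndarray  # (6,) rad/s
    base_frame: RigidTransform = field(default_factory=RigidTransform.identity)
    flange_frame: RigidTransform = field(default_factory=RigidTransform.identity)
    name: str = "robot"

    def __post_init__(self) -> None:
        if len(self.joints) != 6:
            raise ValueError(f"expected exactly 6 revolute joints, got {len(self.joints)}")
        self.joint_limits = np.asarray(self.joint_limits, dtype=float).reshape(6, 2)
        self.velocity_limits = np.asarray(self.velocity_limits, dtype=float).reshape(6)
        if np.any(self.joint_limits[:, 0] >= self.joint_limits[:, 1]):
            raise ValueError("joint limits must satisfy min < max")
        if np.any(self.velocity_limits <= 0):
            raise ValueError("velocity limits must be positive")

    # joint-frame chain: base, then cumulative products of DH transforms
    def _frames(self, q: np.ndarray) -> list[np.ndarray]:
        frames = [self.base_frame.as_matrix()]
        for joint, qi in zip(self.joints, q):
            frames.append(frames[-1] @ joint.transform(qi))
        frames[-1] = frames[-1] @ self.flange_frame.as_matrix()
        return frames

    def fk(self, q: np.ndarray) -> RigidTransform:
        return forward_kinematics(self, q)

    def random_configuration(self, rng: np.random.Generator, margin: float = 0.1) -> np.ndarray:
        lo, hi = self.joint_limits[:, 0], self.joint_limits[:, 1]
        span = hi - lo
        return rng.uniform(lo + margin * span, hi - margin * span)


@dataclass
class JointTrajectory:
    """Uniformly sampled joint-space trajectory (rad)."""

    rate: float
    q: np.ndarray  # (n, 6)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 6:
            raise ValueError("q must have shape (n, 6)")

    def __len__(self) -> int:
        return self.q.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    def velocities(self) -> np.ndarray:
        """Central finite differences at the native rate (one-sided at ends)."""
        if len(self) < 2:
            raise ValueError("need at least 2 timepoints")
        return np.gradient(self.q, 1.0 / self.rate, axis=0)


def forward_kinematics(model: RobotModel, q: np.ndarray) -> RigidTransform:
    """End-effector pose in the robot base frame (ordered DH product)."""
    q = np.asarray(q, dtype=float).reshape(6)
    if not np.all(np.isfinite(q)):
        raise ValueError("joint vector contains non-finite values")
    return RigidTransform.from_matrix(model._frames(q)[-1], validate=False)


def geometric_jacobian(model: RobotModel, q: np.ndarray) -> np.ndarray:
    """6x6 geometric Jacobian, rows = [linear; angular], base frame.

    Column i is the screw of revolute joint i evaluated at the end-effector
    point: linear part z_{i-1} x (p_e - p_{i-1}), angular part z_{i-1}.
    """
    q = np.asarray(q, dtype=float).reshape(6)
    frames = model._frames(q)
    p_e = frames[-1][:3, 3]
    J = np.zeros((6, 6))
    for i in range(6):
        z = frames[i][:3, 2]
        p = frames[i][:3, 3]
        J[:3, i] = np.cross(z, p_e - p)
        J[3:, i] = z
    return J


def _pose_error(current: RigidTransform, target: RigidTransform) -> np.ndarray:
    """6-vector twist error [dp; rotvec(R_t R^T)] from current to target."""
    dp = target.translation - current.translation
    dr = matrix_to_rotvec(target.rotation @ current.rotation.T)
    return np.concatenate([dp, dr])


def inverse_kinematics(
    model: RobotModel,
    target: RigidTransform,
    q_seed: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 300,
    damping: float = 1e-12,
) -> np.ndarray:
    """Damped-least-squares IK with Jacobian-transpose fallback.

    Converges to the solution branch nearest the seed (trajectory continuity
    is obtained by seeding each timepoint with the previous solution). Raises
    :class:`UnreachableError` when the residual cannot be driven below ``tol``
    within the iteration budget.
    """
    q = np.asarray(q_seed, dtype=float).reshape(6).copy()
    e = _pose_error(forward_kinematics(model, q), target)
    res = float(np.linalg.norm(e))
    best_q, best_res = q.copy(), res
    lam = damping
    for _ in range(max_iter):
        if res < tol:
            return q
        J = geometric_jacobian(model, q)
        try:
            dq = np.linalg.solve(J.T @ J + lam * np.eye(6), J.T @ e)
        except np.linalg.LinAlgError:
            dq = J.T @ e * 0.1  # Jacobian-transpose fallback
        step = np.linalg.norm(dq)
        if step > 0.5:  # trust region: avoid wild jumps near singularities
            dq *= 0.5 / step
        q_try = q + dq
        e_try = _pose_error(forward_kinematics(model, q_try), target)
        res_try = float(np.linalg.norm(e_try))
        if res_try < res:  # accept, relax damping toward Gauss-Newton
            q, e, res = q_try, e_try, res_try
            lam = max(lam * 0.2, damping)
            if res < best_res:
                best_res, best_q = res, q.copy()
        else:  # reject, strengthen damping
            lam = min(lam * 10.0, 1e6)
    raise UnreachableError(
        f"IK did not converge (best residual {best_res:.3g})", best_res, best_q
    )


@dataclass
class LimitReport:
    feasible: bool
    position_ok: np.ndarray  # (6,) bool
    velocity_utilization: np.ndarray  # (6,) max_k |qdot_i(k)| / qdot_max_i
    max_position: np.ndarray
    min_position: np.ndarray
    violations: list[str]


def check_limits(model: RobotModel, traj: JointTrajectory) -> LimitReport:
    """Per-joint excursion and velocity-utilization report.

    Feasible iff every joint stays inside its position limits and every
    utilization u_i = max_k |qdot_i(k)| / qdot_i^max is at most 1.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 timepoints to check limits")
    q = traj.q
    qdot = traj.velocities()
    util = np.abs(qdot).max(axis=0) / model.velocity_limits
    qmin, qmax = q.min(axis=0), q.max(axis=0)
    pos_ok = (qmin >= model.joint_limits[:, 0] - 1e-12) & (qmax <= model.joint_limits[:, 1] + 1e-12)
    violations = []
    for i in range(6):
        if not pos_ok[i]:
            violations.append(
                f"J{i + 1} position [{qmin[i]:.4f}, {qmax[i]:.4f}] rad outside "
                f"[{model.joint_limits[i, 0]:.4f}, {model.joint_limits[i, 1]:.4f}]"
            )
        if util[i] > 1.0:
            violations.append(f"J{i + 1} velocity utilization {util[i]:.3f} > 1")
    return LimitReport(
        feasible=not violations,
        position_ok=pos_ok,
        velocity_utilization=util,
        max_position=qmax,
        min_position=qmin,
        violations=violations,
    )


# ---------------------------------------------------------------------------
# Configuration loading


def load_robot(source) -> RobotModel:
    """Load a robot from a YAML config (path, file object, or dict).

    Schema (angles in degrees, lengths in meters)::

        name: my-robot
        dh:                       # six rows, standard DH
          - {a: 0.15, alpha: -90, d: 0.525, theta_offset: 0}
          ...
        joint_limits_deg: [[-185, 185], ...]
        velocity_limits_deg_s: [195, ...]
    """
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    for key in ("dh", "joint_limits_deg", "velocity_limits_deg_s"):
        if key not in cfg:
            raise ValueError(f"robot config missing required field '{key}'")
    joints = [
        DHJoint(
            a=float(row.get("a", 0.0)),
            alpha=np.deg2rad(float(row.get("alpha", 0.0))),
            d=float(row.get("d", 0.0)),
            theta_offset=np.deg2rad(float(row.get("theta_offset", 0.0))),
        )
        for row in cfg["dh"]
    ]
    return RobotModel(
        joints=joints,
        joint_limits=np.deg2rad(np.asarray(cfg["joint_limits_deg"], dtype=float)),
        velocity_limits=np.deg2rad(np.asarray(cfg["velocity_limits_deg_s"], dtype=float)),
        name=str(cfg.get("name", "robot")),
    )


def _load_packaged(name: str) -> RobotModel:
    with resources.files("roboreplay.data").joinpath(name).open() as fh:
        return load_robot(fh)


def default_robot() -> RobotModel:
    """Approximate M20iA-class 6R industrial arm (config-shipped)."""
    return _load_packaged("m20ia_class.yaml")


def planar_test_robot() -> RobotModel:
    """Analytic two-effective-link test model (a1 = a2 = 0.5 m, rest zero)."""
    return _load_packaged("planar_test.yaml")
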