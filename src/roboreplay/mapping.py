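"""Gravity-consistent mapping of motion-capture trajectories to joint space.

A trajectory recorded in the motion-capture frame is relocated into the robot
workspace by a 4-parameter mapping — a rotation about the gravitational axis
(theta) plus a 3-D translation — which preserves the trajectory's kinetic
properties (gravity keeps its direction relative to the motion, and speeds
are unchanged under the isometry). Two optimizers search for a feasible
joint-space realization that minimizes joint-velocity utilization:

* a derivative-free formulation (COBYLA) over the six initial joint angles
  q(0), from which the mapping is implied and the rest of the trajectory
  follows by sequential inverse kinematics;
* a gradient-based large-scale NLP (trust-region SQP/interior point) over
  the full joint trajectory plus the mapping parameters, used to re-optimize
  quickly when the tool frame changes (virtual -> physically clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, NonlinearConstraint, minimize

from .robot import (
    JointTrajectory,
    RobotModel,
    UnreachableError,
    check_limits,
    forward_kinematics,
    geometric_jacobian,
    inverse_kinematics,
)
from .trajectory import PoseTrajectory
from .transforms import RigidTransform, matrix_to_rotvec

__all__ = [
    "FrameMapping",
    "MappingResult",
    "apply_mapping",
    "implied_mapping_from_initial_joints",
    "optimize_derivative_free",
    "optimize_gradient_based",
    "generate_virtual_tool_frames",
]

GRAVITY_AXIS = np.array([0.0, 0.0, 1.0])  # gravity is -Z in MC and robot frames
FK_TOL = 1e-6
TILT_TOL = 1e-3


@dataclass(frozen=True)
class FrameMapping:
    """R_T_MC: rotation by theta about the gravity axis plus a translation."""

    theta: float
    translation: np.ndarray

    def transform(self) -> RigidTransform:
        c, s = np.cos(self.theta), np.sin(self.theta)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return RigidTransform(rz, np.asarray(self.translation, dtype=float))


@dataclass
class MappingResult:
    joint_trajectory: JointTrajectory | None
    mapping: FrameMapping | None
    objective_value: float
    feasible: bool
    fk_residuals: np.ndarray | None  # (n, 2): position m, orientation rad
    velocity_utilization: np.ndarray | None
    message: str = ""

    @property
    def max_fk_residual(self) -> tuple[float, float]:
        if self.fk_residuals is None:
            return (np.inf, np.inf)
        return (float(self.fk_residuals[:, 0].max()), float(self.fk_residuals[:, 1].max()))


def apply_mapping(mapping: FrameMapping, traj: PoseTrajectory) -> PoseTrajectory:
    """Relocate an MC-frame trajectory into the robot frame (left-multiply)."""
    return traj.transformed(mapping.transform(), source_frame="R")


def _yaw_of(rotation: np.ndarray) -> float:
    """Angle of the gravity-axis rotation closest (Frobenius) to ``rotation``."""
    return float(np.arctan2(rotation[1, 0] - rotation[0, 1], rotation[0, 0] + rotation[1, 1]))


def implied_mapping_from_initial_joints(
    robot: RobotModel,
    q0: np.ndarray,
    tool: RigidTransform,
    first_pose: RigidTransform,
) -> tuple[FrameMapping, float]:
    """Mapping implied by placing the first trajectory sample at K(q0).

    The candidate transform ``K(q0) . EE_T_H . (MC_T_H^0)^-1`` is reduced to
    the gravity-consistent form by extracting the yaw component of its
    rotation; the returned tilt residual is the geodesic angle between the
    candidate rotation and that yaw rotation (zero iff the candidate is
    already a pure gravity-axis rotation).
    """
    candidate = forward_kinematics(robot, q0) @ tool @ first_pose.invert()
    theta = _yaw_of(candidate.rotation)
    mapping = FrameMapping(theta, candidate.translation)
    tilt = float(
        np.linalg.norm(matrix_to_rotvec(mapping.transform().rotation.T @ candidate.rotation))
    )
    return mapping, tilt


def _solve_joint_trajectory(
    robot: RobotModel,
    traj_robot: PoseTrajectory,
    tool: RigidTransform,
    q0: np.ndarray,
    ik_tol: float = 1e-10,
) -> tuple[JointTrajectory, np.ndarray]:
    """Sequential IK over all timepoints, each seeded with its predecessor.

    Branch continuity (nearest-to-previous solution) makes the joint
    trajectory unique given q(0). Returns the trajectory and per-waypoint
    FK residuals (position m, orientation rad).
    """
    tool_inv = tool.invert()
    n = len(traj_robot)
    q = np.empty((n, 6))
    residuals = np.empty((n, 2))
    q_prev = np.asarray(q0, dtype=float)
    for k in range(n):
        target = traj_robot[k] @ tool_inv  # K(q) = D_R_T_H . (EE_T_H)^-1
        q_prev = inverse_kinematics(robot, target, q_prev, tol=ik_tol)
        q[k] = q_prev
        achieved = forward_kinematics(robot, q_prev)
        residuals[k, 0] = np.linalg.norm(achieved.translation - target.translation)
        residuals[k, 1] = np.linalg.norm(
            matrix_to_rotvec(target.rotation @ achieved.rotation.T)
        )
    return JointTrajectory(traj_robot.rate, q), residuals


def _evaluate_candidate(
    robot: RobotModel,
    traj_MC: PoseTrajectory,
    tool: RigidTransform,
    q0: np.ndarray,
) -> dict:
    """Full pipeline for one q(0) candidate: mapping, IK, limits."""
    mapping, tilt = implied_mapping_from_initial_joints(robot, q0, tool, traj_MC[0])
    out = {"mapping": mapping, "tilt": tilt, "ok": False}
    try:
        jt, res = _solve_joint_trajectory(robot, apply_mapping(mapping, traj_MC), tool, q0)
    except UnreachableError as err:
        out["error"] = str(err)
        return out
    out["ok"] = True
    out["joint_trajectory"] = jt
    out["fk_residuals"] = res
    if len(jt) >= 2:
        report = check_limits(robot, jt)
        out["util"] = report.velocity_utilization
        out["limits"] = report
        out["objective"] = float(report.velocity_utilization.max())
        out["pos_margin"] = float(
            min(
                (jt.q - robot.joint_limits[:, 0]).min(),
                (robot.joint_limits[:, 1] - jt.q).min(),
            )
        )
    else:  # stationary single-pose trajectory: no motion, utilization zero
        out["util"] = np.zeros(6)
        out["limits"] = None
        out["objective"] = 0.0
        out["pos_margin"] = float(
            min(
                (jt.q - robot.joint_limits[:, 0]).min(),
                (robot.joint_limits[:, 1] - jt.q).min(),
            )
        )
    return out


def _result_from_candidate(cand: dict, message: str = "") -> MappingResult:
    # The gravity-axis projection makes the *used* mapping exactly gravity-
    # consistent for any q0, so feasibility does not depend on the candidate
    # tilt; re-parameterizing the solution by its own first joint vector
    # drives the tilt to the IK residual (~1e-11) automatically.
    feasible = (
        cand.get("ok", False)
        and cand.get("pos_margin", -1.0) >= 0.0
        and cand.get("objective", np.inf) <= 1.0
        and cand["fk_residuals"][:, 0].max() < FK_TOL
        and cand["fk_residuals"][:, 1].max() < FK_TOL
    )
    return MappingResult(
        joint_trajectory=cand.get("joint_trajectory"),
        mapping=cand.get("mapping"),
        objective_value=cand.get("objective", np.inf),
        feasible=bool(feasible),
        fk_residuals=cand.get("fk_residuals"),
        velocity_utilization=cand.get("util"),
        message=message or cand.get("error", ""),
    )


def optimize_derivative_free(
    robot: RobotModel,
    traj_MC: PoseTrajectory,
    tool: RigidTransform,
    seed_q0: np.ndarray | None = None,
    maxiter: int = 80,
    rhobeg: float = 0.3,
) -> MappingResult:
    """COBYLA over the six initial joint angles q(0).

    Each candidate q(0) implies a mapping via the gravity-axis projection of
    ``K(q0) . EE_T_H . (MC_T_H^0)^-1`` — exactly gravity-consistent by
    construction — under which the trajectory is relocated, solved by
    sequential IK, and scored by its maximum joint velocity utilization.
    Constraints: joint position limits and utilization <= 1 (the tilt of the
    unprojected candidate is a diagnostic only; re-parameterizing a solution
    by its own first joint vector drives it to the IK tolerance). Returns
    the best feasible result, or an infeasibility report when no candidate
    satisfies the robot limits.
    """
    mid = 0.5 * (robot.joint_limits[:, 0] + robot.joint_limits[:, 1])
    if seed_q0 is None:
        starts = [mid]
    else:
        starts = [np.asarray(seed_q0, dtype=float)]
    # deterministic multi-start fallbacks: elbow-up/down postures around the
    # workspace center (COBYLA is local; restarts recover from bad basins)
    span = robot.joint_limits[:, 1] - robot.joint_limits[:, 0]
    starts += [
        mid + span * np.array([0.0, -0.15, 0.10, 0.0, 0.15, 0.0]),
        mid + span * np.array([0.10, 0.15, -0.10, -0.05, -0.15, 0.05]),
        mid + span * np.array([-0.10, 0.0, 0.15, 0.05, 0.10, -0.05]),
    ]
    cache: dict[bytes, dict] = {}
    best: dict | None = None

    def evaluate(q0: np.ndarray) -> dict:
        key = np.asarray(q0).tobytes()
        if key not in cache:
            cache.clear()  # COBYLA revisits only the current point
            cand = _evaluate_candidate(robot, traj_MC, tool, q0)
            cache[key] = cand
            nonlocal best
            if cand.get("ok") and _result_from_candidate(cand).feasible:
                if best is None or cand["objective"] < best["objective"]:
                    best = cand
        return cache[key]

    def objective(q0):
        cand = evaluate(q0)
        if not cand.get("ok"):
            return 10.0
        return cand["objective"]

    def constraint(q0):
        cand = evaluate(q0)
        if not cand.get("ok"):
            return np.array([-1.0, -1.0])
        return np.array([cand["pos_margin"], 1.0 - cand["objective"]])

    for start in starts:
        minimize(
            objective,
            start,
            method="COBYLA",
            constraints=[{"type": "ineq", "fun": constraint}],
            options={"maxiter": maxiter, "rhobeg": rhobeg, "tol": 1e-8},
        )
        if best is not None:
            return _result_from_candidate(best, "derivative-free optimization converged")
    final = _evaluate_candidate(robot, traj_MC, tool, starts[0])
    return _result_from_candidate(
        final, "no feasible joint-space trajectory found (robot limits unsatisfiable)"
    )


# ---------------------------------------------------------------------------
# Gradient-based refinement


def _humerus_jacobian(robot: RobotModel, q: np.ndarray, tool: RigidTransform) -> np.ndarray:
    """Geometric Jacobian evaluated at the humerus (tool) origin."""
    J = geometric_jacobian(robot, q)
    fk = forward_kinematics(robot, q)
    r = fk.rotation @ tool.translation  # lever arm flange -> tool origin
    Jh = J.copy()
    Jh[:3] += np.cross(J[3:].T, r).T  # v_tool = v_flange + w x r
    return Jh


def optimize_gradient_based(
    robot: RobotModel,
    traj_MC: PoseTrajectory,
    tool: RigidTransform,
    initial: MappingResult,
    maxiter: int = 300,
) -> MappingResult:
    """Large-scale NLP over the full joint trajectory plus (theta, t).

    Decision variables are every q(k) and the four mapping parameters;
    equality constraints enforce the kinematic chain at every retained
    timepoint, inequality constraints the joint position/velocity limits;
    the objective is the smooth sum over time and joints of squared
    normalized joint velocities. Sparse analytic constraint Jacobians are
    assembled from the geometric Jacobian. After the NLP returns, the
    mapping is re-projected to exact kinematic feasibility by sequential IK
    (so the FK residual never worsens relative to the warm start), and the
    better of warm start and refinement is returned.
    """
    if initial.joint_trajectory is None or initial.mapping is None:
        raise ValueError("gradient-based optimization needs a warm-start result")
    jt0 = initial.joint_trajectory
    n = len(jt0)
    dt = 1.0 / jt0.rate
    vmax = robot.velocity_limits
    w = 1.0 / (dt * vmax)  # per-joint velocity normalization of differences

    def split(z):
        return z[: 6 * n].reshape(n, 6), z[6 * n], z[6 * n + 1 :]

    def objective(z):
        q, _, _ = split(z)
        d = (q[1:] - q[:-1]) * w
        return float(np.sum(d * d))

    def gradient(z):
        q, _, _ = split(z)
        g = np.zeros_like(z)
        d = (q[1:] - q[:-1]) * w * w
        gq = np.zeros((n, 6))
        gq[1:] += 2.0 * d
        gq[:-1] -= 2.0 * d
        g[: 6 * n] = gq.ravel()
        return g

    rv_mc = traj_MC.translations
    rot_mc = traj_MC.rotations

    def constraint_fun(z):
        q, theta, t = split(z)
        mapping = FrameMapping(theta, t).transform()
        out = np.empty(6 * n)
        for k in range(n):
            fk = forward_kinematics(robot, q[k])
            g_pose = fk @ tool
            h_rot = mapping.rotation @ rot_mc[k]
            h_t = mapping.rotation @ rv_mc[k] + mapping.translation
            out[6 * k : 6 * k + 3] = g_pose.translation - h_t
            out[6 * k + 3 : 6 * k + 6] = matrix_to_rotvec(g_pose.rotation @ h_rot.T)
        return out

    def constraint_jac(z):
        q, theta, t = split(z)
        c, s = np.cos(theta), np.sin(theta)
        drz = np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])
        rows, cols, vals = [], [], []
        for k in range(n):
            Jh = _humerus_jacobian(robot, q[k], tool)
            for a in range(6):
                for b in range(6):
                    rows.append(6 * k + a)
                    cols.append(6 * k + b)
                    vals.append(Jh[a, b])
            dtheta_pos = -(drz @ rv_mc[k])
            for a in range(3):
                rows.append(6 * k + a)
                cols.append(6 * n)
                vals.append(dtheta_pos[a])
                # translation block: d e_pos / d t = -I
                rows.append(6 * k + a)
                cols.append(6 * n + 1 + a)
                vals.append(-1.0)
            # rotating the target about +Z decreases the orientation error
            rows.append(6 * k + 5)
            cols.append(6 * n)
            vals.append(-1.0)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(6 * n, 6 * n + 4))

    # linear velocity-limit constraints |q(k+1) - q(k)| / dt <= vmax
    rows, cols, vals = [], [], []
    for k in range(n - 1):
        for i in range(6):
            r = 6 * k + i
            rows += [r, r]
            cols += [6 * (k + 1) + i, 6 * k + i]
            vals += [1.0, -1.0]
    D = sparse.csr_matrix((vals, (rows, cols)), shape=(6 * (n - 1), 6 * n + 4))
    vbound = np.tile(vmax * dt, n - 1)

    lo = np.concatenate([np.tile(robot.joint_limits[:, 0], n), [-np.inf] * 4])
    hi = np.concatenate([np.tile(robot.joint_limits[:, 1], n), [np.inf] * 4])

    z0 = np.concatenate(
        [jt0.q.ravel(), [initial.mapping.theta], initial.mapping.translation]
    )
    sol = minimize(
        objective,
        z0,
        jac=gradient,
        method="trust-constr",
        constraints=[
            NonlinearConstraint(constraint_fun, 0.0, 0.0, jac=constraint_jac),
            LinearConstraint(D, -vbound, vbound),
        ],
        bounds=Bounds(lo, hi),
        options={"maxiter": maxiter, "gtol": 1e-8, "xtol": 1e-10, "verbose": 0},
    )
    q_sol, theta_sol, t_sol = split(sol.x)
    # feasibility restoration: exact IK re-solve under the refined mapping
    mapping = FrameMapping(float(theta_sol), np.asarray(t_sol))
    try:
        jt, res = _solve_joint_trajectory(
            robot, apply_mapping(mapping, traj_MC), tool, q_sol[0]
        )
    except UnreachableError as err:
        return MappingResult(
            None, mapping, np.inf, False, None, None,
            message=f"refinement failed during feasibility restoration: {err}",
        )
    report = check_limits(robot, jt) if len(jt) >= 2 else None
    util = report.velocity_utilization if report else np.zeros(6)
    refined = MappingResult(
        joint_trajectory=jt,
        mapping=mapping,
        objective_value=objective(np.concatenate([jt.q.ravel(), [mapping.theta], mapping.translation])),
        feasible=bool(
            (report is None or report.feasible)
            and res[:, 0].max() < FK_TOL
            and res[:, 1].max() < FK_TOL
        ),
        fk_residuals=res,
        velocity_utilization=util,
        message="gradient-based refinement",
    )
    # descent guarantee: never return something worse than the warm start
    if initial.feasible:
        init_obj = objective(
            np.concatenate(
                [jt0.q.ravel(), [initial.mapping.theta], initial.mapping.translation]
            )
        )
        if not refined.feasible or refined.objective_value > init_obj:
            return MappingResult(
                joint_trajectory=jt0,
                mapping=initial.mapping,
                objective_value=init_obj,
                feasible=True,
                fk_residuals=initial.fk_residuals,
                velocity_utilization=initial.velocity_utilization,
                message="warm start retained (refinement did not improve)",
            )
    return refined


def generate_virtual_tool_frames(
    physical: RigidTransform,
    arm_length: float = 0.30,
    rotation_increment_deg: float = 30.0,
    clamp_inset: float = 0.0254,
) -> list[RigidTransform]:
    """Physical tool frame plus 35 virtual variants (36 total).

    The humerus can be re-clamped in its cylindrical fixture at three
    positions along the shaft — about one inch distal to the humeral head
    (the as-clamped position), at midshaft, and about one inch proximal to
    the epicondyle midpoint — and rotated about its long (superior) axis in
    30 degree increments. Frame [0] is the physical frame itself (first
    clamp position, zero rotation); within each clamp position successive
    frames differ by exactly the rotation increment about the humeral axis.
    """
    n_rot = int(round(360.0 / rotation_increment_deg))
    # shaft runs along -Y (distal) from the head-centered humeral frame;
    # clamp offsets are relative to the as-clamped (first) position
    offsets = [0.0, -(arm_length / 2.0 - clamp_inset), -(arm_length - 2.0 * clamp_inset)]
    frames = []
    for d in offsets:
        for j in range(n_rot):
            alpha = np.deg2rad(rotation_increment_deg * j)
            ca, sa = np.cos(alpha), np.sin(alpha)
            ry = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
            delta = RigidTransform(ry, np.array([0.0, d, 0.0]))
            frames.append(physical @ delta)
    return frames
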