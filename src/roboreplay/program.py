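"""Waypoint subsampling, motion-program emission, and virtual execution.

Industrial controllers choke on dense 200 Hz trajectories (their look-ahead
planners slow the motion down), so dense trajectories are thinned to a
waypoint budget — by default 20% of the original points, which at 200 Hz
puts programmed points about 25 ms apart on average, matching controller
vendor guidance of roughly 24 ms. The subsampler is pose-aware: it keeps
points where the combined position/orientation curvature is highest rather
than uniformly.

The motion-program dialect is a minimal line-oriented text format (one
waypoint per line: index, six joint values in degrees, segment speed in
mm/s, smoothness 0-100) standing in for vendor languages; the virtual
controller that executes it exists to exercise the verification pipeline
end-to-end and deliberately models no proprietary look-ahead behavior.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .robot import JointTrajectory, RobotModel, forward_kinematics
from .trajectory import PoseTrajectory
from .transforms import matrix_to_rotvec

__all__ = [
    "MotionProgram",
    "nonuniform_subsample",
    "emit_motion_program",
    "parse_motion_program",
    "simulate_execution",
]

ROT_WEIGHT = 0.3  # m/rad: characteristic humeral length converting angle to distance


@dataclass
class MotionProgram:
    """Joint-space waypoint program with per-segment speeds and blending."""

    joints_deg: np.ndarray  # (n, 6)
    speeds_mm_s: np.ndarray  # (n-1,) per-segment linear tool speed
    smoothness: np.ndarray  # (n,) int 0..100
    rate: float  # native rate of the source trajectory, Hz
    times_s: np.ndarray = field(default=None)  # waypoint times in source clock

    def __post_init__(self) -> None:
        self.joints_deg = np.asarray(self.joints_deg, dtype=float)
        self.speeds_mm_s = np.asarray(self.speeds_mm_s, dtype=float)
        self.smoothness = np.asarray(self.smoothness, dtype=int)
        if len(self.joints_deg) < 2:
            raise ValueError("a program needs at least 2 waypoints")
        if len(self.speeds_mm_s) != len(self.joints_deg) - 1:
            raise ValueError("need one speed per segment")
        if np.any(self.speeds_mm_s <= 0):
            raise ValueError("segment speeds must be positive")
        if np.any((self.smoothness < 0) | (self.smoothness > 100)):
            raise ValueError("smoothness must be in [0, 100]")
        if self.times_s is None:
            self.times_s = np.zeros(len(self.joints_deg))
        else:
            self.times_s = np.asarray(self.times_s, dtype=float)


def _pose_deviation(
    translations: np.ndarray,
    rotations_obj: Rotation,
    i: int,
    j: int,
) -> tuple[float, int]:
    """Max combined deviation of interior points from the (i, j) chord.

    Interior points are compared against linear position interpolation and
    orientation slerp; deviation = ||dp|| + ROT_WEIGHT * geodesic angle.
    Returns (max deviation, argmax index); (0, -1) when no interior points.
    """
    if j - i < 2:
        return 0.0, -1
    idx = np.arange(i + 1, j)
    frac = (idx - i) / (j - i)
    p_interp = translations[i] + np.outer(frac, translations[j] - translations[i])
    slerp = Slerp([0.0, 1.0], rotations_obj[[i, j]])
    r_interp = slerp(frac)
    dp = np.linalg.norm(translations[idx] - p_interp, axis=1)
    dr = (rotations_obj[idx].inv() * r_interp).magnitude()
    d = dp + ROT_WEIGHT * dr
    a = int(np.argmax(d))
    return float(d[a]), idx[a]


def nonuniform_subsample(traj: PoseTrajectory, keep_fraction: float) -> np.ndarray:
    """Pose-aware thinning to exactly ``round(f * N)`` indices.

    Greedy max-deviation insertion (adaptive Ramer-Douglas-Peucker with the
    combined position+orientation metric): starting from the endpoints, the
    interior point farthest from the interpolated kept path is inserted
    until the budget is reached, so kept-point density concentrates where
    the trajectory bends. Ties in deviation fall back to the longest gap,
    which reduces near-straight trajectories to near-uniform spacing.
    """
    n = len(traj)
    if n < 3:
        raise ValueError("need at least 3 timepoints to subsample")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    budget = int(round(keep_fraction * n))
    if budget < 2:
        raise ValueError(f"keep_fraction {keep_fraction} keeps fewer than 2 of {n} points")
    if budget >= n:
        return np.arange(n)
    rot = Rotation.from_matrix(traj.rotations)
    kept = [0, n - 1]
    target_gap = (n - 1) / (budget - 1)  # uniform spacing at this budget
    # segment table keyed by (deviation, gap length)
    segs: dict[tuple[int, int], tuple[float, int]] = {
        (0, n - 1): _pose_deviation(traj.translations, rot, 0, n - 1)
    }
    eps = 1e-12
    while len(kept) < budget:
        # numerically-zero deviations are true ties: fall through to gap size
        (i, j), (dev, arg) = max(
            segs.items(),
            key=lambda kv: (kv[1][0] if kv[1][0] > eps else 0.0, kv[0][1] - kv[0][0]),
        )
        if arg < 0 or dev <= eps:
            # zero-curvature stretch: bisect in whole multiples of the
            # uniform spacing so straight segments come out near-uniform
            gap = j - i
            m = max(2, int(round(gap / target_gap)))
            arg = i + int(round((m // 2) * gap / m))
            arg = min(max(arg, i + 1), j - 1)
        kept.append(arg)
        del segs[(i, j)]
        segs[(i, arg)] = _pose_deviation(traj.translations, rot, i, arg)
        segs[(arg, j)] = _pose_deviation(traj.translations, rot, arg, j)
    return np.array(sorted(kept))


def max_chord_deviation(traj: PoseTrajectory, indices: np.ndarray) -> float:
    """Max combined deviation of discarded points from the kept path."""
    rot = Rotation.from_matrix(traj.rotations)
    worst = 0.0
    for i, j in zip(indices[:-1], indices[1:]):
        d, _ = _pose_deviation(traj.translations, rot, int(i), int(j))
        worst = max(worst, d)
    return worst


def emit_motion_program(
    joint_traj: JointTrajectory,
    pose_traj: PoseTrajectory,
    indices: np.ndarray,
    smoothness: int = 100,
) -> tuple[MotionProgram, str]:
    """Build a program from retained indices and render its text form.

    Per-segment speed is the tool-point distance between retained poses
    divided by their time separation. Endpoints always get smoothness 0
    (fine positioning), interior waypoints the supplied blend value.
    """
    indices = np.asarray(indices, dtype=int)
    if len(indices) < 2 or np.any(np.diff(indices) <= 0):
        raise ValueError("indices must be sorted, unique, and at least 2")
    t = indices / joint_traj.rate
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("zero time delta between waypoints")
    dp = np.linalg.norm(np.diff(pose_traj.translations[indices], axis=0), axis=1)
    speeds = np.maximum(dp / dt * 1000.0, 0.1)  # mm/s, floored for pure rotations
    smooth = np.full(len(indices), int(smoothness))
    smooth[0] = smooth[-1] = 0
    program = MotionProgram(
        joints_deg=np.rad2deg(joint_traj.q[indices]),
        speeds_mm_s=speeds,
        smoothness=smooth,
        rate=joint_traj.rate,
        times_s=t,
    )
    return program, render_program(program)


def render_program(program: MotionProgram) -> str:
    buf = io.StringIO()
    buf.write(f"# roboreplay motion program; rate_hz={program.rate:.12g}\n")
    buf.write("# idx j1..j6[deg] time_s speed_mm_s smoothness\n")
    for k in range(len(program.joints_deg)):
        joints = " ".join(f"{v:.12g}" for v in program.joints_deg[k])
        speed = program.speeds_mm_s[k - 1] if k > 0 else 0.0
        buf.write(
            f"{k} {joints} {program.times_s[k]:.12g} {speed:.12g} {program.smoothness[k]}\n"
        )
    return buf.getvalue()


def parse_motion_program(text: str) -> MotionProgram:
    rate = 200.0
    joints, times, speeds, smooth = [], [], [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "rate_hz=" in line:
                rate = float(line.split("rate_hz=")[1].split()[0])
            continue
        parts = line.split()
        if len(parts) != 10:
            raise ValueError(f"malformed program line: {line!r}")
        joints.append([float(v) for v in parts[1:7]])
        times.append(float(parts[7]))
        speeds.append(float(parts[8]))
        smooth.append(int(parts[9]))
    if len(joints) < 2:
        raise ValueError("program has fewer than 2 waypoints")
    return MotionProgram(
        joints_deg=np.array(joints),
        speeds_mm_s=np.array(speeds[1:]),
        smoothness=np.array(smooth),
        rate=rate,
        times_s=np.array(times),
    )


@dataclass
class ControllerParams:
    """Virtual-controller knobs (all deliberately simple, no look-ahead)."""

    max_blend_s: float = 0.05  # corner-rounding window at smoothness 100
    tracking_lag_s: float = 0.0  # extra first-order lag, for degradation studies


def simulate_execution(
    program: MotionProgram,
    robot: RobotModel,
    tool=None,
    params: ControllerParams | None = None,
    output_rate: float = 200.0,
) -> tuple[JointTrajectory, PoseTrajectory]:
    """Execute a program on a virtual controller.

    Joint motion is piecewise linear between waypoints at the programmed
    segment timing, stretched wherever a segment would exceed a joint
    velocity limit (the robot saturates and arrives late). Corners are
    blended by a moving-average window proportional to the waypoint
    smoothness value — the box filter of a piecewise-linear profile yields
    exactly trapezoidal velocity transitions. Endpoints are held briefly so
    the achieved trajectory coincides with the first and last waypoints.
    Returns the achieved joint trajectory and the achieved tool (or flange)
    pose trajectory resampled at ``output_rate``.
    """
    params = params or ControllerParams()
    q_wp = np.deg2rad(program.joints_deg)
    lo, hi = robot.joint_limits[:, 0], robot.joint_limits[:, 1]
    if np.any(q_wp < lo - 1e-9) or np.any(q_wp > hi + 1e-9):
        raise ValueError("program contains waypoints outside joint limits")
    # segment durations: programmed timing (or speed/distance when no timing
    # metadata), stretched under joint velocity saturation
    dt_prog = np.diff(program.times_s)
    durations = np.empty_like(dt_prog, dtype=float)
    for k in range(len(durations)):
        planned = dt_prog[k]
        if planned <= 0:  # derive from the commanded tool speed
            p0 = forward_kinematics(robot, q_wp[k])
            p1 = forward_kinematics(robot, q_wp[k + 1])
            if tool is not None:
                p0, p1 = p0 @ tool, p1 @ tool
            dist_mm = np.linalg.norm(p1.translation - p0.translation) * 1000.0
            planned = max(dist_mm / program.speeds_mm_s[k], 1e-4)
        dq = np.abs(q_wp[k + 1] - q_wp[k])
        t_min = float(np.max(dq / robot.velocity_limits))
        durations[k] = max(planned, t_min)
    t_wp = np.concatenate([[0.0], np.cumsum(durations)])
    # dense piecewise-linear joint profile
    dt = 1.0 / output_rate
    smooth_frac = float(np.max(program.smoothness[1:-1], initial=0)) / 100.0
    window_s = smooth_frac * min(params.max_blend_s, float(durations.min()))
    pad = window_s + params.tracking_lag_s * 4.0 + dt
    n_total = int(np.ceil(t_wp[-1] / dt - 1e-12))
    n_pad = int(np.ceil(pad / dt))
    # grid aligned so a sample lands at (or just past) the final waypoint
    t_dense = (np.arange(-n_pad, n_total + n_pad + 1)) * dt
    q_dense = np.empty((len(t_dense), 6))
    for i in range(6):
        q_dense[:, i] = np.interp(t_dense, t_wp, q_wp[:, i])
    if window_s > dt:
        w = max(int(round(window_s / dt)), 1)
        kernel = np.ones(2 * (w // 2) + 1)
        kernel /= kernel.sum()
        for i in range(6):
            q_dense[:, i] = np.convolve(q_dense[:, i], kernel, mode="same")
    if params.tracking_lag_s > 0:
        a = dt / (params.tracking_lag_s + dt)
        for i in range(6):
            y = q_dense[0, i]
            for k in range(len(t_dense)):
                y += a * (q_dense[k, i] - y)
                q_dense[k, i] = y
    keep = (t_dense >= -1e-12) & (t_dense <= n_total * dt + 1e-12)
    q_out = q_dense[keep]
    # fine positioning at endpoints (smoothness 0 there by construction)
    q_out[0] = q_wp[0]
    q_out[-1] = q_wp[-1]
    jt = JointTrajectory(output_rate, q_out)
    poses = []
    for q in q_out:
        fk = forward_kinematics(robot, q)
        poses.append(fk if tool is None else fk @ tool)
    achieved = PoseTrajectory.from_transforms(output_rate, poses, source_frame="R", body_frame="H")
    return jt, achieved
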