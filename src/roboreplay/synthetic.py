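"""Synthetic humeral trajectories, tracker noise, and calibration fixtures.

The generator emulates the *statistical shape* of skin-marker humeral
kinematics for four activity archetypes — jumping jack, jogging, jug lift,
and rapid internal rotation — as sums of low-frequency sinusoids with
activity-appropriate position/orientation spans and speeds. It reproduces
smoothness, spans and rates (the properties the downstream pipeline contracts
depend on), not individual subjects or soft-tissue artefact.

Gravity points along -Z of the motion-capture frame (data contract shared
with the robot frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import CalibrationSet
from .trajectory import PoseTrajectory
from .transforms import RigidTransform, rotvec_to_matrix

__all__ = [
    "ActivityParams",
    "ACTIVITY_TABLE",
    "generate_activity",
    "add_optical_noise",
    "make_calibration_fixture",
]

ACTIVITIES = ("jumping_jack", "jogging", "jug_lift", "internal_rotation")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-axis amplitude/frequency envelope of one activity archetype.

    ``pos_amp`` (m) and ``rot_amp`` (rad) are per-axis base amplitudes of the
    dominant sinusoid (axes: X anterior, Y lateral, Z superior of the
    motion-capture frame); ``freq`` is its frequency in Hz; ``drift`` (m) is a
    monotone translation completed over the trial (jogging's forward travel).
    ``rot_axis_hint`` names the dominant rotation axis for readability.
    """

    pos_amp: tuple[float, float, float]
    rot_amp: tuple[float, float, float]
    freq: float
    duration: float
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rot_axis_hint: str = ""


# Defaults express the activities' qualitative signatures: jumping jacks are
# a large arm-elevation oscillation within a compact volume; jogging combines
# a long anterior travel with moderate oscillation; jug lifts are slow,
# large-amplitude bending-plane rotations (peak angular speed kept at or
# below ~30 deg/s); internal rotation is a fast axial twist with almost no
# translation.
ACTIVITY_TABLE: dict[str, ActivityProfile] = {
    "jumping_jack": ActivityProfile(
        pos_amp=(0.04, 0.10, 0.15),
        rot_amp=(1.10, 0.15, 0.10),
        freq=0.55,
        duration=4.0,
        rot_axis_hint="elevation (about anterior axis)",
    ),
    "jogging": ActivityProfile(
        pos_amp=(0.05, 0.03, 0.05),
        rot_amp=(0.25, 0.35, 0.15),
        freq=1.30,
        duration=1.6,
        drift=(0.45, 0.0, 0.0),
        rot_axis_hint="flexion (about lateral axis)",
    ),
    "jug_lift": ActivityProfile(
        pos_amp=(0.10, 0.02, 0.12),
        rot_amp=(0.05, 0.80, 0.04),
        freq=0.05,
        duration=10.0,
        rot_axis_hint="bending plane (about lateral axis)",
    ),
    "internal_rotation": ActivityProfile(
        pos_amp=(0.004, 0.004, 0.003),
        rot_amp=(0.05, 0.05, 1.00),
        freq=1.50,
        duration=3.0,
        rot_axis_hint="axial (about superior axis)",
    ),
}


@dataclass
class ActivityParams:
    activity: str
    duration: float | None = None
    rate: float = 200.0
    seed: int = 0
    amplitude_scale: float = 1.0
    base_translation: tuple[float, float, float] = (0.45, 0.0, 0.55)
    profile_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_TABLE:
            raise ValueError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )

    def profile(self) -> ActivityProfile:
        base = ACTIVITY_TABLE[self.activity]
        if not self.profile_overrides:
            return base
        fields_ = {k: getattr(base, k) for k in base.__dataclass_fields__}
        fields_.update(self.profile_overrides)
        return ActivityProfile(**fields_)


def _smooth_channels(
    rng: np.random.Generator,
    t: np.ndarray,
    amps: np.ndarray,
    freq: float,
    duration: float,
) -> np.ndarray:
    """Sum of a dominant sinusoid plus two weaker harmonics per axis.

    Phases are randomized; a smooth cosine envelope takes every channel to
    zero value/velocity at both ends so trials start and finish at rest.
    """
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(t / duration, 0, 1)))
    out = np.zeros((len(t), 3))
    for ax in range(3):
        y = np.zeros_like(t)
        for harmonic, rel in ((1.0, 1.0), (2.0, 0.25), (3.0, 0.10)):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            jitter = rng.uniform(0.9, 1.1)
            y += amps[ax] * rel * np.sin(2.0 * np.pi * freq * harmonic * jitter * t + phase)
        out[:, ax] = y * envelope
    return out


def generate_activity(params: ActivityParams) -> tuple[PoseTrajectory, RigidTransform]:
    """Generate one synthetic trial: humeral MC-frame trajectory + thorax pose.

    Deterministic given ``params.seed``. Returns ``(trajectory,
    initial_thorax_pose)``; the thorax is a fixed pose near the trajectory
    start whose axes serve as the ML/AP/IS reporting frame.
    """
    prof = params.profile()
    duration = params.duration or prof.duration
    rng = np.random.default_rng(params.seed)
    n = int(round(duration * params.rate)) + 1
    t = np.arange(n) / params.rate

    pos = _smooth_channels(rng, t, params.amplitude_scale * np.asarray(prof.pos_amp), prof.freq, duration)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.clip(t / duration, 0, 1)))  # 0 -> 1, zero end slopes
    pos += np.outer(ramp, prof.drift)
    pos += np.asarray(params.base_translation)

    rv = _smooth_channels(rng, t, params.amplitude_scale * np.asarray(prof.rot_amp), prof.freq, duration)
    rots = np.stack([rotvec_to_matrix(v) for v in rv])

    traj = PoseTrajectory(params.rate, rots, pos, source_frame="MC", body_frame="H")
    thorax_rot = rotvec_to_matrix(rng.normal(scale=0.05, size=3))
    thorax = RigidTransform(thorax_rot, pos[0] + np.array([0.0, 0.0, -0.25]))
    return traj, thorax


def _fit_pose_to_markers(body_pts: np.ndarray, world_pts: np.ndarray) -> RigidTransform:
    """Kabsch/Procrustes rigid fit of a marker constellation (SVD)."""
    bc = body_pts.mean(axis=0)
    wc = world_pts.mean(axis=0)
    H = (body_pts - bc).T @ (world_pts - wc)
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(R, wc - R @ bc)


def _constellation(n_markers: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform marker constellation on a hemisphere."""
    k = np.arange(n_markers)
    phi = np.arccos(1.0 - k / max(n_markers - 1, 1))  # polar angle in [0, pi/2]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def add_optical_noise(
    traj: PoseTrajectory,
    sigma: float,
    seed: int = 0,
    constellation_radius: float = 0.05,
    n_markers: int = 16,
) -> PoseTrajectory:
    """Optical-tracker noise model applied to a pose trajectory.

    Translations receive isotropic Gaussian noise of SD ``sigma`` (m) — the
    tracker's stated point accuracy. Orientation noise is propagated from
    marker level: each pose's rotation is re-fit from a virtual centered
    rigid marker constellation (default: 16 markers on a 50 mm hemisphere,
    matching a tracking rigid body) whose marker positions are perturbed by
    the same sigma, so angular noise is ~sigma/(radius*sqrt(n)) and shrinks
    with constellation radius as real tracking rigid bodies do.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return PoseTrajectory(
            traj.rate, traj.rotations.copy(), traj.translations.copy(),
            traj.source_frame, traj.body_frame,
        )
    rng = np.random.default_rng(seed)
    body_pts = _constellation(n_markers, constellation_radius)
    body_pts = body_pts - body_pts.mean(axis=0)  # rotation-only sensitivity
    rots = np.empty_like(traj.rotations)
    for k in range(len(traj)):
        world = body_pts @ traj.rotations[k].T + rng.normal(scale=sigma, size=body_pts.shape)
        rots[k] = _fit_pose_to_markers(body_pts, world).rotation
    trans = traj.translations + rng.normal(scale=sigma, size=traj.translations.shape)
    return PoseTrajectory(traj.rate, rots, trans, traj.source_frame, traj.body_frame)


def make_calibration_fixture(
    true_R_OT: np.ndarray,
    true_EE_T_HS: RigidTransform,
    n_poses: int = 20,
    seed: int = 0,
    sigma: float = 0.0,
    constellation_radius: float = 0.05,
    n_markers: int = 16,
    degenerate: bool = False,
) -> CalibrationSet:
    """Synthetic calibration pose pairs with known ground truth.

    Robot flange poses are sampled with rotation axes spanning 3D (or, when
    ``degenerate`` is set, sharing a single axis — a known unidentifiable
    configuration for testing error paths). Tracked poses are constructed
    from the ground truth; marker-level Gaussian noise of SD ``sigma`` (m) is
    injected through the same virtual-constellation model as
    :func:`add_optical_noise`. Robot poses are treated as exact (industrial
    repeatability is an order of magnitude below tracker noise).
    """
    if n_poses < 3 and not degenerate:
        raise ValueError("need at least 3 calibration poses")
    rng = np.random.default_rng(seed)
    R_OT = np.asarray(true_R_OT, dtype=float)
    OT_T_R = RigidTransform(R_OT, np.array([0.3, -0.2, 0.1])).invert()
    body_pts = _constellation(n_markers, constellation_radius)
    robot_poses, tracked_poses = [], []
    for i in range(n_poses):
        if degenerate:
            rv = np.array([0.0, 0.0, 0.3 + 0.2 * i])
        else:
            rv = rng.uniform(-1.2, 1.2, size=3)
        t = np.array([1.0, 0.0, 0.8]) + rng.uniform(-0.25, 0.25, size=3)
        r_t_ee = RigidTransform(rotvec_to_matrix(rv), t)
        ot_t_hs = OT_T_R @ r_t_ee @ true_EE_T_HS
        if sigma > 0.0:
            centered = body_pts - body_pts.mean(axis=0)
            world = centered @ ot_t_hs.rotation.T + rng.normal(scale=sigma, size=centered.shape)
            ot_t_hs = RigidTransform(
                _fit_pose_to_markers(centered, world).rotation,
                ot_t_hs.translation + rng.normal(scale=sigma, size=3),
            )
        robot_poses.append(r_t_ee)
        tracked_poses.append(ot_t_hs)
    return CalibrationSet(robot_poses, tracked_poses)
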