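"""Pose-trajectory container, filtering, differentiation, ramps, and CSV I/O.

A :class:`PoseTrajectory` is a uniformly sampled sequence of rigid-body poses
(200 Hz is the motion-capture native rate used throughout). Derivatives follow
the verification convention: orientations are converted to unwrapped rotation
vectors, components are low-pass filtered once with a zero-phase Butterworth
filter, then differentiated by central differences — once for velocity, a
second time for acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .transforms import (
    RigidTransform,
    matrix_to_rotvec,
    orthonormalize,
    rotvec_to_matrix,
    unwrap_rotvecs,
)

__all__ = [
    "PoseTrajectory",
    "KinematicDerivatives",
    "lowpass_filter",
    "derive_kinematics",
    "constant_jerk_ramp",
    "normalize_to_first_waypoint",
]

_CSV_COLUMNS = [
    "time_s",
    "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
    "tx_m", "ty_m", "tz_m",
]


@dataclass
class PoseTrajectory:
    """Uniformly sampled rigid-body pose trajectory.

    Parameters
    ----------
    rate : float
        Sampling rate in Hz.
    rotations : (n, 3, 3) array
        Per-timepoint rotation matrices (body frame in source frame).
    translations : (n, 3) array
        Per-timepoint translations in meters.
    source_frame, body_frame : str
        Frame labels, e.g. ``"MC"`` and ``"H"``.
    """

    rate: float
    rotations: np.ndarray
    translations: np.ndarray
    source_frame: str = "MC"
    body_frame: str = "H"

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n, 3, 3)")
        if self.translations.shape != (self.rotations.shape[0], 3):
            raise ValueError("translations must have shape (n, 3)")
        if len(self) < 1:
            raise ValueError("trajectory needs at least one timepoint")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.rotations.shape[0]

    def __getitem__(self, k: int) -> RigidTransform:
        return RigidTransform(self.rotations[k], self.translations[k], validate=False)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate

    @classmethod
    def from_transforms(
        cls,
        rate: float,
        poses: list[RigidTransform],
        source_frame: str = "MC",
        body_frame: str = "H",
    ) -> "PoseTrajectory":
        return cls(
            rate,
            np.stack([p.rotation for p in poses]),
            np.stack([p.translation for p in poses]),
            source_frame,
            body_frame,
        )

    def rotvecs(self, unwrap: bool = True) -> np.ndarray:
        """Per-timepoint rotation vectors, branch-unwrapped for continuity."""
        v = np.stack([matrix_to_rotvec(r) for r in self.rotations])
        return unwrap_rotvecs(v) if unwrap else v

    def transformed(self, world: RigidTransform, source_frame: str | None = None) -> "PoseTrajectory":
        """Left-multiply every pose by ``world`` (re-express in a new frame)."""
        return PoseTrajectory(
            self.rate,
            np.einsum("ij,njk->nik", world.rotation, self.rotations),
            self.translations @ world.rotation.T + world.translation,
            source_frame or self.source_frame,
            self.body_frame,
        )

    def slice(self, start: int, stop: int) -> "PoseTrajectory":
        return PoseTrajectory(
            self.rate,
            self.rotations[start:stop],
            self.translations[start:stop],
            self.source_frame,
            self.body_frame,
        )

    # -- CSV schema: time_s, r11..r33 (row-major), tx_m, ty_m, tz_m ---------

    def to_csv(self, path) -> None:
        n = len(self)
        data = np.column_stack(
            [self.timestamps, self.rotations.reshape(n, 9), self.translations]
        )
        pd.DataFrame(data, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, source_frame: str = "MC", body_frame: str = "H") -> "PoseTrajectory":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            rate = 200.0
        else:
            dt = np.diff(t)
            rate = 1.0 / np.median(dt)
            if np.abs(dt - 1.0 / rate).max() > 1e-6:
                raise ValueError("trajectory CSV is not uniformly sampled")
        rots = df[_CSV_COLUMNS[1:10]].to_numpy().reshape(-1, 3, 3)
        # tolerate mild round-off from text serialization, then re-project
        for k, r in enumerate(rots):
            err = np.abs(r @ r.T - np.eye(3)).max()
            if err > 1e-6:
                raise ValueError(f"row {k}: rotation not orthonormal (err {err:.3g})")
            rots[k] = orthonormalize(r)
        return cls(rate, rots, df[["tx_m", "ty_m", "tz_m"]].to_numpy(), source_frame, body_frame)


@dataclass
class KinematicDerivatives:
    """First and second derivatives of a pose trajectory.

    Angular quantities are rates of the unwrapped rotation-vector components
    (the verification-metric convention), not body angular velocity.
    """

    rate: float
    position: np.ndarray
    rotvec: np.ndarray
    linear_velocity: np.ndarray
    angular_velocity: np.ndarray
    linear_acceleration: np.ndarray
    angular_acceleration: np.ndarray

    @property
    def linear_speed(self) -> np.ndarray:
        return np.linalg.norm(self.linear_velocity, axis=1)

    @property
    def angular_speed(self) -> np.ndarray:
        return np.linalg.norm(self.angular_velocity, axis=1)

    @property
    def linear_acceleration_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.linear_acceleration, axis=1)

    @property
    def angular_acceleration_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.angular_acceleration, axis=1)


def lowpass_filter(
    data: np.ndarray,
    rate: float,
    cutoff: float,
    order: int = 4,
    bidirectional: bool = True,
) -> np.ndarray:
    """Zero-phase (bidirectional) Butterworth low-pass along axis 0.

    The bidirectional pass squares the magnitude response, so a 4th-order
    design attenuates like an 8th-order filter while adding no phase lag.
    """
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2.0} Hz)")
    sos = signal.butter(order, cutoff, fs=rate, output="sos")
    data = np.asarray(data, dtype=float)
    if bidirectional:
        # pad several filter time-constants so edge transients (and slow
        # trends such as jogging's forward travel) are not distorted
        padlen = min(data.shape[0] - 2, max(24, int(3 * rate / cutoff)))
        return signal.sosfiltfilt(sos, data, axis=0, padlen=padlen)
    return signal.sosfilt(sos, data, axis=0)


def derive_kinematics(traj: PoseTrajectory, cutoff: float = 8.0, order: int = 4) -> KinematicDerivatives:
    """Filter once, then differentiate twice by central differences.

    Positions and unwrapped rotation-vector components are smoothed with a
    zero-phase Butterworth filter (default 8 Hz, 4th order), then
    differentiated at the native rate; endpoints use one-sided differences.
    """
    if len(traj) < 5:
        raise ValueError("need at least 5 timepoints to differentiate")
    dt = 1.0 / traj.rate
    pos = lowpass_filter(traj.translations, traj.rate, cutoff, order)
    rv = lowpass_filter(traj.rotvecs(), traj.rate, cutoff, order)
    vel_p = np.gradient(pos, dt, axis=0)
    vel_r = np.gradient(rv, dt, axis=0)
    acc_p = np.gradient(vel_p, dt, axis=0)
    acc_r = np.gradient(vel_r, dt, axis=0)
    return KinematicDerivatives(traj.rate, pos, rv, vel_p, vel_r, acc_p, acc_r)


def _quartic_ramp_components(p: np.ndarray, v: np.ndarray, a: np.ndarray, n_points: int, rate: float) -> np.ndarray:
    """Quartic per component: rest end (t=0) has zero vel/acc, junction end
    (t=T) matches position p, velocity v, acceleration a. Returns (n, dim)
    samples covering [0, T) — the junction sample itself is excluded so the
    ramp concatenates with the trajectory without duplication."""
    T = n_points / rate
    t = np.arange(n_points) / rate
    # f(t) = c0 + c1 t + c2 t^2 + c3 t^3 + c4 t^4 with f'(0)=f''(0)=0 -> c1=c2=0
    # remaining: f(T)=p, f'(T)=v, f''(T)=a
    A = np.array(
        [
            [1.0, T**3, T**4],
            [0.0, 3 * T**2, 4 * T**3],
            [0.0, 6 * T, 12 * T**2],
        ]
    )
    rhs = np.stack([p, v, a])  # (3, dim)
    coef = np.linalg.solve(A, rhs)  # rows: c0, c3, c4
    return coef[0] + np.outer(t**3, coef[1]) + np.outer(t**4, coef[2])


def constant_jerk_ramp(
    junction_pose: RigidTransform,
    junction_velocity: np.ndarray,
    junction_acceleration: np.ndarray,
    n_points: int = 30,
    rate: float = 200.0,
    direction: str = "ramp-up",
) -> PoseTrajectory:
    """Quartic ramp-up / slow-down segment joining rest to a moving junction.

    ``junction_velocity``/``junction_acceleration`` are 6-vectors: linear
    (m/s, m/s^2) stacked with rotation-vector rates (rad/s, rad/s^2) expressed
    as world-frame offsets relative to the junction orientation. The segment
    spans ``n_points`` samples (default 30 at 200 Hz = 0.15 s); the rest end
    has zero velocity and acceleration.
    """
    if n_points < 2:
        raise ValueError("ramp needs at least 2 points")
    v = np.asarray(junction_velocity, dtype=float).reshape(6)
    a = np.asarray(junction_acceleration, dtype=float).reshape(6)
    p = np.concatenate([junction_pose.translation, np.zeros(3)])
    if direction == "ramp-up":
        comps = _quartic_ramp_components(p, v, a, n_points, rate)  # (n, 6)
    elif direction == "slow-down":
        # time reversal of a ramp-up flips first derivatives, keeps second
        comps = _quartic_ramp_components(p, -v, a, n_points, rate)[::-1]
    else:
        raise ValueError("direction must be 'ramp-up' or 'slow-down'")
    rots = np.stack(
        [rotvec_to_matrix(c[3:]) @ junction_pose.rotation for c in comps]
    )
    return PoseTrajectory(rate, rots, comps[:, :3], "MC", "H")


def normalize_to_first_waypoint(traj: PoseTrajectory) -> PoseTrajectory:
    """Subtract the first translation from every waypoint (rotations kept).

    Translating a whole trajectory does not alter its kinetics, so this is a
    pure readability normalization for desired-vs-achieved comparisons.
    """
    return PoseTrajectory(
        traj.rate,
        traj.rotations.copy(),
        traj.translations - traj.translations[0],
        traj.source_frame,
        traj.body_frame,
    )
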