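"""Desired-vs-achieved agreement metrics for kinematics and kinetics.

The achieved trajectory is reconstructed from optical tracking through the
session calibration, temporally aligned to the desired trajectory by
cross-correlation, re-expressed along the subject's initial thorax axes
(mediolateral / anterior-posterior / inferior-superior), and scored by the
span-normalized mean absolute error: MAE divided by (max - min) of the
desired signal, per axis and for the Euclidean magnitude. Load agreement
additionally uses the normalized error-at-peak — the desired-vs-achieved
discrepancy at the instant of maximum desired load, divided by the desired
span — which is less noise-sensitive than a whole-trace MAE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import (
    KinematicDerivatives,
    PoseTrajectory,
    derive_kinematics,
    normalize_to_first_waypoint,
)
from .transforms import RigidTransform

__all__ = [
    "ComparisonReport",
    "achieved_from_tracking",
    "temporal_align",
    "normalized_mae",
    "error_at_peak",
    "compare_trajectories",
]

AXIS_LABELS = ("ML", "AP", "IS", "norm")


class AlignmentUndefinedError(ValueError):
    """Signals with no variance cannot be aligned by cross-correlation."""


def achieved_from_tracking(
    tracked: PoseTrajectory,
    R_OT: np.ndarray,
    HS_T_H: RigidTransform,
) -> PoseTrajectory:
    """Humerus-in-robot-frame trajectory from tracked rigid-body poses.

    Per timepoint: A_R_T_H = [R_OT | 0] . OT_T_HS . HS_T_H — the tracker-to-
    robot embedding is rotation-only because all metrics are translation-
    normalized to the first waypoint.
    """
    embed = RigidTransform(np.asarray(R_OT, dtype=float), np.zeros(3))
    rots = np.einsum("ij,njk,kl->nil", embed.rotation, tracked.rotations, HS_T_H.rotation)
    trans = (
        tracked.translations + np.einsum("njk,k->nj", tracked.rotations, HS_T_H.translation)
    ) @ embed.rotation.T
    return PoseTrajectory(tracked.rate, rots, trans, source_frame="R", body_frame="H")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd < 1e-12):
        raise AlignmentUndefinedError("flat channel: temporal alignment undefined")
    return (x - x.mean(axis=0)) / sd


def temporal_align(
    desired: PoseTrajectory,
    achieved: PoseTrajectory,
    max_offset: int | None = None,
) -> int:
    """Offset (samples) of achieved relative to desired, by cross-correlation.

    All six channels (three positions, three rotation-vector components) are
    scored by their Pearson correlation over the overlap window — a per-
    window normalization, so meters and radians contribute comparably and
    partial overlaps are not biased — and the offset maximizing the summed
    correlation is chosen; ties break toward the smallest |offset|. Positive
    offset means the achieved signal lags.
    """
    d = np.hstack([desired.translations, desired.rotvecs()])
    a = np.hstack([achieved.translations, achieved.rotvecs()])
    _zscore(d)  # raises on flat channels (alignment undefined)
    _zscore(a)
    n_short = min(len(d), len(a))
    if max_offset is None:
        max_offset = n_short // 2  # keep >= 50% overlap
    best = (-np.inf, 0)
    for off in range(-max_offset, max_offset + 1):
        if off >= 0:
            dd, aa = d[off:], a[: len(d) - off]
        else:
            dd, aa = d[: len(d) + off], a[-off:]
        m = min(len(dd), len(aa))
        if m < max(n_short // 2, 3):
            continue
        dw = dd[:m] - dd[:m].mean(axis=0)
        aw = aa[:m] - aa[:m].mean(axis=0)
        denom = np.sqrt(np.sum(dw * dw, axis=0) * np.sum(aw * aw, axis=0))
        valid = denom > 1e-12
        if not np.any(valid):
            continue
        score = float(np.sum(np.sum(dw * aw, axis=0)[valid] / denom[valid]))
        if score > best[0] + 1e-12 or (
            abs(score - best[0]) <= 1e-12 and abs(off) < abs(best[1])
        ):
            best = (score, off)
    return best[1]


def _spans(x: np.ndarray) -> np.ndarray:
    return x.max(axis=0) - x.min(axis=0)


def _mae_rows(
    desired: np.ndarray, achieved: np.ndarray, floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis + magnitude normalized MAE (%), with the spans used.

    Returns arrays of length 4 (three axes then Euclidean magnitude); axes
    whose desired span is below ``floor`` are NaN (undefined), mirroring the
    span-inflation caveat for secondary axes of motion.
    """
    mae = np.abs(desired - achieved).mean(axis=0)
    span = _spans(desired)
    d_mag = np.linalg.norm(desired, axis=1)
    a_mag = np.linalg.norm(achieved, axis=1)
    mae = np.append(mae, np.abs(d_mag - a_mag).mean())
    span = np.append(span, d_mag.max() - d_mag.min())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(span > floor, mae / span * 100.0, np.nan)
    return out, span


@dataclass
class ComparisonReport:
    """Normalized MAE per variable/axis plus alignment metadata."""

    offset_samples: int
    rows: pd.DataFrame = field(default=None)  # variable, axis, mae_pct, span

    def value(self, variable: str, axis: str) -> float:
        sel = self.rows[(self.rows.variable == variable) & (self.rows.axis == axis)]
        if len(sel) != 1:
            raise KeyError(f"no unique row for ({variable}, {axis})")
        return float(sel.mae_pct.iloc[0])

    def magnitude(self, variable: str) -> float:
        return self.value(variable, "norm")


def normalized_mae(
    desired: dict[str, np.ndarray],
    achieved: dict[str, np.ndarray],
    thorax_frame: RigidTransform,
) -> pd.DataFrame:
    """Span-normalized MAE table for paired (n, 3) signal dictionaries.

    Signals are re-expressed along the initial-thorax ML/AP/IS axes (the
    thorax rotation's columns) before scoring; each variable yields four
    rows: one per axis and one for the Euclidean magnitude (which is
    rotation-invariant but normalized by the magnitude-signal span).
    """
    Rt = thorax_frame.rotation.T
    records = []
    for var, d in desired.items():
        a = achieved[var]
        if d.shape != a.shape:
            raise ValueError(f"{var}: desired {d.shape} vs achieved {a.shape}")
        d_t = d @ Rt.T
        a_t = a @ Rt.T
        vals, spans = _mae_rows(d_t, a_t)
        for axis, v, s in zip(AXIS_LABELS, vals, spans):
            records.append({"variable": var, "axis": axis, "mae_pct": v, "span": s})
    return pd.DataFrame.from_records(records)


def error_at_peak(desired: np.ndarray, achieved: np.ndarray, floor: float = 1e-12) -> float:
    """|desired(t*) - achieved(t*)| / span(desired) * 100, t* = argmax |desired|.

    No mean-centering is applied — the metric is exactly the span-normalized
    discrepancy at the instant of peak desired load.
    """
    desired = np.asarray(desired, dtype=float).ravel()
    achieved = np.asarray(achieved, dtype=float).ravel()
    if desired.shape != achieved.shape:
        raise ValueError("series must have equal length")
    span = desired.max() - desired.min()
    if span <= floor:
        raise ValueError("zero desired span: error-at-peak undefined")
    k = int(np.argmax(np.abs(desired)))
    return float(abs(desired[k] - achieved[k]) / span * 100.0)


def compare_trajectories(
    desired: PoseTrajectory,
    achieved: PoseTrajectory,
    thorax_frame: RigidTransform,
    cutoff: float = 8.0,
    align: bool = True,
) -> ComparisonReport:
    """Full kinematic comparison: align, normalize, differentiate, score.

    Both trajectories are first re-expressed in the initial-thorax frame (the
    reference frame for all metrics — this keeps rotation vectors near the
    origin, where span normalization is meaningful), translation-normalized
    to their first waypoint, temporally aligned, cropped to the overlap,
    smoothed/differentiated (8 Hz zero-phase Butterworth, central
    differences), and scored by span-normalized MAE for position,
    orientation, linear/angular velocity and linear/angular acceleration.
    ``thorax_frame`` must be expressed in the same frame as the trajectories.
    """
    thorax_inv = thorax_frame.invert()
    desired = desired.transformed(thorax_inv, source_frame="T")
    achieved = achieved.transformed(thorax_inv, source_frame="T")
    offset = temporal_align(desired, achieved) if align else 0
    if offset >= 0:
        d, a = desired.slice(offset, len(desired)), achieved
    else:
        d, a = desired, achieved.slice(-offset, len(achieved))
    m = min(len(d), len(a))
    d, a = d.slice(0, m), a.slice(0, m)
    d = normalize_to_first_waypoint(d)
    a = normalize_to_first_waypoint(a)
    kd = derive_kinematics(d, cutoff)
    ka = derive_kinematics(a, cutoff)

    def channels(k: KinematicDerivatives) -> dict[str, np.ndarray]:
        return {
            "position": k.position - k.position[0],
            "orientation": k.rotvec,
            "linear_velocity": k.linear_velocity,
            "angular_velocity": k.angular_velocity,
            "linear_acceleration": k.linear_acceleration,
            "angular_acceleration": k.angular_acceleration,
        }

    # channels are already along thorax axes; no further rotation needed
    rows = normalized_mae(channels(kd), channels(ka), RigidTransform.identity())
    return ComparisonReport(offset_samples=offset, rows=rows)
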