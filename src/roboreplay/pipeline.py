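"""End-to-end orchestration: trajectory -> robot program -> verification.

Chains the pipeline stages with the study defaults (200 Hz native rate,
20% subsampling, 8 Hz verification filter, 30-point ramps) and returns all
intermediate artifacts, so both the command-line interface and tests drive
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, mapping, metrics, program, synthetic
from .robot import RobotModel, default_robot
from .trajectory import PoseTrajectory, derive_kinematics
from .transforms import RigidTransform

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Study defaults; every field is overridable."""

    subsample_fraction: float = 0.2
    verification_cutoff_hz: float = 8.0
    smoothness: int = 100
    tracker_noise_m: float = 1e-4  # optical-tracker point accuracy (0.1 mm)
    optimizer: str = "cobyla"  # or "sqp" for gradient-based refinement
    activity: str = "jug_lift"
    arm_length: float = 0.30
    seed: int = 0
    tool: RigidTransform = field(default_factory=lambda: RigidTransform(np.eye(3), np.array([0.0, 0.0, 0.10])))


@dataclass
class PipelineResult:
    mapping_result: mapping.MappingResult
    motion_program: program.MotionProgram | None
    program_text: str
    achieved: PoseTrajectory | None
    report: metrics.ComparisonReport | None
    desired_loads: dynamics.LoadTrajectory | None
    achieved_loads: dynamics.LoadTrajectory | None
    load_error_at_peak: dict[str, float] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.mapping_result.feasible


def run_pipeline(
    traj_MC: PoseTrajectory,
    thorax: RigidTransform,
    robot: RobotModel | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Optimize, subsample, emit, simulate, verify, and compute loads.

    Infeasibility (robot limits unsatisfiable for every mapping) is a valid
    scientific outcome: the result carries the infeasible mapping report and
    empty downstream artifacts rather than raising.
    """
    robot = robot or default_robot()
    cfg = config or PipelineConfig()

    mres = mapping.optimize_derivative_free(robot, traj_MC, cfg.tool)
    if mres.feasible and cfg.optimizer == "sqp":
        mres = mapping.optimize_gradient_based(robot, traj_MC, cfg.tool, mres)
    if not mres.feasible:
        return PipelineResult(mres, None, "", None, None, None, None)

    traj_R = mapping.apply_mapping(mres.mapping, traj_MC)
    indices = program.nonuniform_subsample(traj_R, cfg.subsample_fraction)
    prog, text = program.emit_motion_program(
        mres.joint_trajectory, traj_R, indices, smoothness=cfg.smoothness
    )
    _, achieved = program.simulate_execution(prog, robot, tool=cfg.tool, output_rate=traj_MC.rate)
    if cfg.tracker_noise_m > 0:
        # the achieved trajectory is measured through the optical tracker
        achieved = synthetic.add_optical_noise(achieved, cfg.tracker_noise_m, seed=cfg.seed)

    thorax_R = mres.mapping.transform() @ thorax  # thorax pose in robot frame
    report = metrics.compare_trajectories(
        traj_R, achieved, thorax_R, cutoff=cfg.verification_cutoff_hz
    )

    # kinetics on desired and achieved kinematics, compared at peak
    model = dynamics.build_prosthesis_model(cfg.arm_length, cfg.activity)
    n = min(len(traj_R), len(achieved))
    d_traj, a_traj = traj_R.slice(0, n), achieved.slice(0, n)
    d_loads = dynamics.rnea_loads(model, d_traj, derive_kinematics(d_traj, cfg.verification_cutoff_hz))
    a_loads = dynamics.rnea_loads(model, a_traj, derive_kinematics(a_traj, cfg.verification_cutoff_hz))
    eap = {}
    for name in ("axial_force", "torsional_moment", "bending_moment"):
        d = getattr(d_loads, name)
        a = getattr(a_loads, name)
        if d.max() - d.min() > 1e-9:
            eap[name] = metrics.error_at_peak(d, a)
    return PipelineResult(mres, prog, text, achieved, report, d_loads, a_loads, eap)


def loads_to_frame(loads: dynamics.LoadTrajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": np.arange(len(loads)) / loads.rate,
            "fx_n": loads.force[:, 0],
            "fy_n": loads.force[:, 1],
            "fz_n": loads.force[:, 2],
            "mx_nm": loads.moment[:, 0],
            "my_nm": loads.moment[:, 1],
            "mz_nm": loads.moment[:, 2],
            "axial_n": loads.axial_force,
            "torsion_nm": loads.torsional_moment,
            "bending_nm": loads.bending_moment,
        }
    )
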