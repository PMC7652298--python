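"""Prosthesis model assembly and recursive Newton-Euler interface loads."""

import numpy as np
import pytest

from roboreplay.dynamics import (
    GRAVITY,
    build_prosthesis_model,
    gravitational_fraction,
    project_loads,
    rnea_loads,
)
from roboreplay.synthetic import ActivityParams, generate_activity
from roboreplay.trajectory import PoseTrajectory, derive_kinematics
from roboreplay.transforms import rotation_about_axis


def _static_traj(rotation, n=50, rate=200.0):
    rots = np.tile(rotation, (n, 1, 1))
    return PoseTrajectory(rate, rots, np.zeros((n, 3)))


class TestBuildModel:
    def test_connection_dimensions_from_arm_length(self):
        model = build_prosthesis_model(0.30, "jogging")
        conn = model.segments[0]
        assert conn.length == pytest.approx(0.225)
        assert conn.mass == pytest.approx(0.50823 * 0.225 + 0.3)  # 0.414 kg
        assert model.elbow_angle_deg == 90.0
        assert [s.name for s in model.segments] == ["connection", "forearm", "hand"]

    def test_jug_lift_gets_jug_and_straight_elbow(self):
        model = build_prosthesis_model(0.30, "jug_lift")
        assert model.elbow_angle_deg == 180.0
        jug = model.segments[-1]
        assert jug.name == "jug"
        assert jug.mass == pytest.approx(3.800)
        # 180 deg extension: everything collinear along the shaft (-Y)
        for seg in model.segments:
            assert np.allclose(np.abs(seg.axis), [0, 1, 0])

    def test_elbow_angles_per_activity(self):
        assert build_prosthesis_model(0.3, "jumping_jack").elbow_angle_deg == 135.0
        assert build_prosthesis_model(0.3, "internal_rotation").elbow_angle_deg == 90.0

    def test_unknown_activity_rejected(self):
        with pytest.raises(ValueError):
            build_prosthesis_model(0.3, "underhand_toss")


class TestRneaLoads:
    def test_stationary_zero_gravity_gives_zero_wrench(self):
        traj = _static_traj(np.eye(3))
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jogging")
        loads = rnea_loads(model, traj, kin, gravity=np.zeros(3))
        assert np.abs(loads.force).max() < 1e-9
        assert np.abs(loads.moment).max() < 1e-9

    def test_free_fall_gives_zero_wrench(self):
        """Equivalence principle: linear acceleration equal to gravity."""
        rate = 200.0
        t = np.arange(600) / rate
        pos = 0.5 * GRAVITY * t[:, None] ** 2
        traj = PoseTrajectory(rate, np.tile(np.eye(3), (len(t), 1, 1)), pos)
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jug_lift")
        loads = rnea_loads(model, traj, kin)
        interior = slice(150, -150)  # filter transients at the edges
        assert np.abs(loads.force[interior]).max() < 1e-3 * model.total_mass * 9.81
        assert np.abs(loads.moment[interior]).max() < 1e-3

    def test_static_horizontal_arm_matches_statics_oracle(self):
        """Arm horizontal: interface moment = sum of m*g*d lever terms."""
        # Rz(-pi/2) maps the humeral +Y (superior) axis onto world +X, so the
        # shaft (-Y) lies horizontally along -X
        rot = rotation_about_axis([0.0, 0.0, 1.0], -np.pi / 2)
        model = build_prosthesis_model(0.3, "jug_lift")
        traj = _static_traj(rot)
        kin = derive_kinematics(traj)
        loads = rnea_loads(model, traj, kin)
        # independent statics: forces m g, moments about the interface point
        f_expected = -GRAVITY * model.total_mass  # support force
        m_expected = np.zeros(3)
        p_int = rot @ model.interface_point
        for seg in model.segments:
            c = rot @ seg.centroid
            m_expected += np.cross(c - p_int, -seg.mass * GRAVITY)
        assert np.allclose(loads.force[25], f_expected, atol=1e-9)
        assert np.allclose(loads.moment[25], m_expected, atol=1e-9)
        # horizontal straight arm: pure bending, no torsion or axial force
        assert abs(loads.axial_force[25]) < 1e-9
        assert abs(loads.torsional_moment[25]) < 1e-9
        assert loads.bending_moment[25] == pytest.approx(
            np.linalg.norm(m_expected), abs=1e-9
        )

    def test_momentum_derivative_oracle(self):
        """RNEA wrench equals d/dt of summed segment momenta minus gravity."""
        traj, _ = generate_activity(ActivityParams("jumping_jack", seed=5, duration=3.0))
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jumping_jack")
        loads = rnea_loads(model, traj, kin)
        rate = traj.rate
        n = len(traj)
        # oracle: finite differences of the filtered pose trajectory
        R = np.empty_like(traj.rotations)
        from roboreplay.transforms import rotvec_to_matrix

        for k in range(n):
            R[k] = rotvec_to_matrix(kin.rotvec[k])
        p = kin.position
        P = np.zeros((n, 3))  # linear momentum
        L = np.zeros((n, 3))  # angular momentum about the world origin
        Rdot = np.gradient(R, 1.0 / rate, axis=0)
        omega_hat = np.einsum("nij,nkj->nik", Rdot, R)
        omega = np.stack(
            [omega_hat[:, 2, 1], omega_hat[:, 0, 2], omega_hat[:, 1, 0]], axis=1
        )
        for seg in model.segments:
            x = p + np.einsum("nij,j->ni", R, seg.centroid)
            v = np.gradient(x, 1.0 / rate, axis=0)
            P += seg.mass * v
            I_w = np.einsum("nij,jk,nlk->nil", R, seg.inertia_centroidal(), R)
            L += np.cross(x, seg.mass * v) + np.einsum("nij,nj->ni", I_w, omega)
        F = np.gradient(P, 1.0 / rate, axis=0) - model.total_mass * GRAVITY
        dL = np.gradient(L, 1.0 / rate, axis=0)
        r_int = p + np.einsum("nij,j->ni", R, model.interface_point)
        grav_moment = np.zeros((n, 3))
        for seg in model.segments:
            x = p + np.einsum("nij,j->ni", R, seg.centroid)
            grav_moment += np.cross(x, seg.mass * GRAVITY)
        M = dL - np.cross(r_int, F) - grav_moment
        interior = slice(50, -50)
        f_scale = np.abs(loads.force[interior]).max()
        m_scale = np.abs(loads.moment[interior]).max()
        assert np.abs(F[interior] - loads.force[interior]).max() < 0.01 * f_scale
        assert np.abs(M[interior] - loads.moment[interior]).max() < 0.01 * m_scale

    def test_load_linearity_in_mass(self):
        traj, _ = generate_activity(ActivityParams("jogging", seed=1, duration=1.5))
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jogging")
        doubled = build_prosthesis_model(0.3, "jogging")
        for seg in doubled.segments:
            object.__setattr__(seg, "mass", seg.mass * 2.0)
        a = rnea_loads(model, traj, kin)
        b = rnea_loads(doubled, traj, kin)
        assert np.allclose(b.force, 2.0 * a.force, rtol=1e-9, atol=1e-9)
        assert np.allclose(b.moment, 2.0 * a.moment, rtol=1e-9, atol=1e-9)

    def test_length_mismatch_rejected(self):
        traj, _ = generate_activity(ActivityParams("jogging", seed=1, duration=1.5))
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jogging")
        with pytest.raises(ValueError):
            rnea_loads(model, traj.slice(0, 10), kin)


class TestProjections:
    def test_axial_and_pythagorean_cases(self):
        axial, torsion, bending = project_loads([0, 0, -50.0], [3.0, 4.0, 0.0], [0, 0, 1.0])
        assert axial[0] == pytest.approx(-50.0)
        assert torsion[0] == pytest.approx(0.0, abs=1e-12)
        assert bending[0] == pytest.approx(5.0)

    def test_norm_decomposition_invariants(self, rng):
        f = rng.normal(size=3) * 100
        m = rng.normal(size=3) * 10
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        axial, torsion, bending = project_loads(f, m, a)
        inplane = np.linalg.norm(f - axial[0] * a)
        assert axial[0] ** 2 + inplane**2 == pytest.approx(f @ f, rel=1e-12)
        assert torsion[0] ** 2 + bending[0] ** 2 == pytest.approx(m @ m, rel=1e-12)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            project_loads([1, 0, 0], [0, 1, 0], [0, 0, 2.0])


class TestGravitationalFraction:
    def test_stationary_fraction_is_one(self):
        rot = rotation_about_axis([0, 0, 1], 0.5) @ rotation_about_axis([1, 0, 0], 1.2)
        traj = _static_traj(rot)
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jug_lift")
        frac, at_peak = gravitational_fraction(model, traj, kin)
        assert at_peak == pytest.approx(1.0, abs=1e-9)

    def test_slow_jug_lift_is_gravity_dominated(self):
        traj, _ = generate_activity(ActivityParams("jug_lift", seed=0))
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jug_lift")
        _, at_peak = gravitational_fraction(model, traj, kin)
        assert at_peak >= 0.90

    def test_zero_gravity_fraction_is_zero(self):
        traj, _ = generate_activity(ActivityParams("jumping_jack", seed=2, duration=2.0))
        kin = derive_kinematics(traj)
        model = build_prosthesis_model(0.3, "jumping_jack")
        full = rnea_loads(model, traj, kin, gravity=np.zeros(3))
        static = rnea_loads(model, traj, kin, gravity=np.zeros(3), zero_motion=True)
        k = int(np.argmax(full.bending_moment))
        assert full.bending_moment[k] > 0.1  # inertial loads present
        assert static.bending_moment[k] == pytest.approx(0.0, abs=1e-12)
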