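"""Rigid-body layer: joint limits, ground contact, and whole-chain dynamics.

The equations of motion are checked against independent mechanical
oracles: ballistic center-of-mass motion, conservation of energy and of
angular momentum about the center of mass during passive flight.
"""

import numpy as np
import pytest

from mlrgait import config, rigid_body, simulate


def com_state(q, qd, cfg):
    """Independent center-of-mass position/velocity oracle (test-side)."""
    seg = cfg["body"]["segments"]
    fg = cfg["body"]["foot_geometry"]
    m0, L0, c0 = seg["HAT"]["mass"], seg["HAT"]["length"], seg["HAT"]["com"]
    m1, L1, c1 = seg["thigh"]["mass"], seg["thigh"]["length"], seg["thigh"]["com"]
    m2, L2, c2 = seg["shank"]["mass"], seg["shank"]["length"], seg["shank"]["com"]
    m3 = seg["foot"]["mass"]
    cx, cy = fg["com"]
    hip = np.array(q[:2])
    hipv = np.array(qd[:2])
    parts = []
    th = q[2]
    parts.append((m0, hip + c0 * np.array([-np.sin(th), np.cos(th)]),
                  hipv + c0 * qd[2] * np.array([-np.cos(th), -np.sin(th)])))
    for ath in (3, 6):
        t1, t2, ph = q[ath], q[ath + 1], q[ath + 2]
        w1, w2, wp = qd[ath], qd[ath + 1], qd[ath + 2]
        d1 = np.array([np.sin(t1), -np.cos(t1)])
        d1p = np.array([np.cos(t1), np.sin(t1)])
        d2 = np.array([np.sin(t2), -np.cos(t2)])
        d2p = np.array([np.cos(t2), np.sin(t2)])
        parts.append((m1, hip + c1 * d1, hipv + c1 * w1 * d1p))
        parts.append((m2, hip + L1 * d1 + c2 * d2, hipv + L1 * w1 * d1p + c2 * w2 * d2p))
        R = np.array([[np.cos(ph), -np.sin(ph)], [np.sin(ph), np.cos(ph)]])
        off = R @ np.array([cx, cy])
        offp = np.array([-off[1], off[0]])
        parts.append((m3, hip + L1 * d1 + L2 * d2 + off,
                      hipv + L1 * w1 * d1p + L2 * w2 * d2p + wp * offp))
    M = sum(m for m, _, _ in parts)
    com = sum(m * p for m, p, _ in parts) / M
    comv = sum(m * v for m, _, v in parts) / M
    return com, comv, M


class TestJointLimitTorque:
    def test_zero_inside_range(self):
        assert rigid_body.joint_limit_torque(-1.0, 0.0, -2.8, -0.1, 2e3, 3e2) == 0.0

    @pytest.mark.parametrize(
        "angle, lo, hi, k, c, expected",
        [
            (-2.9, -2.8, -0.1, 2.0e3, 3.0e2, 200.0),   # knee hyperflexed
            (0.64, -1.0, 0.54, 2.0e3, 3.0e1, -200.0),  # ankle past dorsiflexion
        ],
    )
    def test_linear_restoring_magnitude(self, angle, lo, hi, k, c, expected):
        tau = rigid_body.joint_limit_torque(angle, 0.0, lo, hi, k, c)
        assert tau == pytest.approx(expected, abs=1e-12)
        # directed toward the range
        assert np.sign(tau) == (1.0 if angle < lo else -1.0)

    def test_continuous_at_boundary(self):
        for b in (-2.8, -0.1):
            assert rigid_body.joint_limit_torque(b, 0.0, -2.8, -0.1, 2e3, 3e2) == 0.0
        eps = 1e-9
        assert abs(rigid_body.joint_limit_torque(-0.1 + eps, 0.0, -2.8, -0.1, 2e3, 3e2)) < 1e-4


class TestContactForce:
    def test_airborne_zero(self, cfg):
        fx, fz = rigid_body.contact_force(0.01, (0.0, 0.0), 0.0, cfg["body"]["contact"])
        assert (fx, fz) == (0.0, 0.0)

    def test_static_penetration(self, cfg):
        _, fz = rigid_body.contact_force(-0.01, (0.0, 0.0), 0.0, cfg["body"]["contact"])
        assert fz == pytest.approx(2.5e4 * 0.01, rel=1e-12)

    def test_unilateral_clamp_no_adhesion(self, cfg):
        # strong upward velocity: spring + damper would be tensile
        _, fz = rigid_body.contact_force(-0.001, (0.0, 1.0), 0.0, cfg["body"]["contact"])
        assert fz == 0.0

    def test_horizontal_needs_load(self, cfg):
        fx, fz = rigid_body.contact_force(0.01, (1.0, 0.0), 0.0, cfg["body"]["contact"],
                                          x=0.5, anchor_x=0.0)
        assert fx == 0.0 and fz == 0.0

    def test_non_finite_rejected(self, cfg):
        with pytest.raises(ValueError):
            rigid_body.contact_force(np.nan, (0.0, 0.0), 0.0, cfg["body"]["contact"])


class TestEquationsOfMotion:
    def test_requires_six_torques(self, cfg):
        q = rigid_body.standing_posture(cfg)
        with pytest.raises(ValueError):
            rigid_body.equations_of_motion(q, np.zeros(9), np.zeros(3), cfg)

    def test_suspended_passive_chain_com_acceleration(self, passive_cfg):
        """Airborne, torque-free: the COM accelerates at exactly -g."""
        cfg = passive_cfg
        q = rigid_body.standing_posture(cfg)
        q[1] += 1.0  # lift clear of the ground
        q[2], q[3], q[4] = 0.2, 0.4, -0.3
        qd = np.zeros(9)
        qdd, cf = rigid_body.equations_of_motion(q, qd, np.zeros(6), cfg)
        assert np.all(cf == 0.0)
        # v_com is linear in qd, so a central difference in qd at fixed q
        # gives the Jacobian-projected acceleration exactly (qd = 0 here,
        # so the convective term vanishes)
        h = 1e-6
        _, v_minus, _ = com_state(q, qd - h * qdd, cfg)
        _, v_plus, _ = com_state(q, qd + h * qdd, cfg)
        a_com = (v_plus - v_minus) / (2 * h)
        g = cfg["body"]["gravity"]
        assert a_com[0] == pytest.approx(0.0, abs=1e-6)
        assert a_com[1] == pytest.approx(-g, rel=1e-6)

    def test_passive_flight_conserves_energy_and_momentum(self, passive_cfg):
        """0.5 s of airborne tumbling at dt = 0.1 ms: energy drift below
        1e-6 of the initial energy per second, and the COM follows a
        ballistic parabola (independent mechanical oracles)."""
        cfg = passive_cfg
        seg, foot_geom, *_ = rigid_body.pack_body_params(cfg)
        g = cfg["body"]["gravity"]
        q0 = rigid_body.standing_posture(cfg)
        q0[1] += 5.0  # well clear of the ground
        q0[2], q0[3], q0[4], q0[7] = 0.2, 0.4, -0.3, 0.25
        qd0 = np.zeros(9)
        qd0[0], qd0[2], qd0[3] = 0.5, 0.8, -1.2

        def f(t, x):
            qdd, _ = rigid_body.equations_of_motion(x[:9], x[9:], np.zeros(6), cfg)
            return np.concatenate([x[9:], qdd])

        dt = 1e-4
        x = np.concatenate([q0, qd0])
        states = [x]
        for k in range(5000):
            x = simulate.rk4_step(f, k * dt, x, dt)
            if k % 100 == 99:
                states.append(x)
        states = np.asarray(states)
        t_rec = np.r_[0.0, (np.arange(len(states) - 1) + 1) * 100 * dt]
        E = np.array(
            [rigid_body.mechanical_energy(s[:9], s[9:], seg, foot_geom, g) for s in states]
        )
        e_scale = abs(E[0] - rigid_body.mechanical_energy(q0 * 0, qd0 * 0, seg, foot_geom, g)) + 1.0
        assert np.max(np.abs(E - E[0])) < 1e-6 * e_scale * 0.5
        # ballistic COM oracle
        coms = np.array([com_state(s[:9], s[9:], cfg)[0] for s in states])
        _, v0, _ = com_state(q0, qd0, cfg)
        assert np.allclose(coms[:, 0], coms[0, 0] + v0[0] * t_rec, atol=1e-7)
        y_pred = coms[0, 1] + v0[1] * t_rec - 0.5 * g * t_rec**2
        assert np.allclose(coms[:, 1], y_pred, atol=1e-7)

    def test_gait_impulse_balances_weight(self, cfg):
        """Steady gait: the vertical GRF impulse over whole strides equals
        body weight x duration (2%); GRFs never pull downward."""
        from pathlib import Path

        params_path = Path(__file__).resolve().parents[1] / "src" / "mlrgait" / "data" / "normal_params.json"
        from mlrgait import optimize

        vec = optimize.load_parameters(params_path)
        traj = simulate.run(cfg, vec)
        # average from one left touchdown to a later left touchdown so the
        # window spans an integer number of gait cycles
        left = [t for t, leg in simulate.detect_steps(traj) if leg == "left"]
        assert len(left) >= 4
        sl = (traj.t >= left[1]) & (traj.t < left[-1])
        total = traj.grf[sl].sum(axis=1)
        weight = config.total_mass(cfg) * cfg["body"]["gravity"]
        assert np.mean(total) == pytest.approx(weight, rel=0.02)
        assert np.all(traj.grf >= 0.0)


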