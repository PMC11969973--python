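"""MLR, CPG, reflex and motoneuron model behaviour."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mlrgait import neural


def mlr_params(cfg):
    m = cfg["mlr"]
    return (m["tau_ppn"], m["tau_cnf"], m["beta_ppn"], m["beta_cnf"],
            m["w_ppn_from_cnf"], m["w_cnf_from_ppn"], m["w_hc"])


def integrate_mlr(cfg, hc_fn, t_end, x0=(0.0, 0.0)):
    p = mlr_params(cfg)

    def f(t, x):
        hp, hc = hc_fn(t)
        return neural.mlr_derivatives(x[0], x[1], hp, hc, *p)

    return solve_ivp(f, (0, t_end), list(x0), max_step=1e-3, rtol=1e-10, atol=1e-12)


class TestHigherCenter:
    @pytest.mark.parametrize(
        "t, s, expected",
        [(1.5, 0.3, 0.3), (3.0, 0.3, 0.3), (4.0, 0.3, 1.0), (4.0, 1.7, 1.0)],
    )
    def test_piecewise_constant(self, t, s, expected):
        hp, hc = neural.higher_center_input(t, s, s, 3.0, 1.0)
        assert hp == expected and hc == expected


class TestMlr:
    def test_rest_is_equilibrium_without_input(self, cfg):
        d = neural.mlr_derivatives(0.0, 0.0, 0.0, 0.0, *mlr_params(cfg))
        assert d == (0.0, 0.0)

    def test_unit_input_fixed_point_is_one_one(self, cfg):
        fp = neural.mlr_fixed_point(cfg, hc=(1.0, 1.0))
        assert fp[0] == pytest.approx(1.0, abs=1e-9)
        assert fp[1] == pytest.approx(1.0, abs=1e-9)
        sol = integrate_mlr(cfg, lambda t: (1.0, 1.0), 10.0)
        assert sol.y[0, -1] == pytest.approx(1.0, abs=1e-6)
        assert sol.y[1, -1] == pytest.approx(1.0, abs=1e-6)

    def test_pulse_response_ppn_outlasts_cnf(self, cfg):
        """PPN activity decays slower than CnF after a brief pulse."""

        def hc(t):
            return (1.0, 1.0) if 0.0 <= t <= 0.01 else (0.0, 0.0)

        sol = integrate_mlr(cfg, hc, 5.0)
        t = sol.t
        decay_times = []
        for row in sol.y:
            peak_i = int(np.argmax(row))
            peak = row[peak_i]
            below = np.where((t > t[peak_i]) & (row < 0.1 * peak))[0]
            decay_times.append(t[below[0]] - t[peak_i])
        assert decay_times[0] > decay_times[1]  # PPN long-lasting


class TestCpg:
    def free_weights(self):
        return np.array([2.0, 2.0, 2.0, 0.8, 0.8, 0.6, 0.6, 0.6, 0.6])

    def integrate(self, cfg, drive, t_end, x0=None, u0=1.5):
        W = neural.build_cpg_matrix(self.free_weights())
        c = cfg["cpg"]

        def f(t, x):
            du, dv = neural.cpg_derivatives(
                x[:12], x[12:], W, c["tau"], c["tau_adapt"], c["beta"],
                u0, drive, np.zeros(12),
            )
            return np.concatenate([du, dv])

        if x0 is None:
            x0 = np.zeros(24)
            x0[0] = 0.05
        return solve_ivp(f, (0, t_end), x0, max_step=2e-3, rtol=1e-8, atol=1e-10)

    def test_matrix_skeleton(self):
        W = neural.build_cpg_matrix(self.free_weights())
        assert np.all(np.diag(W) == 0.0)
        assert np.all(W <= 0.0)  # purely inhibitory skeleton
        # left/right mirror: permuting legs leaves the matrix invariant
        perm = np.r_[6:12, 0:6]
        assert np.array_equal(W[np.ix_(perm, perm)], W)

    def test_zero_state_zero_drive_is_equilibrium(self, cfg):
        c = cfg["cpg"]
        du, dv = neural.cpg_derivatives(
            np.zeros(12), np.zeros(12), neural.build_cpg_matrix(self.free_weights()),
            c["tau"], c["tau_adapt"], c["beta"], 1.5, 0.0, np.zeros(12),
        )
        assert np.all(du == 0.0) and np.all(dv == 0.0)

    def test_limit_cycle_under_unit_drive(self, cfg):
        sol = self.integrate(cfg, 1.0, 20.0)
        y = np.maximum(sol.y[:12], 0.0)
        late = sol.t > 10.0
        # sustained periodic activity in every unit
        for i in range(12):
            assert y[i, late].max() - y[i, late].min() > 0.1

    def test_quiescent_under_zero_drive(self, cfg):
        sol = self.integrate(cfg, 0.0, 10.0)
        assert np.max(np.abs(sol.y[:, -1])) < 1e-6

    def test_period_invariant_to_start_time(self, cfg):
        """Autonomy: the limit-cycle period does not depend on the phase
        of the initial condition."""

        def period(x0):
            sol = self.integrate(cfg, 1.0, 25.0, x0=x0)
            mask = sol.t > 12.0
            s = np.maximum(sol.y[0, mask], 0.0)
            s = s - s.mean()
            t = sol.t[mask]
            idx = np.where((s[:-1] < 0) & (s[1:] >= 0))[0]
            return np.mean(np.diff(t[idx]))

        x0a = np.zeros(24)
        x0a[0] = 0.05
        x0b = np.zeros(24)
        x0b[3] = 0.2
        x0b[7] = 0.1
        assert period(x0a) == pytest.approx(period(x0b), rel=1e-2)


class TestSensoryFeedback:
    def seg_angles(self, mirror=False):
        a = {"HAT": -0.05, "thigh_L": 0.2, "shank_L": -0.1,
             "thigh_R": -0.15, "shank_R": 0.05}
        if mirror:
            a = {"HAT": a["HAT"], "thigh_L": a["thigh_R"], "shank_L": a["shank_R"],
                 "thigh_R": a["thigh_L"], "shank_R": a["shank_L"]}
        return a

    def test_zero_weights_zero_feedback(self):
        f = neural.sensory_feedback(self.seg_angles(), (300.0, 400.0), 700.0, np.zeros(16))
        assert np.all(f == 0.0)

    def test_weight_count_enforced(self):
        with pytest.raises(ValueError):
            neural.sensory_feedback(self.seg_angles(), (300.0, 400.0), 700.0, np.zeros(15))

    def test_mirror_symmetry(self):
        w = np.linspace(0.1, 1.6, 16)
        f = neural.sensory_feedback(self.seg_angles(), (300.0, 400.0), 700.0, w)
        f_sw = neural.sensory_feedback(self.seg_angles(mirror=True), (400.0, 300.0), 700.0, w)
        assert np.array_equal(f[:6], f_sw[6:])
        assert np.array_equal(f[6:], f_sw[:6])

    def test_linearity(self):
        w = np.linspace(0.1, 1.6, 16)
        a = self.seg_angles()
        f1 = neural.sensory_feedback(a, (300.0, 400.0), 700.0, w)
        a3 = {k: 3.0 * v for k, v in a.items()}
        f3 = neural.sensory_feedback(a3, (900.0, 1200.0), 700.0, w)
        assert np.allclose(f3, 3.0 * f1, rtol=1e-12)


class TestPostureControl:
    REFS = np.array([-0.04, 0.0, -0.25, 0.0])

    def test_zero_weights_zero_output(self):
        P = neural.posture_control({"HAT": 0.1}, np.zeros(6), (300.0, 400.0), 700.0,
                                   np.zeros(23), self.REFS)
        assert np.all(P == 0.0)

    def test_weight_count_enforced(self):
        with pytest.raises(ValueError):
            neural.posture_control({"HAT": 0.1}, np.zeros(6), (300.0, 400.0), 700.0,
                                   np.zeros(22), self.REFS)

    def test_mirror_symmetry(self):
        w = np.linspace(0.5, 11.5, 23)
        ja = np.array([0.1, -0.3, 0.05, -0.2, -0.5, 0.2])
        ja_sw = np.concatenate([ja[3:], ja[:3]])
        P = neural.posture_control({"HAT": 0.07}, ja, (250.0, 450.0), 700.0, w, self.REFS)
        P_sw = neural.posture_control({"HAT": 0.07}, ja_sw, (450.0, 250.0), 700.0, w, self.REFS)
        assert np.array_equal(P[:9], P_sw[9:])
        assert np.array_equal(P[9:], P_sw[:9])

    def test_forward_pitch_excites_extensors_monotonically(self):
        """Leaning the trunk forward monotonically strengthens the
        stance-gated extensor (antigravity) excitation."""
        w = np.full(23, 5.0)
        ja = np.zeros(6)
        ja[1] = ja[4] = -0.25
        pitches = np.linspace(0.2, -0.4, 15)  # toward forward lean
        gm = []
        so = []
        for p in pitches:
            P = neural.posture_control({"HAT": p}, ja, (350.0, 350.0), 700.0, w, self.REFS)
            gm.append(P[0])
            so.append(P[7])
        # P more negative = stronger excitation
        assert np.all(np.diff(gm) < 0)
        assert np.all(np.diff(so) < 0)


class TestMotoneuron:
    def test_zero_argument_gives_zero(self):
        alpha = neural.motoneuron_output(np.zeros(12), np.zeros(18), 1.0, np.zeros((18, 12)))
        assert np.allclose(alpha, 0.0)

    def test_sigmoid_limits_and_clamp(self):
        W = np.zeros((18, 12))
        # strongly negative argument -> full activation
        a_hi = neural.motoneuron_output(np.zeros(12), np.full(18, -1e3), 1.0, W)
        assert np.allclose(a_hi, 1.0)
        # strongly positive argument -> raw -1, clamped to 0
        a_lo = neural.motoneuron_output(np.zeros(12), np.full(18, 1e3), 1.0, W)
        assert np.allclose(a_lo, 0.0)

    def test_ppn_divides_posture_term(self):
        """alpha(P, 2 u_PPN) equals alpha(P/2, u_PPN)."""
        P = np.linspace(-3, 3, 18)
        a1 = neural.motoneuron_output(np.zeros(12), P, 2.0, np.zeros((18, 12)))
        a2 = neural.motoneuron_output(np.zeros(12), P / 2.0, 1.0, np.zeros((18, 12)))
        assert np.allclose(a1, a2, rtol=1e-12)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = neural.motoneuron_output(
                rng.normal(0, 2, 12), rng.normal(0, 5, 18),
                abs(rng.normal(1, 1)) + 1e-6, rng.normal(0, 1, (18, 12)),
            )
            assert np.all(a >= 0.0) and np.all(a <= 1.0)

    def test_u_ppn_floored_not_raised(self, cfg):
        P = np.full(18, 1.0)
        a_small = neural.motoneuron_output(np.zeros(12), P, 1e-9, np.zeros((18, 12)), floor=1e-3)
        a_floor = neural.motoneuron_output(np.zeros(12), P, 1e-3, np.zeros((18, 12)), floor=1e-3)
        assert np.allclose(a_small, a_floor)
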