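"""Fused compiled core: coupled neural + musculoskeletal RHS and RK4 loop.

This module composes the compiled primitives from :mod:`rigid_body`,
:mod:`muscle` and :mod:`neural` into a single right-hand side of the
44-dimensional state

    x = [q (9), qdot (9), u_PPN, u_CnF, u_CPG (12), v_CPG (12)]

and integrates it with fixed-step 4th-order Runge-Kutta. The horizontal
contact-spring anchors are discrete states held fixed during the four RK
stages and updated once per step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .muscle import force_length, force_velocity, metabolic_rate
from .neural import (
    cpg_derivatives,
    higher_center_input,
    mlr_derivatives,
    motoneuron_output_core,
    posture_control_core,
    sensory_feedback_core,
)
from .rigid_body import contact_kinematics, eom_core, joint_angles, vertical_contact_force

NSTATE = 44


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def _grf(q, qd, seg, foot_geom, cont, ground_h):
    """Vertical GRF per limb (left, right) from the current kinematics."""
    pos, vel = contact_kinematics(q, qd, seg, foot_geom)
    gl = 0.0
    gr = 0.0
    for k in range(4):
        fz = vertical_contact_force(pos[k, 1], vel[k, 1], ground_h, cont[2], cont[3])
        if k < 2:
            gl += fz
        else:
            gr += fz
    return gl, gr


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def _muscle_torques_and_alpha(q, qd, x, gl, gr, mus, refs, walpha, wpos, pref,
                              mg, gain, floor):
    """Joint torques (6,) from all muscles plus the alpha vector (18,)."""
    ja, jv = joint_angles(q, qd)
    u_ppn = x[18]
    y = np.empty(12)
    for i in range(12):
        ui = x[20 + i]
        y[i] = ui if ui > 0.0 else 0.0
    ghat_l = gl / mg
    ghat_r = gr / mg
    P = posture_control_core(q[2], ja, ghat_l, ghat_r, wpos, pref)
    alpha = motoneuron_output_core(y, P, u_ppn, walpha, gain, floor)
    tau = np.zeros(6)
    for m in range(18):
        base = 0 if m < 9 else 3
        L = mus[m, 1]
        Ldot = 0.0
        for j in range(3):
            rho = mus[m, 5 + j]
            L -= rho * (ja[base + j] - refs[j])
            Ldot -= rho * jv[base + j]
        xi = L / mus[m, 1]
        eta = Ldot / mus[m, 2]
        f = (
            mus[m, 0] * force_length(xi) * force_velocity(eta) * alpha[m]
            + mus[m, 3] * Ldot
            + mus[m, 4] * (np.exp(15.0 * (L - mus[m, 1])) - 1.0)
        )
        if f < 0.0:
            f = 0.0  # tendons pull, never push
        for j in range(3):
            tau[base + j] += mus[m, 5 + j] * f
    return tau, alpha, y


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def rhs(t, x, anch_active, anch_x, seg, foot_geom, jvis, klim, alim, cont,
        grav, ground_h, mus, refs, walpha, mlr, u_floor, cpgp, wcpg, u0,
        wfeed, wpos, pref, mg, gain, s_ppn, s_cnf, hc_switch, hc_post):
    """Full coupled right-hand side dx/dt."""
    q = x[:9]
    qd = x[9:18]
    u_ppn = x[18]
    u_cnf = x[19]
    u = x[20:32]
    v = x[32:44]

    gl, gr = _grf(q, qd, seg, foot_geom, cont, ground_h)
    tau, alpha, y = _muscle_torques_and_alpha(
        q, qd, x, gl, gr, mus, refs, walpha, wpos, pref, mg, gain, u_floor
    )
    qdd, _, _, _ = eom_core(
        q, qd, tau, seg, foot_geom, jvis, klim, alim, cont,
        grav, ground_h, anch_active, anch_x,
    )

    hc_p, hc_c = higher_center_input(t, s_ppn, s_cnf, hc_switch, hc_post)
    du_p, du_c = mlr_derivatives(
        u_ppn, u_cnf, hc_p, hc_c,
        mlr[0], mlr[1], mlr[2], mlr[3], mlr[4], mlr[5], mlr[6],
    )
    feed = sensory_feedback_core(q[2], q[3], q[4], q[6], q[7], gl / mg, gr / mg, wfeed)
    du, dv = cpg_derivatives(u, v, wcpg, cpgp[0], cpgp[1], cpgp[2], u0, u_cnf, feed)

    dx = np.empty(NSTATE)
    dx[:9] = qd
    dx[9:18] = qdd
    dx[18] = du_p
    dx[19] = du_c
    dx[20:32] = du
    dx[32:44] = dv
    return dx


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def aux_outputs(q, qd, x, seg, foot_geom, cont, ground_h, mus, refs,
                walpha, wpos, pref, mg, gain, u_floor, c_act, c_short, c_basal):
    """Recorded quantities: GRFs, alpha, CPG outputs, total metabolic rate."""
    gl, gr = _grf(q, qd, seg, foot_geom, cont, ground_h)
    tau, alpha, y = _muscle_torques_and_alpha(
        q, qd, x, gl, gr, mus, refs, walpha, wpos, pref, mg, gain, u_floor
    )
    ja, jv = joint_angles(q, qd)
    edot = 0.0
    for m in range(18):
        base = 0 if m < 9 else 3
        Ldot = 0.0
        for j in range(3):
            Ldot -= mus[m, 5 + j] * jv[base + j]
        eta = Ldot / mus[m, 2]
        edot += metabolic_rate(mus[m, 0], mus[m, 2], alpha[m], eta, c_act, c_short, c_basal)
    return gl, gr, alpha, y, edot


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def _update_anchors(q, qd, anch_active, anch_x, seg, foot_geom, cont, ground_h):
    """Set anchors at touchdown, release when the vertical force vanishes."""
    pos, vel = contact_kinematics(q, qd, seg, foot_geom)
    for k in range(4):
        fz = vertical_contact_force(pos[k, 1], vel[k, 1], ground_h, cont[2], cont[3])
        if fz > 0.0:
            if anch_active[k] == 0:
                anch_active[k] = 1
                anch_x[k] = pos[k, 0]
        else:
            anch_active[k] = 0


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def run_core(x0, dt, n_steps, decim, seg, foot_geom, jvis, klim, alim, cont,
             grav, ground_h, mus, refs, walpha, mlr, u_floor, cpgp, wcpg, u0,
             wfeed, wpos, pref, mg, gain, s_ppn, s_cnf, hc_switch, hc_post,
             c_act, c_short, c_basal, y_stand, fall_frac, fall_pitch,
             rec_t, rec_q, rec_qd, rec_grf, rec_mlr, rec_y, rec_alpha, rec_edot):
    """Fixed-step RK4 integration with recording and fall detection.

    Returns (number of recorded samples, fall step index or -1).
    """
    x = x0.copy()
    anch_active = np.zeros(4, dtype=np.int8)
    anch_x = np.zeros(4)
    _update_anchors(x[:9], x[9:18], anch_active, anch_x, seg, foot_geom, cont, ground_h)
    r = 0
    fall_step = -1
    k2buf = np.empty(NSTATE)
    for k in range(n_steps + 1):
        t = k * dt
        q = x[:9]
        # fall: hip drops below a fraction of standing height, or the
        # trunk pitches past +/- fall_pitch
        if (q[1] - ground_h) < fall_frac * y_stand or abs(q[2]) > fall_pitch:
            fall_step = k
        if k % decim == 0 or fall_step >= 0:
            rec_t[r] = t
            gl, gr, alpha, y, edot = aux_outputs(
                x[:9], x[9:18], x, seg, foot_geom, cont, ground_h, mus, refs,
                walpha, wpos, pref, mg, gain, u_floor, c_act, c_short, c_basal,
            )
            for i in range(9):
                rec_q[r, i] = x[i]
                rec_qd[r, i] = x[9 + i]
            rec_grf[r, 0] = gl
            rec_grf[r, 1] = gr
            rec_mlr[r, 0] = x[18]
            rec_mlr[r, 1] = x[19]
            for i in range(12):
                rec_y[r, i] = y[i]
            for i in range(18):
                rec_alpha[r, i] = alpha[i]
            rec_edot[r] = edot
            r += 1
        if fall_step >= 0 or k == n_steps:
            break
        # RK4 with anchors frozen over the step
        k1 = rhs(t, x, anch_active, anch_x, seg, foot_geom, jvis, klim, alim,
                 cont, grav, ground_h, mus, refs, walpha, mlr, u_floor, cpgp,
                 wcpg, u0, wfeed, wpos, pref, mg, gain, s_ppn, s_cnf,
                 hc_switch, hc_post)
        for i in range(NSTATE):
            k2buf[i] = x[i] + 0.5 * dt * k1[i]
        k2 = rhs(t + 0.5 * dt, k2buf, anch_active, anch_x, seg, foot_geom,
                 jvis, klim, alim, cont, grav, ground_h, mus, refs, walpha,
                 mlr, u_floor, cpgp, wcpg, u0, wfeed, wpos, pref, mg, gain,
                 s_ppn, s_cnf, hc_switch, hc_post)
        for i in range(NSTATE):
            k2buf[i] = x[i] + 0.5 * dt * k2[i]
        k3 = rhs(t + 0.5 * dt, k2buf, anch_active, anch_x, seg, foot_geom,
                 jvis, klim, alim, cont, grav, ground_h, mus, refs, walpha,
                 mlr, u_floor, cpgp, wcpg, u0, wfeed, wpos, pref, mg, gain,
                 s_ppn, s_cnf, hc_switch, hc_post)
        for i in range(NSTATE):
            k2buf[i] = x[i] + dt * k3[i]
        k4 = rhs(t + dt, k2buf, anch_active, anch_x, seg, foot_geom, jvis,
                 klim, alim, cont, grav, ground_h, mus, refs, walpha, mlr,
                 u_floor, cpgp, wcpg, u0, wfeed, wpos, pref, mg, gain,
                 s_ppn, s_cnf, hc_switch, hc_post)
        bad = False
        for i in range(NSTATE):
            x[i] = x[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not np.isfinite(x[i]):
                bad = True
        if bad:
            # numerically blown up: treat as a fall at this step
            fall_step = k + 1
            break
        _update_anchors(x[:9], x[9:18], anch_active, anch_x, seg, foot_geom,
                        cont, ground_h)
    return r, fall_step
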